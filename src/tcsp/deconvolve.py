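"""Subtype mRNA-fraction estimation by linear epsilon-SVR.

A bulk sample's CPM vector over the model genes (B) is normalized gene-wise
by the per-gene maximum of the signature matrix, and the mixture B = S x F
is solved for F with a no-intercept linear epsilon-insensitive support
vector regression. Negative coefficients are clipped to zero and the result
is reported on a 0-100 scale. Raw estimates are not forced to sum to 100:
the five subtypes need not explain the whole sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVR

from tcsp.core_io import SUBTYPES, ExpressionMatrix, SignatureModel
from tcsp.errors import (
    CoverageError,
    InputFormatError,
    UndefinedNormalizationError,
    UndefinedRatioError,
)

logger = logging.getLogger(__name__)


@dataclass
class SolverParams:
    """Hyperparameters of the epsilon-SVR fit.

    The regularization strength is swept over ``c_grid`` and the fit with
    the smallest residual norm is kept.
    """

    epsilon: float = 0.001
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    max_iter: int = 100_000
    tol: float = 1e-10
    coverage_floor: float = 0.5


@dataclass
class CoverageReport:
    matched_genes: int
    model_genes: int
    missing: list[str]

    @property
    def fraction(self) -> float:
        return self.matched_genes / self.model_genes


@dataclass
class SubtypeEstimate:
    """Estimated mRNA fractions of one sample on the 0-100 scale."""

    sample_id: str
    raw: np.ndarray  # length 5, order N, A, EX, EM, CM
    genes_used: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (5,):
            raise InputFormatError(f"raw estimate must have length 5, got {self.raw.shape}")
        if not np.isfinite(self.raw).all() or (self.raw < 0).any():
            raise InputFormatError("raw estimates must be finite and non-negative")

    @property
    def sum(self) -> float:
        return float(self.raw.sum())

    @property
    def normalized(self) -> np.ndarray | None:
        """Sum-normalized fractions in [0, 1]; None when the sum is zero."""
        total = self.sum
        if total <= 0:
            return None
        return self.raw / total

    def __getitem__(self, subtype: str) -> float:
        return float(self.raw[SUBTYPES.index(subtype)])


def align_to_model(
    sample: pd.Series, model: SignatureModel, coverage_floor: float = 0.5
) -> tuple[np.ndarray, CoverageReport]:
    """Order a sample's CPM values by the model genes.

    Model genes absent from the sample are imputed as 0 (logged) so the
    signature matrix stays fixed across a cohort; a matched fraction below
    ``coverage_floor`` is an error.
    """
    genes = model.gene_ids
    present = [g for g in genes if g in sample.index]
    missing = [g for g in genes if g not in sample.index]
    if not present:
        raise CoverageError("sample shares no genes with the model")
    report = CoverageReport(
        matched_genes=len(present), model_genes=len(genes), missing=missing
    )
    if report.fraction < coverage_floor:
        raise CoverageError(
            f"sample covers {report.matched_genes}/{report.model_genes} model genes "
            f"({report.fraction:.2f} < floor {coverage_floor})"
        )
    if missing:
        logger.warning(
            "%d model gene(s) missing from sample, imputed as 0: %s",
            len(missing),
            missing[:10],
        )
    B = np.array([float(sample[g]) if g in sample.index else 0.0 for g in genes])
    return B, report


def normalize_to_model_max(
    B: np.ndarray, model: SignatureModel
) -> tuple[np.ndarray, np.ndarray]:
    """Divide B and S gene-wise by the per-gene maximum of S.

    Every row of the returned S' has maximum exactly 1.
    """
    S = model.S.to_numpy()
    divisor = S.max(axis=1)
    if (divisor <= 0).any():
        raise InputFormatError("model has an all-zero row; cannot normalize")
    return B / divisor, S / divisor[:, None]


def estimate_fractions(
    B_norm: np.ndarray,
    S_norm: np.ndarray,
    params: SolverParams | None = None,
    sample_id: str = "sample",
    genes_used: int | None = None,
) -> SubtypeEstimate:
    """Solve B' = S' F with no-intercept linear epsilon-SVR.

    Fits once per regularization strength in the sweep, keeps the solution
    with minimal residual norm, clips negative coefficients to zero and
    scales by 100. A rank-deficient S' (e.g. duplicated subtype column) is
    flagged in the diagnostics, not an error.
    """
    params = params or SolverParams()
    B_norm = np.asarray(B_norm, dtype=float)
    S_norm = np.asarray(S_norm, dtype=float)
    if not (np.isfinite(B_norm).all() and np.isfinite(S_norm).all()):
        raise InputFormatError("non-finite values in deconvolution input")
    if S_norm.ndim != 2 or S_norm.shape[1] != len(SUBTYPES):
        raise InputFormatError(f"S' must be (genes, 5), got {S_norm.shape}")
    if B_norm.shape != (S_norm.shape[0],):
        raise InputFormatError("B' length does not match S' rows")
    if S_norm.shape[0] < len(SUBTYPES):
        raise InputFormatError("need at least 5 genes to estimate 5 fractions")

    diagnostics: dict = {"solver": "linear epsilon-SVR (no intercept)"}
    rank = int(np.linalg.matrix_rank(S_norm))
    if rank < len(SUBTYPES):
        diagnostics["rank_deficient"] = True
        logger.warning("rank-deficient signature matrix (rank %d < 5)", rank)

    best: tuple[float, float, np.ndarray] | None = None
    for C in params.c_grid:
        svr = LinearSVR(
            epsilon=params.epsilon,
            C=C,
            loss="epsilon_insensitive",
            fit_intercept=False,
            max_iter=params.max_iter,
            tol=params.tol,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            svr.fit(S_norm, B_norm)
        coef = np.asarray(svr.coef_, dtype=float)
        residual = float(np.linalg.norm(S_norm @ coef - B_norm))
        if best is None or residual < best[0]:
            best = (residual, C, coef)
    assert best is not None
    residual, chosen_c, coef = best
    clipped = coef < 0
    raw = np.clip(coef, 0.0, None) * 100.0
    diagnostics.update(
        {
            "residual_norm": residual,
            "C": chosen_c,
            "epsilon": params.epsilon,
            "clipped_subtypes": [SUBTYPES[i] for i in np.where(clipped)[0]],
        }
    )
    if (raw > 100).any():
        diagnostics["above_100"] = [SUBTYPES[i] for i in np.where(raw > 100)[0]]
        logger.warning("estimate(s) above 100 for %s: %s", sample_id, diagnostics["above_100"])
    return SubtypeEstimate(
        sample_id=sample_id,
        raw=raw,
        genes_used=genes_used if genes_used is not None else S_norm.shape[0],
        diagnostics=diagnostics,
    )


def sum_normalize(e: SubtypeEstimate) -> np.ndarray:
    """Raw estimates divided by their sum; error when the sum is zero."""
    normalized = e.normalized
    if normalized is None:
        raise UndefinedNormalizationError(
            f"sample {e.sample_id!r}: all five estimates are zero; normalization undefined"
        )
    return normalized


def composite_ratio(e: SubtypeEstimate, numerator: str, denominator: str) -> float:
    """raw[numerator] / raw[denominator], e.g. the EX/EM exhaustion ratio."""
    num = e[numerator]
    den = e[denominator]
    if den <= 0:
        raise UndefinedRatioError(num, den, f"sample {e.sample_id!r}: {numerator}/{denominator} undefined ({num}/{den})")
    return num / den


def deconvolve_samples(
    expr: ExpressionMatrix,
    model: SignatureModel,
    params: SolverParams | None = None,
) -> list[SubtypeEstimate]:
    """Estimate fractions for every sample of a CPM matrix."""
    if expr.unit != "cpm":
        raise InputFormatError("deconvolution expects a CPM matrix; run compute_cpm first")
    params = params or SolverParams()
    estimates = []
    for sample_id in expr.sample_ids:
        B, report = align_to_model(
            expr.data[sample_id], model, coverage_floor=params.coverage_floor
        )
        B_norm, S_norm = normalize_to_model_max(B, model)
        est = estimate_fractions(
            B_norm, S_norm, params, sample_id=sample_id, genes_used=report.matched_genes
        )
        estimates.append(est)
    return estimates


def estimates_to_frame(
    estimates: Sequence[SubtypeEstimate],
    normalized: bool = False,
    ratios: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Tabulate estimates: sample, N, A, EX, EM, CM, Sum, genes_used [...]."""
    rows = []
    for e in estimates:
        row: dict = {"sample": e.sample_id}
        row.update({t: e.raw[i] for i, t in enumerate(SUBTYPES)})
        row["Sum"] = e.sum
        row["genes_used"] = e.genes_used
        if normalized:
            norm = e.normalized
            for i, t in enumerate(SUBTYPES):
                row[f"{t}_norm"] = norm[i] if norm is not None else np.nan
        for num, den in ratios:
            try:
                row[f"{num}/{den}"] = composite_ratio(e, num, den)
            except UndefinedRatioError:
                row[f"{num}/{den}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
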