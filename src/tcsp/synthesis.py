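"""Seeded synthetic reference, background and mixture generators.

Every other module is testable offline against these: subtype reference
profiles with planted marker genes and negative-binomial replicate noise, a
tumor background panel expressing a disjoint "tumor" gene block, and
count-level mixtures drawn multinomially from a convex combination of
component CPM distributions (the count-space analogue of read-level
subsampling). All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tcsp.core_io import SUBTYPES, ExpressionMatrix, compute_cpm
from tcsp.errors import ConfigError
from tcsp.signature import BackgroundPanel, ReferenceProfileSet

#: The 11-point exhausted-into-background titration series (fractions).
TITRATION_FRACTIONS = (0.0, 0.01, 0.02, 0.05, 0.08, 0.12, 0.17, 0.25, 0.50, 0.75, 1.0)

_DEFAULT_REPLICATES = {"N": 8, "A": 3, "EX": 6, "EM": 5, "CM": 3}
_TUMOR_ORIGINS = ("lung", "ovary", "skin", "breast", "colon")
_IMMUNE_ORIGIN = "haematopoietic_and_lymphoid_tissue"


@dataclass
class SynthesisConfig:
    """Parameters of the synthetic gene universe and its noise model."""

    seed: int
    n_genes: int = 600
    markers_per_subtype: int = 10
    marker_fold: float = 8.0
    replicates_per_subtype: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_REPLICATES)
    )
    background_profiles: int = 5
    depth: int = 1_000_000
    dispersion: float = 0.1
    n_tumor_genes: int = 50
    tumor_fold: float = 8.0
    contamination_markers: int = 0
    immune_lines: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("n_genes", "markers_per_subtype", "background_profiles", "depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.marker_fold < 1:
            raise ConfigError(f"marker_fold must be >= 1, got {self.marker_fold}")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        unknown = set(self.replicates_per_subtype) - set(SUBTYPES)
        if unknown:
            raise ConfigError(f"unknown subtype(s) in replicates_per_subtype: {sorted(unknown)}")
        for t in SUBTYPES:
            if self.replicates_per_subtype.get(t, 0) < 2:
                raise ConfigError(f"subtype {t} needs >= 2 replicates")
        needed = self.markers_per_subtype * len(SUBTYPES) + self.n_tumor_genes
        if needed > self.n_genes:
            raise ConfigError(
                f"{needed} marker+tumor genes do not fit in {self.n_genes} genes"
            )
        if self.contamination_markers > self.markers_per_subtype:
            raise ConfigError("contamination_markers exceeds markers_per_subtype")


@dataclass
class GeneUniverse:
    """Shared baseline and gene-role assignment for one seed."""

    gene_ids: list[str]
    baseline: np.ndarray  # relative expression, arbitrary scale
    markers: dict[str, list[str]]  # subtype -> marker gene ids
    tumor_genes: list[str]


@dataclass
class SyntheticReference:
    counts: ExpressionMatrix
    reference: ReferenceProfileSet
    markers: dict[str, list[str]]
    expected_cpm: pd.DataFrame  # genes x subtypes


@dataclass
class SyntheticBackground:
    counts: ExpressionMatrix
    panel: BackgroundPanel
    expected_cpm: pd.DataFrame  # genes x cell lines
    mean_profile: pd.Series  # expected CPM of an average background sample
    tumor_genes: list[str]
    contaminated_markers: list[str]


@dataclass
class MixtureSpec:
    """A convex combination of expected-CPM component profiles."""

    components: pd.DataFrame  # genes x components, expected CPM
    fractions: Sequence[float]
    depth: int
    seed: int
    sample_id: str = "mix"

    def __post_init__(self) -> None:
        fractions = np.asarray(self.fractions, dtype=float)
        if fractions.ndim != 1 or len(fractions) != self.components.shape[1]:
            raise ConfigError("one fraction per component required")
        if (fractions < 0).any():
            raise ConfigError("fractions must be non-negative")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ConfigError(f"fractions must sum to 1, got {fractions.sum()!r}")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")


def gene_universe(cfg: SynthesisConfig) -> GeneUniverse:
    """Deterministic baseline expression and gene-role assignment.

    Derived from the seed alone, so reference and background generators
    called with the same config share gene identities and baseline levels.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(3)[0])
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n_genes)
    special = rng.choice(
        cfg.n_genes,
        size=cfg.markers_per_subtype * len(SUBTYPES) + cfg.n_tumor_genes,
        replace=False,
    )
    # pin special genes at the baseline median so markers clear the CPM gate
    baseline[special] = 1.0
    markers = {}
    for i, t in enumerate(SUBTYPES):
        block = special[i * cfg.markers_per_subtype : (i + 1) * cfg.markers_per_subtype]
        markers[t] = sorted(gene_ids[j] for j in block)
    tumor = sorted(gene_ids[j] for j in special[cfg.markers_per_subtype * len(SUBTYPES) :])
    return GeneUniverse(gene_ids=gene_ids, baseline=baseline, markers=markers, tumor_genes=tumor)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _expected_cpm(rel: np.ndarray) -> np.ndarray:
    return rel / rel.sum() * 1e6


def generate_reference(cfg: SynthesisConfig) -> SyntheticReference:
    """Subtype reference replicates with planted marker genes.

    Each subtype's expected profile elevates its own markers marker_fold
    over the shared baseline; replicate counts are negative-binomial at the
    configured depth and dispersion.
    """
    uni = gene_universe(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(3)[1])
    index = pd.Index(uni.gene_ids, name="gene")
    marker_pos = {
        t: [uni.gene_ids.index(g) for g in uni.markers[t]] for t in SUBTYPES
    }
    expected = {}
    columns = {}
    labels = {}
    for t in SUBTYPES:
        rel = uni.baseline.copy()
        rel[marker_pos[t]] *= cfg.marker_fold
        cpm = _expected_cpm(rel)
        expected[t] = cpm
        mean_counts = cpm / 1e6 * cfg.depth
        for rep in range(cfg.replicates_per_subtype[t]):
            sample = f"{t}_rep{rep + 1}"
            columns[sample] = _nb_counts(rng, mean_counts, cfg.dispersion)
            labels[sample] = t
    counts = ExpressionMatrix(pd.DataFrame(columns, index=index, dtype=float), unit="counts")
    reference = ReferenceProfileSet(matrix=compute_cpm(counts), labels=labels)
    return SyntheticReference(
        counts=counts,
        reference=reference,
        markers=dict(uni.markers),
        expected_cpm=pd.DataFrame(expected, index=index),
    )


def generate_background(cfg: SynthesisConfig) -> SyntheticBackground:
    """Background (CD45-/CCLE-like) cell-line panel.

    Lines express the baseline plus an elevated disjoint tumor-gene block
    and zero expected expression on every subtype marker, unless
    ``contamination_markers`` plants that many exhausted-subtype markers
    into the background. ``immune_lines`` appends immune-origin lines
    (expressing all markers) that the origin filter should exclude.
    """
    uni = gene_universe(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    index = pd.Index(uni.gene_ids, name="gene")
    all_markers = [g for t in SUBTYPES for g in uni.markers[t]]
    marker_pos = [uni.gene_ids.index(g) for g in all_markers]
    tumor_pos = [uni.gene_ids.index(g) for g in uni.tumor_genes]
    contaminated = uni.markers["EX"][: cfg.contamination_markers]
    contaminated_pos = [uni.gene_ids.index(g) for g in contaminated]

    expected = {}
    columns = {}
    origins = {}
    for i in range(cfg.background_profiles):
        line = f"BG{i + 1:03d}"
        rel = uni.baseline.copy()
        rel[marker_pos] = 0.0
        rel[tumor_pos] = cfg.tumor_fold * rng.lognormal(0.0, 0.25, size=len(tumor_pos))
        if contaminated_pos:
            rel[contaminated_pos] = cfg.marker_fold
        cpm = _expected_cpm(rel)
        expected[line] = cpm
        columns[line] = _nb_counts(rng, cpm / 1e6 * cfg.depth, cfg.dispersion)
        origins[line] = _TUMOR_ORIGINS[i % len(_TUMOR_ORIGINS)]
    for i in range(cfg.immune_lines):
        line = f"IMM{i + 1:03d}"
        rel = uni.baseline.copy()
        pos = [uni.gene_ids.index(g) for g in all_markers]
        rel[pos] *= cfg.marker_fold
        cpm = _expected_cpm(rel)
        expected[line] = cpm
        columns[line] = _nb_counts(rng, cpm / 1e6 * cfg.depth, cfg.dispersion)
        origins[line] = _IMMUNE_ORIGIN

    counts = ExpressionMatrix(pd.DataFrame(columns, index=index, dtype=float), unit="counts")
    panel = BackgroundPanel(matrix=compute_cpm(counts), origin_labels=origins)
    expected_frame = pd.DataFrame(expected, index=index)
    tumor_only = [c for c in expected_frame.columns if c.startswith("BG")]
    mean_profile = expected_frame[tumor_only].mean(axis=1)
    mean_profile = mean_profile / mean_profile.sum() * 1e6
    return SyntheticBackground(
        counts=counts,
        panel=panel,
        expected_cpm=expected_frame,
        mean_profile=mean_profile,
        tumor_genes=list(uni.tumor_genes),
        contaminated_markers=list(contaminated),
    )


def mix_counts(spec: MixtureSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw counts from a convex combination of component CPM profiles.

    The expected mixture CPM is sum_i fraction_i * component CPM_i; counts
    are multinomial at the requested depth. Returns the count matrix and
    the ground-truth fraction vector.
    """
    fractions = np.asarray(spec.fractions, dtype=float)
    comp = spec.components.to_numpy(dtype=float)
    proportions = comp / comp.sum(axis=0, keepdims=True)
    p = proportions @ fractions
    p = p / p.sum()  # guard rounding
    rng = np.random.default_rng(spec.seed)
    draw = rng.multinomial(spec.depth, p)
    frame = pd.DataFrame(
        {spec.sample_id: draw.astype(float)},
        index=spec.components.index.copy(),
    )
    return ExpressionMatrix(frame, unit="counts"), fractions


def make_titration(
    exhausted_profile: pd.Series,
    background_profile: pd.Series,
    fractions: Sequence[float] = TITRATION_FRACTIONS,
    depth: int = 1_000_000,
    seed: int = 0,
) -> list[tuple[ExpressionMatrix, float]]:
    """Mix an exhausted profile into a background profile at each fraction.

    The default series is the 11-point 0-100% design; each element of the
    result pairs a one-sample count matrix with its true exhausted fraction.
    """
    if not exhausted_profile.index.equals(background_profile.index):
        raise ConfigError("profiles must share the same gene index")
    components = pd.DataFrame(
        {"EX": exhausted_profile, "BG": background_profile}
    )
    children = np.random.SeedSequence(seed).spawn(len(fractions))
    out = []
    for f, child in zip(fractions, children):
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"fraction {f} outside [0, 1]")
        spec = MixtureSpec(
            components=components,
            fractions=[f, 1.0 - f],
            depth=depth,
            seed=int(child.generate_state(1)[0]),
            sample_id=f"titr_{int(round(f * 100)):03d}pct",
        )
        matrix, _ = mix_counts(spec)
        out.append((matrix, f))
    return out
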