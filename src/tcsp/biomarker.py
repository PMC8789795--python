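"""Bootstrap out-of-bag biomarker evaluation and comparison statistics.

Features (subtype estimates or gene-set expression) are standardized, a
projection plus classifier pipeline is fit on each bootstrap bag, and
out-of-bag samples collect probability-like scores. A sample's final score
is its mean over all iterations in which it was out-of-bag; one ROC/AUC is
computed from these mean scores, and the same scores thresholded at 0.5
stratify samples for Kaplan-Meier / log-rank survival analysis.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.special import expit
from scipy.stats import mannwhitneyu, rankdata

from tcsp.core_io import SUBTYPES, ExpressionMatrix
from tcsp.deconvolve import SubtypeEstimate
from tcsp.errors import ConfigError, InputFormatError, ParameterError

logger = logging.getLogger(__name__)

PROJECTIONS = ("none", "pca", "ica", "kpca")
CLASSIFIERS = ("adaboost", "knn", "rf", "svm", "constant")

#: Exact Mann-Whitney enumeration is used up to this pooled sample size.
EXACT_MW_LIMIT = 12


@dataclass
class FeatureTable:
    """Per-sample numeric features with binary labels and optional survival."""

    X: pd.DataFrame  # samples x features
    y: pd.Series  # binary labels, index-aligned with X
    survival: pd.DataFrame | None = None  # columns: time, event

    def __post_init__(self) -> None:
        if self.X.isna().to_numpy().any():
            raise InputFormatError("feature table contains missing values")
        self.y = self.y.loc[self.X.index]
        values = set(self.y.unique().tolist())
        if not values <= {0, 1}:
            raise InputFormatError(f"labels must be binary 0/1, got {sorted(values)}")
        if self.survival is not None:
            self.survival = self.survival.loc[self.X.index]
            if (self.survival["time"] <= 0).any():
                raise InputFormatError("survival times must be positive")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ModelSpec:
    """A named projection + classifier combination."""

    projection: str = "none"
    classifier: str = "svm"
    hyperparams: tuple = ()

    def __post_init__(self) -> None:
        if self.projection not in PROJECTIONS:
            raise ParameterError(f"unknown projection {self.projection!r}; options: {PROJECTIONS}")
        if self.classifier not in CLASSIFIERS:
            raise ParameterError(f"unknown classifier {self.classifier!r}; options: {CLASSIFIERS}")

    @property
    def name(self) -> str:
        return f"{self.projection}+{self.classifier}"


@dataclass
class BiomarkerResult:
    scores: pd.Series  # per-sample mean OOB score in [0, 1]
    oob_counts: pd.Series
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    spec: ModelSpec
    n_boot: int
    seed: int
    n_redraws: int = 0
    oob_fractions: np.ndarray = field(default_factory=lambda: np.array([]))
    flags: list[str] = field(default_factory=list)


def default_grid() -> list[ModelSpec]:
    """The full 4 projections x 4 classifiers grid, in deterministic order."""
    return [
        ModelSpec(projection=p, classifier=c)
        for p, c in itertools.product(PROJECTIONS, ("adaboost", "knn", "rf", "svm"))
    ]


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance columns (population sd; constant cols -> 0)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0, 1.0)
    return (X - mean) / sd


def assemble_features(
    estimates: Sequence[SubtypeEstimate],
    labels: Mapping[str, int],
    mode: str = "raw",
    survival: pd.DataFrame | None = None,
) -> FeatureTable:
    """Build a feature table from subtype estimates.

    ``mode`` selects 5 raw features, 5 sum-normalized features, or both
    (10 columns). Standardization is applied downstream, inside each model
    fit, so bootstrap training bags do not leak test statistics.
    """
    if mode not in ("raw", "normalized", "both"):
        raise ParameterError(f"unknown mode {mode!r}")
    by_id = {e.sample_id: e for e in estimates}
    missing = [s for s in labels if s not in by_id]
    if missing:
        raise InputFormatError(f"labeled sample(s) without estimates: {missing[:5]}")
    rows = {}
    for sample_id in labels:
        e = by_id[sample_id]
        row: dict[str, float] = {}
        if mode in ("raw", "both"):
            row.update({t: e.raw[i] for i, t in enumerate(SUBTYPES)})
        if mode in ("normalized", "both"):
            norm = e.normalized
            if norm is None:
                raise InputFormatError(
                    f"sample {sample_id!r} has zero total estimate; "
                    "normalized features undefined"
                )
            row.update({f"{t}_norm": norm[i] for i, t in enumerate(SUBTYPES)})
        rows[sample_id] = row
    X = pd.DataFrame.from_dict(rows, orient="index")
    y = pd.Series({s: int(v) for s, v in labels.items()}, name="label")
    return FeatureTable(X=X, y=y, survival=survival)


def extract_geneset_features(
    expr: ExpressionMatrix,
    gene_list: Iterable[str],
    labels: Mapping[str, int],
    survival: pd.DataFrame | None = None,
) -> FeatureTable:
    """One log2(CPM+1) feature per listed gene present in the matrix."""
    if expr.unit != "cpm":
        raise InputFormatError("gene-set features expect a CPM matrix")
    genes = list(dict.fromkeys(gene_list))
    present = [g for g in genes if g in expr.data.index]
    absent = [g for g in genes if g not in expr.data.index]
    if not present:
        raise InputFormatError("no listed gene found in the expression matrix")
    if absent:
        logger.warning("%d listed gene(s) absent from matrix: %s", len(absent), absent[:10])
    X = np.log2(expr.data.loc[present].T + 1.0)
    X = X.loc[list(labels)]
    y = pd.Series({s: int(v) for s, v in labels.items()}, name="label")
    return FeatureTable(X=X, y=y, survival=survival)


def _make_pipeline(spec: ModelSpec, n_features: int, random_state: int):
    from sklearn.decomposition import PCA, FastICA, KernelPCA
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    hp = dict(spec.hyperparams)
    n_components = hp.get("n_components", min(n_features, 5))
    steps = [("scale", StandardScaler())]
    if spec.projection == "pca":
        steps.append(("project", PCA(n_components=n_components, random_state=random_state)))
    elif spec.projection == "ica":
        steps.append(
            ("project", FastICA(n_components=n_components, random_state=random_state,
                                max_iter=500, tol=1e-3, whiten="unit-variance"))
        )
    elif spec.projection == "kpca":
        steps.append(
            ("project", KernelPCA(n_components=n_components, kernel="rbf",
                                  random_state=random_state))
        )
    if spec.classifier == "adaboost":
        clf = AdaBoostClassifier(n_estimators=hp.get("n_estimators", 50), random_state=random_state)
    elif spec.classifier == "knn":
        clf = KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    elif spec.classifier == "rf":
        clf = RandomForestClassifier(n_estimators=hp.get("n_estimators", 100), random_state=random_state)
    elif spec.classifier == "svm":
        clf = SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 1.0), random_state=random_state)
    else:  # constant: a no-discrimination null baseline
        clf = DummyClassifier(strategy="uniform", random_state=random_state)
    steps.append(("clf", clf))
    return Pipeline(steps)


def _score_samples(pipeline, X: np.ndarray) -> np.ndarray:
    """Probability-like scores in [0, 1] for the positive class."""
    clf = pipeline.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        proba = pipeline.predict_proba(X)
        positive = list(pipeline.classes_).index(1)
        return proba[:, positive]
    return expit(pipeline.decision_function(X))


def bootstrap_oob_evaluate(
    features: FeatureTable,
    spec: ModelSpec,
    n_boot: int = 200,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BiomarkerResult:
    """Bootstrap out-of-bag cross-validation of one model spec.

    Each iteration draws n samples with replacement, refits the pipeline on
    the bag and scores the out-of-bag samples; per-sample scores are
    averaged over iterations and one ROC/AUC is computed from the means.
    Bags containing a single class are redrawn (counted).
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    y = features.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise InputFormatError("both classes must be present")
    X = features.X.to_numpy(dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    fit_seeds = np.random.SeedSequence(seed).spawn(n_boot)
    score_sum = np.zeros(n)
    score_count = np.zeros(n, dtype=int)
    oob_fractions = np.zeros(n_boot)
    n_redraws = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for it in range(n_boot):
            for _ in range(max_redraws):
                bag = rng.integers(0, n, size=n)
                if len(np.unique(y[bag])) == 2:
                    break
                n_redraws += 1
            else:
                raise InputFormatError("could not draw a two-class bootstrap bag")
            oob = np.setdiff1d(np.arange(n), bag)
            oob_fractions[it] = len(oob) / n
            if len(oob) == 0:
                continue
            rs = int(fit_seeds[it].generate_state(1)[0] % (2**31 - 1))
            pipeline = _make_pipeline(spec, X.shape[1], random_state=rs)
            pipeline.fit(X[bag], y[bag])
            scores = _score_samples(pipeline, X[oob])
            score_sum[oob] += scores
            score_count[oob] += 1
    flags = []
    never_oob = np.where(score_count == 0)[0]
    if len(never_oob):
        flags.append(f"never_oob:{[features.X.index[i] for i in never_oob]}")
        logger.warning("sample(s) never out-of-bag: %s", flags[-1])
    scored = score_count > 0
    mean_scores = np.full(n, np.nan)
    mean_scores[scored] = score_sum[scored] / score_count[scored]
    roc, auc = roc_auc(mean_scores[scored], y[scored])
    return BiomarkerResult(
        scores=pd.Series(mean_scores, index=features.X.index, name="oob_score"),
        oob_counts=pd.Series(score_count, index=features.X.index, name="oob_count"),
        roc=roc,
        auc=auc,
        spec=spec,
        n_boot=n_boot,
        seed=seed,
        n_redraws=n_redraws,
        oob_fractions=oob_fractions,
        flags=flags,
    )


def select_best_model(
    features: FeatureTable,
    grid: Sequence[ModelSpec],
    n_boot: int = 200,
    seed: int = 0,
) -> BiomarkerResult:
    """Evaluate every spec with the same seed and return the highest AUC.

    All specs see identical bootstrap bags (shared seed), so AUCs are
    comparable; ties are broken by grid order.
    """
    if not grid:
        raise ParameterError("model grid is empty")
    best: BiomarkerResult | None = None
    for spec in grid:
        result = bootstrap_oob_evaluate(features, spec, n_boot=n_boot, seed=seed)
        logger.info("grid %s: AUC %.3f", spec.name, result.auc)
        if best is None or result.auc > best.auc:
            best = result
    assert best is not None
    return best


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC with ties counted one half.

    AUC is the probability that a random positive outranks a random
    negative (the Mann-Whitney identity), computed from mid-ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputFormatError("roc_auc requires both classes")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    points = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    i = 0
    while i < len(sorted_scores):
        j = i
        while j < len(sorted_scores) and sorted_scores[j] == sorted_scores[i]:
            tp += int(sorted_labels[j] == 1)
            fp += int(sorted_labels[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos, sorted_scores[i]))
        i = j
    roc = pd.DataFrame(points, columns=["fpr", "tpr", "threshold"])
    return roc, float(auc)


@dataclass
class LogrankOutcome:
    groups: pd.Series  # True = biomarker positive
    statistic: float | None
    p_value: float | None
    km_curves: dict[str, pd.DataFrame]
    flags: list[str] = field(default_factory=list)


def stratify_and_logrank(
    result: BiomarkerResult,
    survival: pd.DataFrame,
    threshold: float = 0.5,
) -> LogrankOutcome:
    """Threshold mean OOB scores and compare survival between the groups.

    A sample is biomarker-positive iff its mean OOB score >= threshold.
    Returns the two-group log-rank chi-square statistic, its p-value and
    right-censored Kaplan-Meier estimates per group; a single-group
    stratification is flagged instead of tested.
    """
    scores = result.scores.dropna()
    survival = survival.loc[scores.index]
    positive = scores >= threshold
    flags: list[str] = []
    km_curves: dict[str, pd.DataFrame] = {}
    for name, mask in (("positive", positive), ("negative", ~positive)):
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(
            survival.loc[mask, "time"],
            survival.loc[mask, "event"],
            label=name,
        )
        km_curves[name] = kmf.survival_function_
    if positive.all() or (~positive).all():
        flags.append("single_group")
        logger.warning("stratification produced a single group; log-rank not run")
        return LogrankOutcome(groups=positive, statistic=None, p_value=None,
                              km_curves=km_curves, flags=flags)
    test = logrank_test(
        survival.loc[positive, "time"],
        survival.loc[~positive, "time"],
        event_observed_A=survival.loc[positive, "event"],
        event_observed_B=survival.loc[~positive, "event"],
    )
    return LogrankOutcome(
        groups=positive,
        statistic=float(test.test_statistic),
        p_value=float(test.p_value),
        km_curves=km_curves,
        flags=flags,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a: pairs where a > b, ties counted one half."""
    return float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())


def mann_whitney_one_sided(
    a: Sequence[float], b: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test.

    Exact permutation p-value by full enumeration when the pooled size is
    at most 12 (handles ties); normal approximation with tie correction
    otherwise.
    """
    if alternative not in ("greater", "less"):
        raise ParameterError(f"alternative must be greater/less, got {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputFormatError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    n_total = len(a) + len(b)
    if n_total <= EXACT_MW_LIMIT:
        pooled = np.concatenate([a, b])
        indices = range(n_total)
        count = 0
        total = 0
        for combo in itertools.combinations(indices, len(a)):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if alternative == "greater":
                count += u_perm >= u_obs
            else:
                count += u_perm <= u_obs
            total += 1
        return u_obs, count / total
    stat = mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(stat.statistic), float(stat.pvalue)
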