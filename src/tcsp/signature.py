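"""Construction of the five-subtype signature matrix S.

Per subtype, genes are ranked by log2 fold difference of mean CPM versus
all other subtypes' replicates (with a pseudocount), then gated on
within-subtype coefficient of variation and maximum CPM until a target
number of genes is selected. The union of selections, populated with mean
reference CPM per subtype, forms the preliminary model, which is then
filtered against a tumor background panel: genes whose retained-panel mean
CPM, normalized by the per-gene maximum across the five model columns,
reaches the removal threshold are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tcsp.core_io import SUBTYPES, ExpressionMatrix, SignatureModel
from tcsp.errors import ConstructionError, LabelingError, ParameterError

logger = logging.getLogger(__name__)

#: Origin substrings (case-insensitive) identifying immune-derived cell
#: lines that are excluded from the background panel before averaging.
DEFAULT_EXCLUDED_ORIGINS = (
    "haematopoietic",
    "lymphoid",
    "leukemia",
    "lymphoma",
    "myeloma",
)


@dataclass
class ReferenceProfileSet:
    """Replicate CPM profiles, each labeled with one of the five subtypes."""

    matrix: ExpressionMatrix
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.unit != "cpm":
            raise LabelingError("reference matrix must be CPM before model construction")
        unlabeled = [s for s in self.matrix.sample_ids if s not in self.labels]
        if unlabeled:
            raise LabelingError(f"unlabeled sample(s): {unlabeled[:5]}")
        unknown = {t for t in self.labels.values() if t not in SUBTYPES}
        if unknown:
            raise LabelingError(f"unknown subtype label(s): {sorted(unknown)}")
        counts = {t: 0 for t in SUBTYPES}
        for s in self.matrix.sample_ids:
            counts[self.labels[s]] += 1
        short = [t for t, n in counts.items() if n < 2]
        if short:
            raise LabelingError(
                f"subtype(s) with fewer than 2 replicates (CV undefined): {short}"
            )

    def samples_of(self, subtype: str) -> list[str]:
        if subtype not in SUBTYPES:
            raise LabelingError(f"unknown subtype {subtype!r}")
        return [s for s in self.matrix.sample_ids if self.labels[s] == subtype]

    def samples_not_of(self, subtype: str) -> list[str]:
        return [s for s in self.matrix.sample_ids if self.labels[s] != subtype]


@dataclass
class BackgroundPanel:
    """CPM profiles of background (tumor) cell lines with origin labels."""

    matrix: ExpressionMatrix
    origin_labels: dict[str, str] = field(default_factory=dict)

    def retained_lines(self, excluded_origins: Sequence[str]) -> list[str]:
        """Cell lines whose origin matches no excluded substring."""
        needles = [e.lower() for e in excluded_origins]
        kept = []
        for line in self.matrix.sample_ids:
            origin = self.origin_labels.get(line, "").lower()
            if not any(n in origin for n in needles):
                kept.append(line)
        return kept


@dataclass
class GateSelection:
    """Outcome of walking a ranked gene list through the CV/CPM gates."""

    genes: list[str]
    audit: dict[str, dict]


@dataclass
class SignatureParams:
    """All knobs of the end-to-end model construction."""

    pseudocount: float = 1.0
    cv_max: float = 0.25
    cpm_min: float = 15.0
    n_target: int = 10
    background_threshold: float = 0.2
    excluded_origins: tuple[str, ...] = DEFAULT_EXCLUDED_ORIGINS

    def as_dict(self) -> dict:
        return {
            "pseudocount": self.pseudocount,
            "cv_max": self.cv_max,
            "cpm_min": self.cpm_min,
            "n_target": self.n_target,
            "background_threshold": self.background_threshold,
            "excluded_origins": list(self.excluded_origins),
        }


def rank_genes(
    ref: ReferenceProfileSet, subtype: str, pseudocount: float = 1.0
) -> list[tuple[str, float]]:
    """Rank genes by log2 fold difference of the subtype versus the rest.

    fold(g) = log2((mean CPM in subtype + pc) / (mean CPM over all other
    subtypes' samples + pc)). The list is sorted descending; ties are broken
    lexicographically by gene identifier so ranking is deterministic.
    """
    if pseudocount <= 0:
        raise ParameterError(f"pseudocount must be positive, got {pseudocount}")
    own = ref.samples_of(subtype)
    if not own:
        raise LabelingError(f"no samples labeled {subtype!r}")
    rest = ref.samples_not_of(subtype)
    data = ref.matrix.data
    mean_own = data[own].mean(axis=1)
    mean_rest = data[rest].mean(axis=1)
    fold = np.log2((mean_own + pseudocount) / (mean_rest + pseudocount))
    order = sorted(fold.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, float(v)) for g, v in order]


def replicate_cv(values: np.ndarray) -> float:
    """Coefficient of variation (sample sd over mean); inf when mean is 0."""
    mean = float(np.mean(values))
    if mean == 0:
        return math.inf
    return float(np.std(values, ddof=1)) / mean


def gate_genes(
    ranked: Sequence[tuple[str, float]],
    ref: ReferenceProfileSet,
    subtype: str,
    cv_max: float = 0.25,
    cpm_min: float = 15.0,
    n_target: int = 10,
) -> GateSelection:
    """Walk a ranked list, skipping high-CV / low-CPM genes, until n_target.

    A gene is skipped when its within-subtype CV exceeds ``cv_max`` or its
    maximum CPM over the subtype's replicates falls below ``cpm_min``.
    Accepted genes are returned in rank order; the audit records every
    candidate considered with a machine-readable status.
    """
    if n_target < 1:
        raise ParameterError(f"n_target must be >= 1, got {n_target}")
    own = ref.samples_of(subtype)
    data = ref.matrix.data[own]
    selected: list[str] = []
    audit: dict[str, dict] = {}
    for rank, (gene, fold) in enumerate(ranked):
        if len(selected) >= n_target:
            break
        values = data.loc[gene].to_numpy()
        cv = replicate_cv(values)
        max_cpm = float(values.max())
        record = {
            "rank": rank,
            "log2_fold_difference": fold,
            "cv": cv if math.isfinite(cv) else "inf",
            "max_cpm": max_cpm,
        }
        if cv > cv_max:
            record["status"] = "skipped_cv"
        elif max_cpm < cpm_min:
            record["status"] = "skipped_low_cpm"
        else:
            record["status"] = "accepted"
            selected.append(gene)
        audit[gene] = record
    if len(selected) < n_target:
        logger.warning(
            "subtype %s: only %d of %d target genes passed the gates",
            subtype,
            len(selected),
            n_target,
        )
    return GateSelection(genes=selected, audit=audit)


def build_preliminary_model(
    ref: ReferenceProfileSet, selections: Mapping[str, Iterable[str]]
) -> SignatureModel:
    """Assemble the preliminary model from per-subtype gene selections.

    Rows are the union of all selections (first-selection order across the
    canonical subtype sequence); S(g, t) is the mean CPM of gene g over
    subtype t's replicates.
    """
    for t in SUBTYPES:
        if t not in selections or not list(selections[t]):
            raise ConstructionError(f"empty selection for subtype {t!r}")
    genes: list[str] = []
    selected_by: dict[str, list[str]] = {}
    for t in SUBTYPES:
        for g in selections[t]:
            if g not in selected_by:
                selected_by[g] = []
                genes.append(g)
            selected_by[g].append(t)
    if not genes:
        raise ConstructionError("empty gene union")
    columns = {}
    for t in SUBTYPES:
        columns[t] = ref.matrix.data.loc[genes, ref.samples_of(t)].mean(axis=1)
    S = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    provenance = {"selected_by": selected_by, "genes": {g: {"status": "kept"} for g in genes}}
    return SignatureModel(S=S, provenance=provenance)


def filter_background(
    model: SignatureModel,
    panel: BackgroundPanel,
    threshold: float = 0.2,
    excluded_origins: Sequence[str] = DEFAULT_EXCLUDED_ORIGINS,
) -> SignatureModel:
    """Drop model genes that are broadly expressed in the background panel.

    score(g) = mean panel CPM over retained cell lines / max_t S(g, t);
    g is removed iff score(g) >= threshold (inclusive). Genes absent from
    the panel score 0 and are kept (logged).
    """
    if not (threshold > 0 and math.isfinite(threshold)):
        raise ParameterError(f"threshold must be in (0, inf), got {threshold}")
    retained = panel.retained_lines(excluded_origins)
    panel_data = panel.matrix.data[retained]
    row_max = model.S.max(axis=1)
    kept: list[str] = []
    genes_audit = {g: dict(rec) for g, rec in model.provenance.get("genes", {}).items()}
    absent: list[str] = []
    for gene in model.gene_ids:
        if gene in panel_data.index:
            score = float(panel_data.loc[gene].mean()) / float(row_max[gene]) if len(retained) else 0.0
        else:
            score = 0.0
            absent.append(gene)
        rec = genes_audit.setdefault(gene, {})
        rec["background_score"] = score
        if score >= threshold:
            rec["status"] = "removed_background"
        else:
            rec["status"] = "kept"
            kept.append(gene)
    if absent:
        logger.info("%d model gene(s) absent from background panel, kept with score 0: %s",
                    len(absent), absent[:10])
    if not kept:
        raise ConstructionError("background filter removed every gene")
    new_provenance = dict(model.provenance)
    new_provenance["genes"] = genes_audit
    new_provenance["background"] = {
        "threshold": threshold,
        "excluded_origins": list(excluded_origins),
        "retained_cell_lines": len(retained),
        "dropped_cell_lines": panel.matrix.n_samples - len(retained),
    }
    new_params = dict(model.params)
    new_params["background_threshold"] = threshold
    return SignatureModel(S=model.S.loc[kept].copy(), params=new_params, provenance=new_provenance)


def build_shems(
    ref: ReferenceProfileSet,
    panel: BackgroundPanel,
    params: SignatureParams | None = None,
) -> SignatureModel:
    """End-to-end model construction: rank, gate, assemble, filter.

    Deterministic given the inputs and parameters; the returned model's
    provenance records the per-subtype gate audits and per-gene outcomes.
    """
    params = params or SignatureParams()
    selections: dict[str, list[str]] = {}
    gate_audits: dict[str, dict] = {}
    for t in SUBTYPES:
        ranked = rank_genes(ref, t, pseudocount=params.pseudocount)
        sel = gate_genes(
            ranked,
            ref,
            t,
            cv_max=params.cv_max,
            cpm_min=params.cpm_min,
            n_target=params.n_target,
        )
        selections[t] = sel.genes
        gate_audits[t] = sel.audit
    preliminary = build_preliminary_model(ref, selections)
    preliminary.provenance["gates"] = gate_audits
    preliminary.params = params.as_dict()
    model = filter_background(
        preliminary,
        panel,
        threshold=params.background_threshold,
        excluded_origins=params.excluded_origins,
    )
    return model
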