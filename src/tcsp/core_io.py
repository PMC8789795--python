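"""Expression-matrix and signature-model I/O plus CPM normalization.

Tables are tab-separated text with a header row and gene symbols in the
first column (GEO-supplementary style). Gene identifiers are treated as
case-sensitive opaque strings; duplicate gene rows in count tables are
collapsed by summation because raw counts are additive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from tcsp.errors import (
    DegenerateSampleError,
    InputFormatError,
    ModelFormatError,
    UnsupportedVersionError,
)

logger = logging.getLogger(__name__)

#: Canonical subtype column order: naive, activated, exhausted,
#: effector memory, central memory.
SUBTYPES = ("N", "A", "EX", "EM", "CM")

MODEL_FORMAT_VERSION = "1"

_UNITS = ("counts", "cpm")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample non-negative expression table.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Values must be finite and non-negative.
    unit
        Either ``"counts"`` (raw reads) or ``"cpm"`` (counts per million).
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise InputFormatError(f"unknown unit {self.unit!r}; expected one of {_UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputFormatError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise InputFormatError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise InputFormatError("expression values must be finite")
        if values.size and (values < 0).any():
            gene = self.data.index[np.where(values < 0)[0][0]]
            raise InputFormatError(f"negative expression value at gene {gene!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)].copy(), self.unit)


@dataclass
class SignatureModel:
    """The signature matrix S: selected genes by five subtype columns.

    ``S`` holds mean reference CPM per (gene, subtype); ``params`` records
    the filter parameters the model was built with, and ``provenance`` keeps
    a per-gene audit trail (rank value, CV, max CPM, background score,
    kept/removed reason).
    """

    S: pd.DataFrame
    params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [t for t in SUBTYPES if t not in self.S.columns]
        if missing:
            raise ModelFormatError(f"model missing subtype columns: {missing}")
        self.S = self.S[list(SUBTYPES)].astype(float)
        if self.S.index.has_duplicates:
            raise ModelFormatError("duplicate genes in signature model")
        values = self.S.to_numpy()
        if not np.isfinite(values).all() or (values < 0).any():
            raise ModelFormatError("signature entries must be finite and non-negative")
        if values.size and (values.max(axis=1) <= 0).any():
            bad = self.S.index[values.max(axis=1) <= 0].tolist()
            raise ModelFormatError(f"all-zero signature rows: {bad[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.S.index)

    @property
    def n_genes(self) -> int:
        return self.S.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureModel):
            return NotImplemented
        return (
            self.S.index.equals(other.S.index)
            and bool(np.array_equal(self.S.to_numpy(), other.S.to_numpy()))
            and self.params == other.params
            and self.provenance == other.provenance
        )


def read_counts_table(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    """Read a gene-by-sample raw count table.

    The first column holds gene identifiers; all remaining columns must be
    numeric. Duplicate gene rows are collapsed by summation with a logged
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise InputFormatError(f"could not parse {path}: {exc}") from exc
    if frame.empty or frame.shape[1] == 0:
        raise InputFormatError(f"empty count table: {path}")
    non_numeric = frame.columns[
        [not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
        where = f"gene {bad.index[0]!r}" if len(bad) else f"column {col!r}"
        raise InputFormatError(f"non-numeric value in column {col!r} at {where} of {path}")
    if frame.isna().to_numpy().any():
        gene = frame.index[frame.isna().any(axis=1)][0]
        raise InputFormatError(f"missing value at gene {gene!r} in {path}")
    if (frame.to_numpy() < 0).any():
        gene = frame.index[(frame < 0).any(axis=1)][0]
        raise InputFormatError(f"negative count at gene {gene!r} in {path}")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        logger.warning(
            "collapsing %d duplicate gene row(s) by sum: %s", len(dups), dups[:10]
        )
        frame = frame.groupby(level=0, sort=False).sum()
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(frame.astype(float), unit="counts")


def write_matrix(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as TSV with gene identifiers in the first column."""
    out = m.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=sep, float_format="%.17g")


def compute_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a count matrix to counts per million.

    ``cpm(g, s) = count(g, s) / total(s) * 1e6``; every column of the result
    sums to 1e6. An all-zero sample column is a degenerate sample.
    """
    if m.unit != "counts":
        raise InputFormatError(f"compute_cpm expects counts, got unit={m.unit!r}")
    totals = m.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with zero total counts: {list(zero.index)[:5]}"
        )
    cpm = m.data.div(totals, axis=1) * 1e6
    return ExpressionMatrix(cpm, unit="cpm")


def write_model(model: SignatureModel, path: str | Path) -> None:
    """Write a signature model as headered TSV.

    Header lines (``#key<TAB>value``) record the format version, the filter
    parameters and the per-gene provenance as JSON; the body is a gene
    column followed by the five subtype columns. Numeric values are written
    with 17 significant digits so the round trip is lossless.
    """
    path = Path(path)
    lines = [
        f"#tcsp-model\t{MODEL_FORMAT_VERSION}",
        f"#params\t{json.dumps(model.params, sort_keys=True)}",
        f"#provenance\t{json.dumps(model.provenance, sort_keys=True)}",
        "gene\t" + "\t".join(SUBTYPES),
    ]
    for gene, row in model.S.iterrows():
        lines.append(gene + "\t" + "\t".join(format(v, ".17g") for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> SignatureModel:
    """Read a signature model written by :func:`write_model`."""
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"no such file: {path}")
    header: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            header[key] = value
        elif line.strip():
            body.append(line)
    version = header.get("tcsp-model")
    if version is None:
        raise ModelFormatError(f"{path} is not a tcsp model file (missing version header)")
    if version != MODEL_FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"unsupported model format version {version!r} (this build reads "
            f"version {MODEL_FORMAT_VERSION!r})"
        )
    if not body:
        raise ModelFormatError(f"model file {path} has no table body")
    columns = body[0].split("\t")
    if columns[0] != "gene":
        raise ModelFormatError(f"model table must start with a 'gene' column, got {columns[0]!r}")
    missing = [t for t in SUBTYPES if t not in columns[1:]]
    if missing:
        raise ModelFormatError(f"model file missing subtype column(s): {missing}")
    records = []
    for line in body[1:]:
        parts = line.split("\t")
        if len(parts) != len(columns):
            raise ModelFormatError(f"ragged model row: {line[:60]!r}")
        records.append(parts)
    frame = pd.DataFrame(records, columns=columns).set_index("gene")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ModelFormatError(f"non-numeric model entry in {path}: {exc}") from exc
    params = json.loads(header.get("params", "{}"))
    provenance = json.loads(header.get("provenance", "{}"))
    return SignatureModel(S=frame, params=params, provenance=provenance)


def read_labels(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column (sample_id, subtype) label table without header."""
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, header=None, names=["sample_id", "subtype"], dtype=str)
    labels: Mapping[str, str] = dict(zip(frame["sample_id"], frame["subtype"]))
    return dict(labels)
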