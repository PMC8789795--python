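import numpy as np
import pandas as pd
import pytest

from tcsp.core_io import SUBTYPES, ExpressionMatrix
from tcsp.signature import ReferenceProfileSet, SignatureParams, build_shems
from tcsp.synthesis import SynthesisConfig, generate_background, generate_reference


def make_reference(gene_values: dict[str, dict[str, list[float]]]) -> ReferenceProfileSet:
    """Build a small CPM reference from gene -> subtype -> replicate values.

    Every subtype must appear with the same replicate count in every gene.
    """
    columns: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    for gene, per_subtype in gene_values.items():
        for subtype, values in per_subtype.items():
            for i, v in enumerate(values):
                sample = f"{subtype}{i + 1}"
                labels[sample] = subtype
                columns.setdefault(sample, {})[gene] = float(v)
    frame = pd.DataFrame(columns).loc[list(gene_values)]
    matrix = ExpressionMatrix(frame, unit="cpm")
    return ReferenceProfileSet(matrix=matrix, labels=labels)


def flat_reference(genes: dict[str, float], n_rep: int = 2) -> dict[str, dict[str, list[float]]]:
    """gene -> constant value across all subtypes and replicates."""
    return {
        g: {t: [v] * n_rep for t in SUBTYPES} for g, v in genes.items()
    }


@pytest.fixture(scope="session")
def synth_cfg() -> SynthesisConfig:
    # low dispersion so planted markers pass the CV <= 0.25 gate
    return SynthesisConfig(seed=7, n_genes=550, markers_per_subtype=10,
                           marker_fold=8.0, dispersion=0.005, depth=1_000_000)


@pytest.fixture(scope="session")
def synth_reference(synth_cfg):
    return generate_reference(synth_cfg)


@pytest.fixture(scope="session")
def synth_background(synth_cfg):
    return generate_background(synth_cfg)


@pytest.fixture(scope="session")
def synth_model(synth_reference, synth_background):
    return build_shems(synth_reference.reference, synth_background.panel, SignatureParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
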