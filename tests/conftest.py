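import numpy as np
import pandas as pd
import pytest

from cernapipe.config import RunConfig, SimulationConfig
from cernapipe import simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced but fully structured study: fast enough for per-test reuse."""
    return SimulationConfig(
        seed=11,
        n_coding_genes=20,
        n_novel_transcripts=60,
        n_lncRNA=60,
        n_mRNA=80,
        n_miRNA=60,
        n_planted_triplets=6,
        n_decoy_pairs=8,
    )


@pytest.fixture(scope="session")
def small_run_config(small_config) -> RunConfig:
    return RunConfig(seed=11, simulation=small_config)


@pytest.fixture(scope="session")
def small_expression(small_config):
    return simulate.simulate_expression(small_config)


@pytest.fixture(scope="session")
def small_targets(small_config, small_expression):
    return simulate.simulate_targets(small_config, small_expression.ground_truth)


def make_transcript(tid, exons, strand="+", chrom="chr1", gene=None, biotype="novel"):
    from cernapipe.models import TranscriptModel

    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid,
        chrom=chrom,
        strand=strand,
        exons=list(exons),
        biotype=biotype,
    )


@pytest.fixture
def make_counts():
    def _make(values, features=None, samples=None):
        values = np.asarray(values)
        features = features or [f"f{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        return pd.DataFrame(values, index=features, columns=samples)

    return _make
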