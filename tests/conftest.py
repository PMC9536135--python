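import numpy as np
import pandas as pd
import pytest

from pathstrat import ExpressionMatrix, GeneSet, GeneSetCollection, SimulationConfig, simulate_bulk


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 3 samples with simple integer values."""
    return ExpressionMatrix(
        values=pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 4.0, 4.0], [0.0, 1.0, 2.0]],
            index=["GA", "GB", "GC"],
            columns=["s1", "s2", "s3"],
        )
    )


@pytest.fixture
def gene_set_factory():
    def make(name: str, genes) -> GeneSet:
        return GeneSet(name=name, description="test", genes=tuple(genes))

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """A small 2-cluster cohort with strong planted structure (session-cached)."""
    cfg = SimulationConfig(
        n_genes=600,
        n_samples=30,
        k_clusters=2,
        programs_per_cluster=6,
        program_size=40,
        effect=2.0,
        noise_sd=1.0,
        hazard_by_cluster=(0.04, 0.10),
        censor_rate=0.2,
        seed=101,
        n_decoys=20,
    )
    return simulate_bulk(cfg)


@pytest.fixture
def gmt_file(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("S1\tdesc\tTP53\tE2F1\nS2\tna\tMYC\tE2F1\tSOX2\n")
    return p
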