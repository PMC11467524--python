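import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import survfit as sf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_count_table(strains, counts, samples):
    """Build a CountTable from plain dict/list literals (test convenience)."""
    strain_df = pd.DataFrame(strains).set_index("barcode")
    count_df = pd.DataFrame(counts, index=strain_df.index)
    sample_df = pd.DataFrame(samples).set_index("sample_id")
    return sf.CountTable(strains=strain_df, counts=count_df, samples=sample_df)


@pytest.fixture
def small_library():
    design = sf.LibraryDesign(
        n_genes=20, strains_per_gene_mean=5, strains_per_gene_dispersion=2.0
    )
    return sf.simulate_library(design, seed=11)


@pytest.fixture
def toy_matrix():
    """5 genomes x 8 clusters with a known prevalence spectrum."""
    data = {
        "cluster_id": [f"c{i}" for i in range(8)],
        "g1": [1, 1, 1, 1, 0, 1, 0, 0],
        "g2": [1, 1, 1, 0, 1, 0, 0, 0],
        "g3": [1, 1, 0, 1, 0, 0, 1, 0],
        "g4": [1, 1, 1, 0, 0, 0, 0, 1],
        "g5": [1, 1, 0, 1, 1, 0, 0, 0],
    }
    return pd.DataFrame(data).set_index("cluster_id")


@pytest.fixture
def null_experiment():
    """Deep-coverage simulation with every effect zero."""
    design = sf.LibraryDesign(
        n_genes=50, strains_per_gene_mean=8, strains_per_gene_dispersion=None
    )
    library = sf.simulate_library(design, seed=5)
    effects = sf.EffectModel.null(sorted(library["gene_id"].unique()))
    seq = sf.SequencingModel(depth=1_000_000, replicates=3, reference_samples=6)
    table = sf.simulate_survival_experiment(
        library, effects, [1.0], seq=seq, axis="time_h", seed=6
    )
    return library, table
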