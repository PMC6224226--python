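import numpy as np
import pandas as pd
import pytest

from epiclock import preprocess, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic methylome dataset shared across tests."""
    cfg = simulate.SyntheticConfig(
        n_samples=60, n_sites=800, n_age_sites=40, seed=11
    )
    tables, metadata, truth, conserved = simulate.simulate_methylomes(cfg)
    return cfg, tables, metadata, truth, conserved


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    """The small dataset run through the full preprocessing pipeline."""
    _, tables, metadata, _, _ = small_sim
    pooled = {s: preprocess.pool_strands(t) for s, t in tables.items()}
    matrix, manifest = preprocess.build_matrix(
        pooled, metadata, preprocess.BuildConfig(min_sites=100)
    )
    return matrix, manifest


def make_counts(rows):
    """Native-dialect record frame from (chrom, pos, strand, meth, total) rows."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "total"])


def make_table(entries):
    """Pooled count table from {(chrom, pos): (meth, total)}."""
    idx = pd.MultiIndex.from_tuples(list(entries), names=["chrom", "pos"])
    vals = np.array(list(entries.values()), dtype=int)
    return pd.DataFrame({"meth": vals[:, 0], "total": vals[:, 1]}, index=idx)
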