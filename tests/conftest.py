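import numpy as np
import pandas as pd
import pytest

import stresswaves as sw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """300 genes, 5% induced / 5% shut down, driven by 10 TFs."""
    return sw.sample_gene_population(
        n_genes=300,
        tfs=[f"TF{i}" for i in range(10)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bulk(small_population):
    design = sw.CourseDesign(n_replicates=3, library_size=2e6, seed=11)
    return sw.simulate_bulk_counts(design, small_population)


@pytest.fixture(scope="session")
def read_sim(small_population):
    """Gene models + simulated reads for 60 genes at the 45-min state."""
    genes = small_population[:60]
    models = sw.sample_gene_models([g.gene_id for g in genes], seed=21)
    abund = {}
    for g in genes:
        u, s = sw.simulate_kinetics(g, [0.75])
        abund[g.gene_id] = (float(u[0]), float(s[0]))
    records, truth = sw.simulate_reads(models, abund, n_reads=8000, seed=22)
    return models, abund, records, truth


@pytest.fixture(scope="session")
def phospho_sim():
    spec = sw.PhosphoSimSpec(n_peptides=1500, seed=31)
    return sw.simulate_phospho(spec)


def make_profiles(n_per_cluster, centers, noise_sd, seed, n_cols=10):
    """Planted profile matrix: len(centers) clusters of smooth curves."""
    r = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_cols)
    rows, labels = [], []
    for ci, c in enumerate(centers):
        base = c(t)
        for _ in range(n_per_cluster):
            rows.append(base + r.normal(0, noise_sd, n_cols))
            labels.append(ci)
    idx = [f"f{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.array(labels)
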