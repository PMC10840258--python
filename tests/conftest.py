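import numpy as np
import pandas as pd
import pytest

from nichelda import (LdaHyperparams, associate_niches, blocked_phi, fit_lda,
                      match_subcommunities, simulate_dataset,
                      simulate_linked_niches)
from nichelda.tables_io import OtuTable


def make_meta(table, niche):
    """Metadata frame where each sample is its own subject."""
    return pd.DataFrame({
        "sample_id": table.sample_ids,
        "subject_id": table.sample_ids,
        "niche": niche,
    })


@pytest.fixture(scope="session")
def recovery_study():
    """K=5 parameter-recovery study: well-separated (disjoint-support)
    sub-communities, S=300 samples at depth 2000, sparse-composition prior."""
    phi = blocked_phi(5, 300, seed=11, background=0.0)
    sim = simulate_dataset(5, 300, 300, 2000, alpha=1.0, gamma=0.1, seed=1,
                           phi=phi)
    fit = fit_lda(sim.table, 5, LdaHyperparams(gamma=0.001, n_iterations=400,
                                               burn_in=200, seed=2023))
    perm = match_subcommunities(fit.phi, sim.true_phi)
    return sim, fit, perm


@pytest.fixture(scope="session")
def two_block_study():
    """K=2 disjoint OTU blocks, S=200 at depth 1000."""
    phi = blocked_phi(2, 100, seed=3, background=0.0)
    sim = simulate_dataset(2, 100, 200, 1000, alpha=1.0, gamma=0.1, seed=4,
                           phi=phi)
    fit = fit_lda(sim.table, 2, LdaHyperparams(gamma=0.01, n_iterations=300,
                                               burn_in=150, seed=2022))
    perm = match_subcommunities(fit.phi, sim.true_phi)
    return sim, fit, perm


@pytest.fixture(scope="session")
def linked_strong_assoc():
    """Strongly coupled two-niche fixture and its association analysis."""
    sim_a, sim_b = simulate_linked_niches(S=80, V=120, depth=600, effect=8.0,
                                          seed=5)
    tables = {
        "A": (sim_a.table, make_meta(sim_a.table, "A")),
        "B": (sim_b.table, make_meta(sim_b.table, "B")),
    }
    hyper = LdaHyperparams(n_iterations=300, burn_in=150, seed=2022)
    assoc = associate_niches(tables, {"A": 2, "B": 2}, hyper, n_perm=1000,
                             seed=7)
    return sim_a, sim_b, assoc


@pytest.fixture
def toy_table():
    counts = np.array([[5, 0], [0, 7], [1, 1]])
    return OtuTable(counts, ["s1", "s2", "s3"], ["o1", "o2"])
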