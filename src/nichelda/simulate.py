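"""Synthetic OTU tables from the LDA generative process, with ground truth.

The generative model: each sub-community k has a composition
phi_k ~ Dirichlet(gamma * 1_V) shared by all samples; each sample s has
mixing proportions theta_s ~ Dirichlet(alpha * 1_K); each of its reads picks
a sub-community z ~ Multinomial(theta_s) and then an OTU w ~
Multinomial(phi_z).  Marginally a sample's reads are a single multinomial
draw from theta_s @ Phi, which is how counts are generated here (identical
in distribution, much faster); per-read sub-community labels can be
reconstructed on demand from their exact posterior.

Also provides the label-switching resolver (optimal assignment on cosine
similarity) and a two-niche fixture with tunable between-niche coupling for
exercising the association pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tables_io import OtuTable

__all__ = [
    "SimulatedDataset",
    "simulate_dataset",
    "blocked_phi",
    "reconstruct_assignments",
    "simulate_linked_niches",
    "match_subcommunities",
]


@dataclass
class SimulatedDataset:
    """A simulated OTU table together with its generative ground truth."""

    table: OtuTable
    true_theta: np.ndarray  # (S, K), row-stochastic
    true_phi: np.ndarray    # (K, V), row-stochastic
    K: int
    V: int
    S: int
    depth: int
    alpha: float
    gamma: float
    seed: int


def _check_dims(K: int, V: int, S: int, depth: int) -> None:
    for name, val in (("K", K), ("V", V), ("S", S), ("depth", depth)):
        if int(val) < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")


def blocked_phi(
    K: int,
    V: int,
    seed: int,
    within_alpha: float = 1.0,
    background: float = 0.1,
) -> np.ndarray:
    """Well-separated sub-community compositions.

    OTUs are split into K contiguous blocks; component k puts mass
    ``1 - background`` on block k (within-block proportions drawn
    Dirichlet(within_alpha)) and spreads ``background`` over all V OTUs as
    a component-specific low-abundance tail — mirroring real communities,
    which pair a handful of dominant taxa with a long rare tail.  With
    ``background = 0`` the supports are fully disjoint.
    """
    if V < K:
        raise ValueError("need V >= K for blocked compositions")
    if not 0 <= background < 1:
        raise ValueError("background must be in [0, 1)")
    rng = np.random.default_rng(seed)
    phi = np.zeros((K, V))
    bounds = np.linspace(0, V, K + 1).astype(int)
    for k in range(K):
        lo, hi = bounds[k], bounds[k + 1]
        phi[k, lo:hi] = rng.dirichlet(np.full(hi - lo, within_alpha))
        if background > 0:
            phi[k] = (1 - background) * phi[k] + background * rng.dirichlet(np.ones(V))
    return phi


def simulate_dataset(
    K: int,
    V: int,
    S: int,
    depth: int,
    alpha: float,
    gamma: float,
    seed: int,
    phi: np.ndarray | None = None,
) -> SimulatedDataset:
    """Draw an OTU table from the generative process.

    ``phi`` overrides the Dirichlet(gamma) draw of component compositions
    (e.g. with :func:`blocked_phi`); theta is always drawn per sample.
    """
    _check_dims(K, V, S, depth)
    if alpha <= 0 or gamma <= 0:
        raise ValueError("alpha and gamma must be positive")
    rng = np.random.default_rng(seed)
    if phi is None:
        phi = rng.dirichlet(np.full(V, gamma), size=K)
    else:
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (K, V):
            raise ValueError(f"phi override has shape {phi.shape}, expected {(K, V)}")
    theta = rng.dirichlet(np.full(K, alpha), size=S)
    mixed = theta @ phi
    # guard against tiny negative round-off before the multinomial draw
    mixed = np.clip(mixed, 0.0, None)
    mixed /= mixed.sum(axis=1, keepdims=True)
    counts = np.empty((S, V), dtype=np.int64)
    for s in range(S):
        counts[s] = rng.multinomial(depth, mixed[s])
    table = OtuTable(
        counts,
        [f"sample{s:05d}" for s in range(S)],
        [f"otu{v:05d}" for v in range(V)],
    )
    return SimulatedDataset(table, theta, phi, K, V, S, depth, alpha, gamma, seed)


def reconstruct_assignments(sim: SimulatedDataset, seed: int) -> np.ndarray:
    """Sample per-(sample, sub-community) read counts n_{s,k}.

    Given observed counts and the latent (theta, phi), the reads of OTU v in
    sample s carry sub-community labels that are iid categorical with
    probability proportional to theta_{s,k} * phi_{k,v}; this draws one such
    labelling and returns the (S, K) count matrix.
    """
    rng = np.random.default_rng(seed)
    S, K = sim.true_theta.shape
    n_sk = np.zeros((S, K), dtype=np.int64)
    for s in range(S):
        weights = sim.true_theta[s][:, None] * sim.true_phi  # (K, V)
        for v in np.flatnonzero(sim.table.counts[s]):
            p = weights[:, v]
            p = p / p.sum()
            n_sk[s] += rng.multinomial(sim.table.counts[s, v], p)
    return n_sk


def simulate_linked_niches(
    S: int,
    V: int,
    depth: int,
    effect: float,
    seed: int,
    K: int = 2,
    gamma: float = 0.1,
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Two niches with logistic-normally coupled sub-community proportions.

    Each niche has its own compositions (blocked, hence well separated).
    With ``effect == 0`` the two niches' theta are independent Dirichlet(1)
    draws; with ``effect > 0`` both niches share a per-subject Gaussian
    score eta_i, perturbed by independent noise of scale ``1/effect``, and
    theta = softmax(eta + noise) — large effect means matched components
    are nearly identical across niches.  Sample ids are subject ids, shared
    between the two tables.  This is a test fixture for the association
    pipeline, not a biological model.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    phis = [blocked_phi(K, V, seed=int(rng.integers(2**31))) for _ in range(2)]
    if effect == 0:
        thetas = [rng.dirichlet(np.ones(K), size=S) for _ in range(2)]
    else:
        eta = rng.normal(0.0, 1.5, size=(S, K))
        thetas = []
        for _ in range(2):
            noisy = eta + rng.normal(0.0, 1.0 / effect, size=(S, K))
            e = np.exp(noisy - noisy.max(axis=1, keepdims=True))
            thetas.append(e / e.sum(axis=1, keepdims=True))
    out = []
    for niche in range(2):
        mixed = thetas[niche] @ phis[niche]
        mixed /= mixed.sum(axis=1, keepdims=True)
        counts = np.empty((S, V), dtype=np.int64)
        for s in range(S):
            counts[s] = rng.multinomial(depth, mixed[s])
        table = OtuTable(
            counts,
            [f"subj{s:05d}" for s in range(S)],
            [f"otu{v:05d}" for v in range(V)],
        )
        out.append(
            SimulatedDataset(table, thetas[niche], phis[niche], K, V, S, depth,
                             1.0, gamma, seed)
        )
    return out[0], out[1]


def match_subcommunities(est_phi: np.ndarray, true_phi: np.ndarray) -> np.ndarray:
    """Resolve label switching between two composition matrices.

    Returns the permutation ``perm`` maximizing the total cosine similarity
    between ``est_phi[perm[k]]`` and ``true_phi[k]``, found by optimal
    assignment; deterministic.
    """
    est_phi = np.asarray(est_phi, dtype=float)
    true_phi = np.asarray(true_phi, dtype=float)
    if est_phi.shape != true_phi.shape:
        raise ValueError(f"shape mismatch: {est_phi.shape} vs {true_phi.shape}")
    en = est_phi / np.maximum(np.linalg.norm(est_phi, axis=1, keepdims=True), 1e-300)
    tn = true_phi / np.maximum(np.linalg.norm(true_phi, axis=1, keepdims=True), 1e-300)
    sim = tn @ en.T  # sim[k, j] = cos(true_k, est_j)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(est_phi.shape[0], dtype=int)
    perm[rows] = cols
    return perm
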