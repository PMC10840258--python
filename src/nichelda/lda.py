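"""Latent Dirichlet allocation for OTU tables via collapsed Gibbs sampling.

Each sample s is modelled as a mixture over K latent sub-communities with
proportions theta_s, and each sub-community k as a distribution phi_k over
the V OTUs.  Integrating theta and phi out, the sampler resamples each
read's sub-community label z from

    p(z = k | rest)  ∝  (n_sk + alpha) (n_kv + gamma) / (n_k. + V gamma),

where the n's are label counts excluding the current read.  Point estimates
are the usual posterior means from the final state,

    theta_sk = (n_sk + alpha) / (N_s + K alpha),
    phi_kv   = (n_kv + gamma) / (n_k. + V gamma),

optionally averaged over post-burn-in sweeps.  Sub-community indices are
arbitrary (label switching); compare runs through
``simulate.match_subcommunities``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .tables_io import OtuTable, taxon_labels

__all__ = [
    "LdaHyperparams",
    "LdaFit",
    "fit_lda",
    "infer_theta",
    "top_taxa",
    "dominance_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class LdaHyperparams:
    """Gibbs sampler settings.

    ``alpha`` is the symmetric Dirichlet prior weight on sub-communities per
    sample (``None`` resolves to the conventional 50/K at fit time) and
    ``gamma`` the prior weight on OTUs per sub-community.  Estimates come
    from the final sweep unless ``average_after_burn_in`` is set.
    """

    alpha: float | None = None
    gamma: float = 0.1
    n_iterations: int = 2000
    burn_in: int = 1000
    seed: int = 2022
    average_after_burn_in: bool = False

    def resolve(self, K: int) -> "LdaHyperparams":
        alpha = 50.0 / K if self.alpha is None else float(self.alpha)
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_iterations < 1 or not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        return LdaHyperparams(alpha, self.gamma, self.n_iterations,
                              self.burn_in, self.seed, self.average_after_burn_in)


@dataclass
class LdaFit:
    """A fitted sub-community model."""

    K: int
    theta: np.ndarray          # (S, K) row-stochastic
    phi: np.ndarray            # (K, V) row-stochastic
    n_sk: np.ndarray           # (S, K) final-state label counts
    n_kv: np.ndarray           # (K, V)
    hyper: LdaHyperparams
    loglik_trace: np.ndarray   # complete-data log joint per sweep
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: list[str] | None = None

    def theta_frame(self) -> pd.DataFrame:
        cols = [f"subcommunity_{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.theta, index=self.sample_ids, columns=cols)

    def phi_frame(self) -> pd.DataFrame:
        idx = [f"subcommunity_{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.phi, index=idx, columns=self.otu_ids)


# ---------------------------------------------------------------------------
# Numba kernels.  All randomness below uses numba's own RNG, seeded once per
# fit, so a (seed, data, K) triple gives a bit-identical chain.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _nb_init(doc, word, K, z, n_sk, n_kv, n_k):
    for t in range(doc.size):
        k = np.random.randint(0, K)
        z[t] = k
        n_sk[doc[t], k] += 1
        n_kv[k, word[t]] += 1
        n_k[k] += 1


@njit(cache=True)
def _nb_sweep(doc, word, z, n_sk, n_kv, n_k, alpha, gamma, vgamma, cum):
    K = n_k.size
    for t in range(doc.size):
        s = doc[t]
        v = word[t]
        k = z[t]
        n_sk[s, k] -= 1
        n_kv[k, v] -= 1
        n_k[k] -= 1
        total = 0.0
        for kk in range(K):
            total += (n_sk[s, kk] + alpha) * (n_kv[kk, v] + gamma) / (n_k[kk] + vgamma)
            cum[kk] = total
        u = np.random.random() * total
        k = 0
        while k < K - 1 and cum[k] < u:
            k += 1
        z[t] = k
        n_sk[s, k] += 1
        n_kv[k, v] += 1
        n_k[k] += 1


@njit(cache=True)
def _nb_sweep_fixed_phi(doc, word, z, n_sk, phi, alpha, cum):
    # holdout inference: phi frozen, only the per-sample mixing resampled
    K = phi.shape[0]
    for t in range(doc.size):
        s = doc[t]
        v = word[t]
        k = z[t]
        n_sk[s, k] -= 1
        total = 0.0
        for kk in range(K):
            total += (n_sk[s, kk] + alpha) * phi[kk, v]
            cum[kk] = total
        u = np.random.random() * total
        k = 0
        while k < K - 1 and cum[k] < u:
            k += 1
        z[t] = k
        n_sk[s, k] += 1


def _tokens(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s_idx, v_idx = np.nonzero(counts)
    reps = counts[s_idx, v_idx]
    doc = np.repeat(s_idx, reps).astype(np.int32)
    word = np.repeat(v_idx, reps).astype(np.int32)
    return doc, word


def _joint_loglik(n_sk, n_kv, n_k, depths, alpha, gamma) -> float:
    """Collapsed log p(w, z | alpha, gamma), up to no constants dropped."""
    S, K = n_sk.shape
    V = n_kv.shape[1]
    ll = K * (gammaln(V * gamma) - V * gammaln(gamma))
    ll += np.sum(gammaln(n_kv + gamma)) - np.sum(gammaln(n_k + V * gamma))
    ll += S * (gammaln(K * alpha) - K * gammaln(alpha))
    ll += np.sum(gammaln(n_sk + alpha)) - np.sum(gammaln(depths + K * alpha))
    return float(ll)


def fit_lda(table: OtuTable, K: int, hyper: LdaHyperparams | None = None) -> LdaFit:
    """Fit a K-sub-community model by collapsed Gibbs sampling."""
    if K < 1:
        raise ValueError("K must be >= 1")
    hyper = (hyper or LdaHyperparams()).resolve(K)
    depths = table.depths()
    if np.any(depths == 0):
        empty = [table.sample_ids[i] for i in np.flatnonzero(depths == 0)]
        raise ValueError(f"samples with zero reads: {empty[:5]}")
    S, V = table.counts.shape
    doc, word = _tokens(table.counts)
    z = np.empty(doc.size, dtype=np.int32)
    n_sk = np.zeros((S, K), dtype=np.int64)
    n_kv = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    cum = np.empty(K, dtype=np.float64)
    _nb_seed(int(hyper.seed) & 0x7FFFFFFF)
    _nb_init(doc, word, K, z, n_sk, n_kv, n_k)
    alpha, gamma = hyper.alpha, hyper.gamma
    trace = np.empty(hyper.n_iterations)
    theta_acc = np.zeros((S, K)) if hyper.average_after_burn_in else None
    phi_acc = np.zeros((K, V)) if hyper.average_after_burn_in else None
    for it in range(hyper.n_iterations):
        _nb_sweep(doc, word, z, n_sk, n_kv, n_k, alpha, gamma, V * gamma, cum)
        trace[it] = _joint_loglik(n_sk, n_kv, n_k, depths, alpha, gamma)
        if theta_acc is not None and it >= hyper.burn_in:
            theta_acc += (n_sk + alpha) / (depths[:, None] + K * alpha)
            phi_acc += (n_kv + gamma) / (n_k[:, None] + V * gamma)
        if (it + 1) % 200 == 0:
            logger.debug("gibbs sweep %d/%d loglik=%.1f", it + 1,
                         hyper.n_iterations, trace[it])
    if theta_acc is not None:
        draws = hyper.n_iterations - hyper.burn_in
        theta, phi = theta_acc / draws, phi_acc / draws
    else:
        theta = (n_sk + alpha) / (depths[:, None] + K * alpha)
        phi = (n_kv + gamma) / (n_k[:, None] + V * gamma)
    return LdaFit(K, theta, phi, n_sk, n_kv, hyper, trace,
                  list(table.sample_ids), list(table.otu_ids),
                  None if table.taxonomy is None else list(table.taxonomy))


def infer_theta(
    fit: LdaFit,
    new_table: OtuTable,
    n_iterations: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Infer mixing proportions for new samples with phi frozen.

    New OTU columns are matched to the fit's by id; columns absent from the
    fit are ignored, and an empty overlap is an error.
    """
    col_map = {o: j for j, o in enumerate(fit.otu_ids)}
    pairs = [(i, col_map[o]) for i, o in enumerate(new_table.otu_ids) if o in col_map]
    if not pairs:
        raise ValueError("no overlap between new table's OTUs and the fit's")
    counts = np.zeros((new_table.n_samples, len(fit.otu_ids)), dtype=np.int64)
    for i, j in pairs:
        counts[:, j] = new_table.counts[:, i]
    depths = counts.sum(axis=1)
    if np.any(depths == 0):
        raise ValueError("some new samples have no reads on the fit's OTUs")
    doc, word = _tokens(counts)
    K = fit.K
    alpha = fit.hyper.alpha
    S = counts.shape[0]
    n_sk = np.zeros((S, K), dtype=np.int64)
    z = np.empty(doc.size, dtype=np.int32)
    cum = np.empty(K, dtype=np.float64)
    _nb_seed(int(seed) & 0x7FFFFFFF)
    # initialise from phi alone
    _nb_init(doc, word, K, z, n_sk, np.zeros((K, counts.shape[1]), dtype=np.int64),
             np.zeros(K, dtype=np.int64))
    phi = np.ascontiguousarray(fit.phi)
    for _ in range(n_iterations):
        _nb_sweep_fixed_phi(doc, word, z, n_sk, phi, alpha, cum)
    return (n_sk + alpha) / (depths[:, None] + K * alpha)


def top_taxa(
    fit: LdaFit,
    threshold: float = 0.05,
    rank: str | None = None,
) -> list[list[tuple[str, float]]]:
    """Dominant taxa of each sub-community.

    phi is aggregated to taxon labels (lowest available rank by default);
    taxa with aggregated proportion >= ``threshold`` are returned per
    sub-community, sorted descending.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    labels = taxon_labels(fit.otu_ids, fit.taxonomy, rank=rank)
    frame = pd.DataFrame(fit.phi, columns=labels)
    agg = frame.T.groupby(level=0, sort=True).sum().T
    out: list[list[tuple[str, float]]] = []
    for k in range(fit.K):
        row = agg.iloc[k].sort_values(ascending=False)
        row = row[row >= threshold]
        out.append([(str(name), float(v)) for name, v in row.items()])
    return out


def dominance_summary(
    fit: LdaFit, threshold: float = 0.5
) -> list[tuple[int, float]]:
    """Per sub-community: how many samples it dominates.

    Returns, for each k, the count and percentage of samples with
    theta_{s,k} >= threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    S = fit.theta.shape[0]
    out = []
    for k in range(fit.K):
        n = int(np.sum(fit.theta[:, k] >= threshold))
        out.append((n, 100.0 * n / S))
    return out
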