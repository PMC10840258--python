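"""Between-niche association via sub-community proportions and the global test.

For each niche its samples are decomposed into sub-communities (LDA fitted
on *all* of the niche's samples).  For an ordered niche pair (i, j) the
samples are restricted to subjects present in both niches, the explanatory
matrix is niche j's OTU counts after the arcsinh transform, and each of
niche i's K_i sub-community proportion columns is tested against it with
the global test.  Raw p-values are Bonferroni-multiplied by K_i * m (m =
number of niches, the correction the analysis design prescribes; a strict
mode corrects by the total number of tests instead), capped at 1; a pair is
called significantly associated when its minimum adjusted p-value is <=
alpha_level.  Because proportions within a niche are compositional
(rows of theta sum to one) and the test is invariant to affine response
transforms, sub-communities of one niche tend to stand or fall together.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gtest import global_test
from .lda import LdaFit, LdaHyperparams, fit_lda
from .tables_io import OtuTable, arcsinh_transform, intersect_samples

__all__ = ["AssociationMatrix", "associate_niches", "symmetry_report"]

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Ordered-pair association results between m niches."""

    niches: list[str]
    k_per_niche: dict[str, int]
    raw_p: dict[tuple[str, str], np.ndarray]       # per sub-community of niche i
    adjusted_p: dict[tuple[str, str], np.ndarray]
    min_adjusted: pd.DataFrame                     # m x m, NaN on diagonal
    significant: pd.DataFrame                      # boolean calls
    untestable: list[tuple[str, str]]
    alpha_level: float
    correction: dict[tuple[str, str], float]

    def neg_log10_min_p(self) -> pd.DataFrame:
        """-log10 of the minimum adjusted p per ordered pair (heatmap export)."""
        return -np.log10(self.min_adjusted)


def associate_niches(
    tables: dict[str, tuple[OtuTable, pd.DataFrame]],
    k_per_niche: dict[str, int],
    hyper: LdaHyperparams | None = None,
    alpha_level: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 2022,
    use_relative: bool = False,
    p_source: str = "permutation",
    strict_bonferroni: bool = False,
    fits: dict[str, LdaFit] | None = None,
) -> AssociationMatrix:
    """Run the full pairwise association analysis.

    Parameters
    ----------
    tables
        Mapping niche -> (OtuTable, metadata frame with subject ids).
    k_per_niche
        Number of sub-communities per niche (e.g. from ``kselect.select_k``).
    use_relative
        Apply arcsinh to relative abundances instead of rarefied counts.
    p_source
        "permutation" (default) or "asymptotic" raw p-values.
    strict_bonferroni
        Correct by the total number of tests sum_i K_i * (m - 1) instead of
        the design's K_i * m.
    fits
        Optional pre-computed LDA fits keyed by niche (skips refitting).
    """
    if len(tables) < 2:
        raise ValueError(">= 2 niches required")
    if p_source not in ("permutation", "asymptotic"):
        raise ValueError("p_source must be 'permutation' or 'asymptotic'")
    niches = list(tables)
    m = len(niches)
    hyper = hyper or LdaHyperparams()
    fits = dict(fits or {})
    for niche in niches:
        if niche not in fits:
            table, _ = tables[niche]
            logger.info("fitting LDA for niche %s (K=%d, S=%d)", niche,
                        k_per_niche[niche], table.n_samples)
            fits[niche] = fit_lda(table, k_per_niche[niche], hyper)

    total_tests = sum(k_per_niche[i] * (m - 1) for i in niches)
    raw_p: dict[tuple[str, str], np.ndarray] = {}
    adj_p: dict[tuple[str, str], np.ndarray] = {}
    correction: dict[tuple[str, str], float] = {}
    untestable: list[tuple[str, str]] = []
    min_adj = pd.DataFrame(np.nan, index=niches, columns=niches)
    sig = pd.DataFrame(False, index=niches, columns=niches)

    for i in niches:
        table_i, meta_i = tables[i]
        fit_i = fits[i]
        theta_index = {s: r for r, s in enumerate(fit_i.sample_ids)}
        for j in niches:
            if i == j:
                continue
            table_j, meta_j = tables[j]
            try:
                sub_i, sub_j, _ = intersect_samples(table_i, meta_i, table_j, meta_j)
            except ValueError:
                untestable.append((i, j))
                logger.warning("pair (%s, %s) untestable: no shared subjects", i, j)
                continue
            rows = [theta_index[s] for s in sub_i.sample_ids]
            theta = fit_i.theta[rows]
            Xj = sub_j.relative_abundance() if use_relative else sub_j.counts
            X = arcsinh_transform(Xj)
            K_i = k_per_niche[i]
            factor = float(total_tests if strict_bonferroni else K_i * m)
            pair_seed = (seed + 104729 * (niches.index(i) * m + niches.index(j))) % 2**31
            ps = np.empty(K_i)
            for k in range(K_i):
                res = global_test(theta[:, k], X, n_perm=n_perm, seed=pair_seed,
                                  covariate_names=sub_j.otu_ids)
                ps[k] = res.p_permutation if p_source == "permutation" else res.p_asymptotic
            raw_p[(i, j)] = ps
            adj = np.minimum(ps * factor, 1.0)
            adj_p[(i, j)] = adj
            correction[(i, j)] = factor
            min_adj.loc[i, j] = adj.min()
            sig.loc[i, j] = bool(adj.min() <= alpha_level)
            logger.info("pair (%s -> %s): min adjusted p = %.4g %s", i, j,
                        adj.min(), "***" if sig.loc[i, j] else "")

    return AssociationMatrix(niches, dict(k_per_niche), raw_p, adj_p, min_adj,
                             sig, untestable, alpha_level, correction)


def symmetry_report(assoc: AssociationMatrix) -> list[tuple[str, str]]:
    """Unordered pairs whose (i -> j) and (j -> i) calls disagree.

    An empty list means the significance calls are fully symmetric, the
    behaviour expected when sub-communities capture the OTU-level signal.
    """
    out = []
    for a_idx, i in enumerate(assoc.niches):
        for j in assoc.niches[a_idx + 1:]:
            if (i, j) in assoc.untestable or (j, i) in assoc.untestable:
                continue
            if bool(assoc.significant.loc[i, j]) != bool(assoc.significant.loc[j, i]):
                out.append((i, j))
    return out
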