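"""Nonparametric comparisons and Bray-Curtis dissimilarity.

Mann-Whitney U reports the rank-sum-based W convention (the U statistic of
the first sample, as R's ``wilcox.test`` does).  For small samples without
ties the two-sided p comes from full enumeration of all rank assignments;
otherwise from the normal approximation with tie and continuity
corrections.  Kruskal-Wallis uses the tie-corrected H with a chi-square
reference distribution on k-1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import chi2, norm, rankdata

#: largest pooled sample size for which the exact Mann-Whitney null
#: distribution is enumerated (C(12,6) = 924 subsets at most)
EXACT_CAP = 12


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    method: str
    group_sizes: tuple[int, ...]


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) on nonnegative vectors.

    0 for identical vectors, 1 for disjoint supports; NaN (missing marker)
    when both vectors are entirely zero.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("bray_curtis requires nonnegative vectors")
    denom = float((u + v).sum())
    if denom == 0:
        return math.nan
    return float(np.abs(u - v).sum()) / denom


def _exact_mw_p(u_stat: float, n_x: int, n_y: int) -> float:
    """Two-sided exact p by enumerating all C(n, n_x) rank assignments."""
    n = n_x + n_y
    ranks = range(1, n + 1)
    const = n_x * (n_x + 1) / 2
    us = [sum(c) - const for c in combinations(ranks, n_x)]
    total = len(us)
    p_le = sum(u <= u_stat for u in us) / total
    p_ge = sum(u >= u_stat for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney(x, y, alternative: str = "two-sided", exact_cap: int = EXACT_CAP) -> TestResult:
    """Mann-Whitney U test between two samples.

    Exact enumeration when the pooled size is within ``exact_cap`` and the
    data are tie-free; otherwise the normal approximation with midranks,
    tie correction and continuity correction.  Only the two-sided
    alternative is offered, matching how the test is used here.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x == 0 or n_y == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2  # W convention: U of the first sample

    has_ties = len(np.unique(pooled)) < n_x + n_y
    if n_x + n_y <= exact_cap and not has_ties:
        p = _exact_mw_p(u_x, n_x, n_y)
        method = "exact_enumeration"
    else:
        n = n_x + n_y
        mu = n_x * n_y / 2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var = n_x * n_y / 12 * ((n + 1) - tie_term)
        if var == 0:  # all observations identical
            return TestResult("U", u_x, 1.0, "normal_approx", (n_x, n_y))
        diff = u_x - mu
        z = (diff - math.copysign(0.5, diff)) / math.sqrt(var) if diff != 0 else 0.0
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal_approx"
    return TestResult("U", u_x, p, method, (n_x, n_y))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank test across two or more samples.

    Tie-corrected H compared to chi-square with k-1 df.  Invariant under any
    strictly monotone transform of the pooled data.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        r_mean = ranks[start : start + size].mean()
        h += size * (r_mean - (n + 1) / 2) ** 2
        start += size
    h *= 12 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if correction == 0:  # every observation identical
        return TestResult("H", 0.0, 1.0, "chi2_approx", tuple(sizes))
    h /= correction
    p = float(chi2.sf(h, len(groups) - 1))
    return TestResult("H", float(h), max(p, np.finfo(float).tiny), "chi2_approx", tuple(sizes))


def _mean_profile_vector(leaves, species: str, catalog, basis: str) -> np.ndarray:
    from .matrices import leaf_matrix  # local import to avoid a cycle

    subset = [s for s in leaves if s.species == species]
    if not subset:
        raise ValueError(f"species {species!r} has no leaf samples")
    mat = leaf_matrix(subset, catalog, basis=basis)
    return mat.to_numpy(dtype=float).mean(axis=0)


def host_dissimilarity(
    leaves,
    species_a: str,
    species_b: str,
    catalog,
    basis: str = "compounds",
) -> float:
    """Bray-Curtis between two species' mean leaf profiles.

    ``basis`` is ``"compounds"`` (raw per-compound mg/g) or
    ``"subgroups_activities"`` (four subgroup totals plus the two
    activities).  Concentrations are used untransformed: the index is
    defined on raw abundances.
    """
    if basis not in ("compounds", "subgroups_activities"):
        raise ValueError(f"unknown basis {basis!r}")
    a = _mean_profile_vector(leaves, species_a, catalog, basis)
    b = _mean_profile_vector(leaves, species_b, catalog, basis)
    return bray_curtis(a, b)


def host_dissimilarity_matrix(leaves, catalog, basis: str = "compounds"):
    """Symmetric zero-diagonal dissimilarity table over all species present."""
    import pandas as pd

    species = sorted({s.species for s in leaves})
    out = pd.DataFrame(0.0, index=species, columns=species)
    for a, b in combinations(species, 2):
        d = host_dissimilarity(leaves, a, b, catalog, basis)
        out.loc[a, b] = out.loc[b, a] = d
    return out
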