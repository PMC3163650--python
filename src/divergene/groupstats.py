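"""Nonparametric multi-group statistics for qPCR folds and behavior.

Kruskal-Wallis H over more than two groups, pairwise Mann-Whitney U
follow-ups, and Holm step-down ("sequential Bonferroni") multiplicity
correction.  Exact null distributions are available by enumeration for
small samples; otherwise the usual tie-corrected chi-square / normal
approximations apply.  Tests are two-sided throughout, with mid-ranks
for ties.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["kruskal_wallis", "mann_whitney", "sequential_bonferroni",
           "group_chain"]


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def _exact_kwh_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p for H by enumerating group assignments."""
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    n = pooled.size
    idx = list(range(n))

    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        k = sizes_left[0]
        for combo in combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    count = total = 0
    for assignment in rec(tuple(idx), sizes):
        gs = [pooled[list(c)] for c in assignment]
        h = _h_statistic(gs)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def kruskal_wallis(values, groups, exact_max_n: int = 10
                   ) -> tuple[float, float]:
    """Kruskal-Wallis H test across two or more groups.

    Returns (H, p).  p comes from the chi-square approximation with
    k - 1 df; for total n <= ``exact_max_n`` the exact permutation
    distribution is enumerated instead.  Identical values throughout
    give H = 0, p = 1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    gs = [values[groups == lab] for lab in labels]
    if any(g.size < 1 for g in gs):
        raise ValueError("every group needs n >= 1")
    n = values.size
    if n < 3:
        raise ValueError("need total n >= 3")
    if np.unique(values).size == 1:
        return 0.0, 1.0
    h = _h_statistic(gs)
    if n <= exact_max_n:
        return h, _exact_kwh_p(gs, h)
    p = float(stats.chi2.sf(h, df=len(labels) - 1))
    return h, p


def mann_whitney(group_a, group_b, exact_max_n: int = 8
                 ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the smaller group has n <= ``exact_max_n``
    and there are no ties; tie-corrected normal approximation (with
    continuity correction) otherwise.  Returns (U of the first group, p).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    use_exact = min(a.size, b.size) <= exact_max_n and not ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if use_exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> pd.DataFrame:
    """Holm step-down correction.

    Sort ascending; reject while p(i) <= alpha / (m - i + 1), stop at
    the first failure.  Adjusted p-values are min(1, (m - i + 1) p(i))
    with monotonicity enforced.  With m = 1 this is the unadjusted test.
    """
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, p[order] * (m - np.arange(m)))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] <= alpha / (m - i):
            reject_sorted[i] = True
        else:
            break
    adj = np.empty(m)
    rej = np.empty(m, dtype=bool)
    adj[order] = adj_sorted
    rej[order] = reject_sorted
    return pd.DataFrame({"p_raw": p, "p_adj": adj, "reject": rej})


def group_chain(values, groups, alpha: float = 0.05, gate_p: float = 0.10,
                exact_max_n: int = 8) -> dict:
    """Omnibus-gated pairwise testing chain.

    Kruskal-Wallis first; pairwise Mann-Whitney tests run only when the
    omnibus p is below ``gate_p``, then Holm correction at ``alpha``.
    Returns a dict with the omnibus result and the (possibly empty)
    pairwise table.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    h, p_kwh = kruskal_wallis(values, groups)
    labels = list(pd.unique(groups))
    pairwise = pd.DataFrame(columns=["pair", "U", "p_raw", "p_adj", "reject"])
    if p_kwh < gate_p and len(labels) >= 2:
        rows = []
        for la, lb in combinations(labels, 2):
            u, p = mann_whitney(values[groups == la], values[groups == lb],
                                exact_max_n=exact_max_n)
            rows.append((f"{la}-vs-{lb}", u, p))
        raw = pd.DataFrame(rows, columns=["pair", "U", "p_raw"])
        holm = sequential_bonferroni(raw["p_raw"].to_numpy(), alpha=alpha)
        pairwise = pd.concat([raw, holm[["p_adj", "reject"]]], axis=1)
    return {"H": h, "p_kwh": p_kwh, "pairwise": pairwise,
            "any_reject": bool(pairwise["reject"].any()) if len(pairwise) else False}
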