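"""Shared statistical helpers (multiple testing, set enrichment, rank tests)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def significance_z_threshold(alpha: float = 0.05) -> float:
    """Two-sided standard-normal critical value (1.96 at alpha=0.05).

    Used to call standardized goodness-of-fit residuals significant.
    """
    return float(stats.norm.isf(alpha / 2.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be FDR-adjusted")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper_tail(n_hits: int, set_size: int, n_marked: int, universe: int) -> float:
    """P(X >= n_hits) drawing ``set_size`` from ``universe`` with ``n_marked`` marked."""
    return float(stats.hypergeom.sf(n_hits - 1, universe, n_marked, set_size))


def hypergeom_lower_tail(n_hits: int, set_size: int, n_marked: int, universe: int) -> float:
    return float(stats.hypergeom.cdf(n_hits, universe, n_marked, set_size))


def set_enrichment(
    membership: pd.Series, marked: pd.Series, side: str = "over"
) -> pd.DataFrame:
    """Hypergeometric enrichment of a marked subset within groups.

    Parameters
    ----------
    membership
        Group label per element of the universe (e.g., cluster id or
        matrisome category per protein).
    marked
        Boolean flag per element (same index) marking the subset whose
        over/under-representation is tested.
    side
        ``over`` (upper tail), ``under`` (lower tail) or ``two``.

    Returns a per-group table with counts, p and BH q over groups.
    """
    marked = marked.reindex(membership.index)
    universe = len(membership)
    n_marked = int(marked.sum())
    rows = []
    for group, idx in membership.groupby(membership).groups.items():
        size = len(idx)
        hits = int(marked.loc[idx].sum())
        upper = hypergeom_upper_tail(hits, size, n_marked, universe)
        lower = hypergeom_lower_tail(hits, size, n_marked, universe)
        if side == "over":
            p = upper
        elif side == "under":
            p = lower
        else:
            p = min(1.0, 2.0 * min(upper, lower))
        rows.append({"group": group, "size": size, "hits": hits, "p_value": p})
    out = pd.DataFrame(rows).set_index("group").sort_index()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def rank_sum_test(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Unpaired two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses the exact null distribution when the combined sample size is at
    most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(x), np.sort(y)):
        # Degenerate identical groups: no evidence of a shift.
        return float(x.size * y.size / 2.0), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
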