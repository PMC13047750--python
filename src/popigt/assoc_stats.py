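"""Correlation-based secondary analyses.

Per-wave Pearson correlations between the PoP-ORL parameters and net
proportion play, test–retest reliability across adjacent waves, and
Benjamini–Hochberg false-discovery-rate adjustment of test families.
Correlations use pairwise-complete deletion; p-values come from the
t-distribution transform with n - 2 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PARAM_COLUMNS = ("A_rew_z", "A_pun_z", "beta_f", "beta_b")

#: conventional qualitative reliability bands (our labelling convention,
#: applied uniformly; documented in the methods note)
RELIABILITY_BANDS = [(0.4, "poor"), (0.6, "fair"), (0.75, "good"), (1.01, "excellent")]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_i = min over j with p_j >= p_i of m * p_j / rank_j, capped at 1.
    Monotone in the raw p-values and idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted_sorted, 1.0)
    return out


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with its t-based p-value and n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def param_performance_associations(
    estimates: pd.DataFrame,
    scores: pd.DataFrame,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Per-wave correlations of each parameter with net proportion play.

    The BH family is the four parameter tests within each wave (and within
    each level of ``group_col`` when grouping by, e.g., risk status).
    """
    merged = estimates.merge(scores, on=["subject_id", "wave"], how="inner")
    group_keys = ["wave"] + ([group_col] if group_col else [])
    rows = []
    for keys, sub in merged.groupby(group_keys):
        keys = keys if isinstance(keys, tuple) else (keys,)
        family = []
        for param in PARAM_COLUMNS:
            r, p, n = pearson_with_p(sub[param], sub["net"])
            family.append({
                **dict(zip(group_keys, keys)),
                "variable_pair": f"{param}~net",
                "pearson_r": r, "p_value": p, "n": n,
            })
        ps = np.array([f["p_value"] for f in family])
        valid = ~np.isnan(ps)
        adj = np.full(ps.shape, np.nan)
        if valid.any():
            adj[valid] = bh_fdr(ps[valid])
        for f, a in zip(family, adj):
            f["fdr_adjusted_p"] = a
        rows.extend(family)
    return pd.DataFrame(rows)


def test_retest(wide: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Adjacent-wave Pearson reliabilities for one metric.

    ``wide`` has one row per subject and one column per wave (named by wave
    number).  Pairs with fewer than ``min_overlap`` complete observations
    are reported as missing.
    """
    waves = sorted(int(c) for c in wide.columns)
    rows = []
    for w1, w2 in zip(waves[:-1], waves[1:]):
        r, p, n = pearson_with_p(wide[w1], wide[w2])
        rows.append({
            "wave_pair": f"{w1}-{w2}",
            "pearson_r": r if n >= min_overlap else np.nan,
            "p_value": p if n >= min_overlap else np.nan,
            "n": n,
            "band": reliability_band(r) if n >= min_overlap else "missing",
        })
    return pd.DataFrame(rows)


def reliability_band(r: float) -> str:
    if np.isnan(r):
        return "missing"
    for cutoff, label in RELIABILITY_BANDS:
        if r < cutoff:
            return label
    return "excellent"


def metric_wide(long_df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot a long metric table to subject x wave for test_retest."""
    sub = long_df[long_df["metric_name"] == metric]
    return sub.pivot_table(index="subject_id", columns="wave", values="value",
                           aggfunc="first")


def pooled_t_from_summary(m1, s1, n1, m2, s2, n2) -> tuple[float, float]:
    """Two-sample pooled-variance t-test from summary statistics.

    Returns (t, two-sided p) for H0: equal means, the textbook check used
    on baseline demographic comparisons between groups.
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
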