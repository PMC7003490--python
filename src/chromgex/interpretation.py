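"""TF prioritization from fitted expression models.

A TF matters to the model if its feature keeps a non-zero mean coefficient
across the outer cross-validation folds.  For comparability across samples
the mean coefficients are scaled by the maximum absolute mean coefficient
per sample (signs preserved, values in [-1, 1]).  Set logic over promoter
and loop contexts yields a membership matrix (UpSet-style), and an
expression-enrichment resampling test asks whether a prioritized TF set is
more highly expressed than random TF sets of the same size.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .learning import CVResult

__all__ = [
    "mean_fold_coefficients",
    "scale_coefficients",
    "nonzero_features",
    "tf_set_overlap",
    "tf_expression_enrichment",
    "rank_tfs",
]


def mean_fold_coefficients(cv_result: CVResult) -> pd.Series:
    """Arithmetic mean of the fitted coefficients across the outer folds.

    A feature absent (zeroed) in a fold counts as 0 in the mean.
    """
    return cv_result.coef_matrix().reindex(columns=cv_result.feature_names).fillna(0.0).mean(axis=0)


def scale_coefficients(mean_coeffs: pd.Series) -> pd.Series:
    """Divide by the maximum absolute mean coefficient; signs preserved.

    The result lies in [-1, 1] and scaling is idempotent.
    """
    m = mean_coeffs.abs().max()
    if m == 0 or np.isnan(m):
        raise ValueError("all mean coefficients are zero; nothing to scale")
    return mean_coeffs / m


def nonzero_features(mean_coeffs: pd.Series, tol: float = 0.0) -> set[str]:
    return set(mean_coeffs.index[mean_coeffs.abs() > tol])


def tf_set_overlap(
    sets: Mapping[str, set[str]], min_samples: int = 2
) -> tuple[pd.DataFrame, pd.Series, dict[str, set[str]]]:
    """Membership analysis over named TF sets (e.g. ``"K562:promoter"``).

    Returns the binary membership matrix (TF x set), the per-intersection
    pattern counts, and — per context — the TFs present in at least
    ``min_samples`` of the sets sharing that context suffix.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    tfs = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [tf in s for tf in tfs] for name, s in sets.items()}, index=tfs, dtype=bool
    )
    patterns = membership.apply(
        lambda row: "&".join(c for c in membership.columns if row[c]) or "(none)", axis=1
    )
    counts = patterns.value_counts()

    recurrent: dict[str, set[str]] = {}
    contexts = {name.rsplit(":", 1)[1] for name in sets if ":" in name}
    for ctx in contexts:
        cols = [c for c in membership.columns if c.endswith(f":{ctx}")]
        if cols:
            hits = membership[cols].sum(axis=1)
            recurrent[ctx] = set(hits.index[hits >= min_samples])
    return membership, counts, recurrent


def tf_expression_enrichment(
    query_tfs: Sequence[str],
    tf_universe: Sequence[str],
    expression: Mapping[str, float],
    n_samples: int = 1000,
    seed: int = 0,
    pooled: bool = True,
) -> dict:
    """Is the query TF set more highly expressed than random same-size sets?

    ``n_samples`` random sets are drawn without replacement from the
    universe; the query expression distribution is compared against the
    pooled sampled distribution with a two-sided rank-sum (Mann-Whitney)
    test.  With ``pooled=False`` the p-value is instead the resampling
    fraction of sampled sets whose median expression reaches the query's.
    Returns p-value, effect direction and the medians.
    """
    universe = [t for t in tf_universe if t in expression]
    query = [t for t in query_tfs if t in expression]
    dropped = len(query_tfs) - len(query)
    if dropped:
        warnings.warn(f"{dropped} query TF(s) lack expression values; dropped")
    if not query:
        raise ValueError("no query TF has an expression value")
    if not set(query) <= set(universe):
        raise ValueError("query TFs must be part of the TF universe")
    rng = np.random.default_rng(seed)
    expr = np.array([expression[t] for t in universe], dtype=float)
    q_expr = np.array([expression[t] for t in query], dtype=float)
    m = len(query)
    draws = np.array([rng.choice(len(universe), size=m, replace=False) for _ in range(n_samples)])
    sampled = expr[draws]  # (n_samples, m)

    q_med = float(np.median(q_expr))
    s_med = float(np.median(sampled))
    direction = "higher" if q_med > s_med else ("lower" if q_med < s_med else "equal")
    if pooled:
        stat = scipy.stats.mannwhitneyu(q_expr, sampled.ravel(), alternative="two-sided")
        p = float(stat.pvalue)
    else:
        med_per_set = np.median(sampled, axis=1)
        tail = min(
            (np.sum(med_per_set >= q_med) + 1) / (n_samples + 1),
            (np.sum(med_per_set <= q_med) + 1) / (n_samples + 1),
        )
        p = float(min(1.0, 2 * tail))
    return {
        "p_value": p,
        "direction": direction,
        "query_median": q_med,
        "sampled_median": s_med,
        "n_query": m,
        "n_samples": n_samples,
    }


def rank_tfs(mean_coeffs: pd.Series, top_k: int = 20) -> pd.DataFrame:
    """Top-k features by mean absolute coefficient (ties broken by name)."""
    df = pd.DataFrame({"mean_coef": mean_coeffs})
    df["abs"] = df["mean_coef"].abs()
    # stable sort on a name-sorted frame => lexicographic tie-break
    df = df.sort_index().sort_values("abs", ascending=False, kind="mergesort")
    df = df.loc[df["abs"] > 0].head(top_k).drop(columns="abs")
    df["scaled_coef"] = df["mean_coef"] / mean_coeffs.abs().max()
    df["rank"] = range(1, len(df) + 1)
    return df
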