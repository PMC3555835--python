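"""Hypergeometric over/under-representation of functional categories.

Given a set of predicted target genes and a category -> gene map (GMT-like),
each category is tested with exact hypergeometric tail probabilities:
p_over = P(X >= k) and p_under = P(X <= k) for X ~ Hypergeometric(N, K, n),
where N is the universe size, K the category size, n the target-set size
and k the observed overlap.  The two tail families are adjusted separately
with Benjamini-Hochberg by default (jointly on request) and categories
with adjusted q below alpha are flagged significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_test(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Exact (p_over, p_under) tail probabilities.

    p_over = P(X >= k), p_under = P(X <= k); the tails share P(X = k), so
    they sum to at least 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError("inconsistent counts for hypergeometric test")
    if k < max(0, n + K - N):
        raise ValueError("overlap below the feasible minimum")
    p_over = float(hypergeom.sf(k - 1, N, K, n))
    p_under = float(hypergeom.cdf(k, N, K, n))
    return min(p_over, 1.0), min(p_under, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT-like TSV: category, description, gene ids (tab-separated)."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return out


def enrich(
    targets,
    categories: dict[str, tuple[str, frozenset[str]]],
    universe=None,
    alpha: float = 0.05,
    joint_tails: bool = False,
) -> pd.DataFrame:
    """Test every category for over/under-representation among targets.

    ``universe`` defaults to all genes appearing in the category map.
    Targets must be a subset of the universe.  Returns a table ranked by
    the smaller adjusted q of the two tails.
    """
    cat_map = {
        c: (desc, frozenset(genes)) for c, (desc, genes) in categories.items()
    }
    if universe is None:
        universe = frozenset().union(*(g for _, g in cat_map.values())) if cat_map else frozenset()
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = frozenset(targets)
    if not targets <= universe:
        raise ValueError("targets must be a subset of the universe")
    N, n = len(universe), len(targets)
    rows = []
    for cat, (desc, genes) in cat_map.items():
        genes_u = genes & universe
        K = len(genes_u)
        if K == 0:
            continue
        k = len(genes_u & targets)
        p_over, p_under = hypergeom_test(N, K, n, k)
        rows.append(
            {"category": cat, "description": desc, "N": N, "K": K, "n": n,
             "k": k, "p_over": p_over, "p_under": p_under}
        )
    df = pd.DataFrame(
        rows,
        columns=["category", "description", "N", "K", "n", "k", "p_over", "p_under"],
    )
    if df.empty:
        df["q_over"] = df["q_under"] = df["significant"] = []
        return df
    if joint_tails:
        q = bh_adjust(np.concatenate([df["p_over"], df["p_under"]]))
        df["q_over"], df["q_under"] = q[: len(df)], q[len(df):]
    else:
        df["q_over"] = bh_adjust(df["p_over"])
        df["q_under"] = bh_adjust(df["p_under"])
    qmin = df[["q_over", "q_under"]].min(axis=1)
    df["significant"] = qmin < alpha
    return (
        df.assign(_qmin=qmin)
        .sort_values(["_qmin", "category"], ignore_index=True)
        .drop(columns="_qmin")
    )
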