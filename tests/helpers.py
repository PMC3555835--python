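"""Independent oracles shared by unit and acceptance tests.

These deliberately re-derive expected values by exhaustive enumeration or
direct formula evaluation, independent of the implementation paths they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def match_oracle(q: str, r: str, tol: int = 4):
    """Brute-force end-tolerant matching: enumerate every (offset, trim) pair.

    Returns the best (cost, -core_length, |offset|) key or None, comparing
    column by column with no shortcuts.
    """
    lq, lr = len(q), len(r)
    best = None
    for o in range(-lq + 1, lr):
        for a in range(lq):
            for b in range(a + 1, lq + 1):
                if o + a < 0 or o + b > lr:
                    continue
                if any(q[t] != r[o + t] for t in range(a, b)):
                    continue
                n5 = a + max(o, 0)
                n3 = (lq - b) + max(0, lr - o - lq)
                if n5 + n3 > tol or (b - a) < lq - tol:
                    continue
                key = (n5 + n3, -(b - a), abs(o))
                if best is None or key < best:
                    best = key
    return best


def random_match_cases(rng: np.random.Generator, n_cases: int):
    """Random query/reference pairs: half unrelated, half end-perturbed."""
    bases = list("ACGT")
    out = []
    while len(out) < n_cases:
        lr = int(rng.integers(16, 29))
        r = "".join(rng.choice(bases, lr))
        if rng.random() < 0.5:
            lq = int(rng.integers(15, 31))
            q = "".join(rng.choice(bases, lq))
        else:
            t5, t3 = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            q = (
                "".join(rng.choice(bases, t5))
                + r[int(rng.integers(0, 3)) : lr - int(rng.integers(0, 3))]
                + "".join(rng.choice(bases, t3))
            )[:30]
            if len(q) < 15:
                continue
        out.append((q, r))
    return out


def hypergeom_tails_by_enumeration(N: int, K: int, n: int, k: int):
    """Exact tail probabilities by enumerating every C(N, n) target draw."""
    category = set(range(K))
    total = over = under = 0
    for draw in combinations(range(N), n):
        total += 1
        overlap = len(category.intersection(draw))
        if overlap >= k:
            over += 1
        if overlap <= k:
            under += 1
    return over / total, under / total


def bh_stepup(p):
    """Benjamini-Hochberg by the direct step-up formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def naive_scan(seq: str, genome: str):
    """All plus-strand occurrences of seq by sliding-window comparison."""
    return [
        i
        for i in range(len(genome) - len(seq) + 1)
        if genome[i : i + len(seq)] == seq
    ]


REVCOMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]
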