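"""Nested RNA secondary-structure prediction by base-pair maximisation.

Candidate pre-miRNA hairpins are screened with a Nussinov-style dynamic
programme that maximises the number of base pairs (Watson-Crick plus,
optionally, G·U wobble) subject to a minimum hairpin-loop length.  Among
the typically many structures attaining the maximal pair count, the
traceback prefers structures with the largest number of stacked pairs
(adjacent pairs (i, j) and (i+1, j-1)), so contiguous helices such as a
planted miRNA stem are reported rather than an arbitrary co-optimal
matching.  The stacking preference is a tie-break only: the pair count is
exactly the Nussinov maximum.

Pass/fail evaluation of a candidate follows the community guidelines for
calling a novel miRNA: the mature sequence must sit wholly in one arm of a
stem-loop, pair with the opposite arm at ~16 or more positions, and no
branching (pairs internal to the mature span) may interrupt it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WC_PAIRS = frozenset({"AT", "TA", "CG", "GC"})
WOBBLE_PAIRS = frozenset({"GT", "TG"})

MIN_LOOP = 3  # minimum unpaired nucleotides closed by a pair


def _pairable(a: str, b: str, allow_gu: bool) -> bool:
    ab = a + b
    return ab in WC_PAIRS or (allow_gu and ab in WOBBLE_PAIRS)


def max_pair_structure(
    seq: str, min_loop: int = MIN_LOOP, allow_gu: bool = True
) -> tuple[int, list[tuple[int, int]]]:
    """Return (max base pairs, pair list) for a nested structure of ``seq``.

    The pair list is one structure attaining the maximum, chosen to
    maximise the number of stacked pairs among the co-optima.  U is
    accepted as a synonym of T.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    # F[i][j]: best (pairs, stacks) over all nested structures of s[i..j]
    # C[i][j]: best (pairs, stacks) over structures in which (i, j) pair,
    #          or None when i and j cannot pair.
    NEG = (-1, -1)
    F = [[(0, 0)] * n for _ in range(n)]
    C: list[list[tuple[int, int] | None]] = [[None] * n for _ in range(n)]

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _pairable(s[i], s[j], allow_gu):
                inner = F[i + 1][j - 1] if j - 1 >= i + 1 else (0, 0)
                best_inner = inner
                ci = C[i + 1][j - 1] if j - 1 > i + 1 else None
                if ci is not None:
                    cand = (ci[0], ci[1] + 1)  # stacked on (i+1, j-1)
                    if cand > best_inner:
                        best_inner = cand
                C[i][j] = (best_inner[0] + 1, best_inner[1])
            best = F[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                cik = C[i][k]
                if cik is None:
                    continue
                rest = F[k + 1][j] if k + 1 <= j else (0, 0)
                cand = (cik[0] + rest[0], cik[1] + rest[1])
                if cand > best:
                    best = cand
            F[i][j] = best

    pairs: list[tuple[int, int]] = []

    def trace_closed(i: int, j: int) -> None:
        pairs.append((i, j))
        target = C[i][j]
        assert target is not None
        want = (target[0] - 1, target[1])
        if j - 1 > i + 1:
            ci = C[i + 1][j - 1]
            if ci is not None and (ci[0], ci[1] + 1) == want:
                trace_closed(i + 1, j - 1)
                return
        if j - 1 >= i + 1:
            trace_free(i + 1, j - 1)

    def trace_free(i: int, j: int) -> None:
        while i < j:
            if j - i <= min_loop:
                return
            target = F[i][j]
            if target == (0, 0):
                return
            if F[i + 1][j] == target:
                i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                cik = C[i][k]
                if cik is None:
                    continue
                rest = F[k + 1][j] if k + 1 <= j else (0, 0)
                if (cik[0] + rest[0], cik[1] + rest[1]) == target:
                    trace_closed(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - traceback must always find its choice
                raise AssertionError("inconsistent traceback")

    if n:
        trace_free(0, n - 1)
    total = F[0][n - 1][0] if n else 0
    assert total == len(pairs)
    return total, sorted(pairs)


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def max_pairs_bruteforce(
    seq: str, min_loop: int = MIN_LOOP, allow_gu: bool = True
) -> int:
    """Exhaustive recursion over all nested structures (test oracle).

    Walks the full recursion tree without memoisation for the first
    position of each interval (unpaired, or paired with every legal
    partner), so every nested structure is explored.  Exponential; only
    usable on short sequences.
    """
    s = seq.upper().replace("U", "T")

    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if _pairable(s[i], s[k], allow_gu):
                cand = 1 + rec(i + 1, k - 1) + (rec(k + 1, j) if k < j else 0)
                if cand > best:
                    best = cand
        return best

    return rec(0, len(s) - 1) if s else 0


@dataclass
class HairpinFold:
    """Folding verdict for one candidate precursor."""

    structure: str
    total_pairs: int
    mature_arm_pairs: int
    mature_in_one_arm: bool
    unbranched: bool
    passed: bool
    pairs: list[tuple[int, int]] = field(repr=False, default_factory=list)


def _best_helix(
    pairs: list[tuple[int, int]],
    span: tuple[int, int],
    max_step: int = 2,
    max_interrupts: int = 2,
) -> int:
    """Longest helix-like chain of pairs from the mature span to one side.

    Consecutive pairs in a chain must progress by at most ``max_step``
    positions on either strand (i.e. bulges/internal loops of at most one
    nucleotide per side), with at most ``max_interrupts`` non-stacked
    steps.  This is what distinguishes a genuine stem from the scattered
    pairing a base-pair-maximising fold assigns to random sequence.
    """
    s, e = span
    up = sorted(((a, b) for a, b in pairs if s <= b < e and a < s), key=lambda p: p[1])
    down = sorted((a, b) for a, b in pairs if s <= a < e and b >= e)
    best = 0
    for ps, si in ((up, 1), (down, 0)):
        for start in range(len(ps)):
            cnt, intr = 1, 0
            last = ps[start]
            for t in range(start + 1, len(ps)):
                da = ps[t][si] - last[si]
                db = last[1 - si] - ps[t][1 - si]
                if da < 1 or db < 1:
                    continue
                if da > max_step or db > max_step:
                    break
                if da > 1 or db > 1:
                    intr += 1
                    if intr > max_interrupts:
                        break
                cnt += 1
                last = ps[t]
            best = max(best, cnt)
    return best


def evaluate_hairpin(
    precursor: str,
    mature_span: tuple[int, int],
    min_arm_pairs: int = 16,
    min_loop: int = MIN_LOOP,
    allow_gu: bool = True,
    stray_tolerance: int = 2,
) -> HairpinFold:
    """Fold ``precursor`` and judge whether ``mature_span`` sits in a hairpin arm.

    ``mature_span`` is 0-based half-open within the precursor.  Pass
    criteria: at least ``min_arm_pairs`` pairs between the span and the
    opposite arm arranged as a single helix (see :func:`_best_helix`),
    the span pairing essentially in one direction (at most
    ``stray_tolerance`` terminal bases may be grabbed the other way by
    the pair-maximising objective), and no pair lying entirely inside the
    span (no multiloop branching across the mature).
    """
    s, e = mature_span
    if not (0 <= s < e <= len(precursor)):
        raise ValueError("mature span outside precursor")
    if len(precursor) < (e - s) + min_arm_pairs:
        raise ValueError("precursor too short to harbour a hairpin")
    total, pairs = max_pair_structure(precursor, min_loop=min_loop, allow_gu=allow_gu)
    up = sum(1 for a, b in pairs if s <= b < e and a < s)
    down = sum(1 for a, b in pairs if s <= a < e and b >= e)
    internal = sum(1 for a, b in pairs if s <= a and b < e)
    one_arm = internal == 0 and min(up, down) <= stray_tolerance
    arm_pairs = _best_helix(pairs, mature_span)
    passed = one_arm and arm_pairs >= min_arm_pairs
    return HairpinFold(
        structure=pairs_to_dotbracket(len(precursor), pairs),
        total_pairs=total,
        mature_arm_pairs=arm_pairs,
        mature_in_one_arm=one_arm,
        unbranched=internal == 0,
        passed=passed,
        pairs=pairs,
    )
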