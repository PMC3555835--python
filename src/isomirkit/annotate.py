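"""IsomiR-aware annotation of unique tags against a mature miRNA reference.

The matcher implements end-tolerant exact-core semantics: a tag matches a
reference mature when some ungapped offset alignment leaves a 100%
identical core and at most four *terminal variant* nucleotides in total
over both ends.  Terminal variants are query extensions beyond the
reference, query truncations relative to the reference, and mismatching
terminal positions; internal (non-terminal) mismatches are not tolerated
by default, so internally edited tags fall to the unannotated pool (an
``allow_internal_mismatch`` knob relaxes this).

Tags matching one reference form that miRNA's isomiR cluster; the most
abundant member is the predominant isomiR and names the cluster, and a
flag records whether it diverges from the database mature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import UniqueTag, canonicalize


@dataclass(frozen=True)
class MatureReference:
    """A database mature miRNA sequence with a species-prefixed id."""

    mirna_id: str
    sequence: str

    @property
    def species(self) -> str:
        return self.mirna_id.split("-", 1)[0].lower()


@dataclass(frozen=True)
class MatchResult:
    mirna_id: str
    offset: int  # query start relative to the reference 5' end
    n_5prime_variant: int
    n_3prime_variant: int
    core_length: int

    @property
    def cost(self) -> int:
        return self.n_5prime_variant + self.n_3prime_variant


def match_end_tolerant(
    query: str,
    reference: MatureReference,
    tolerance: int = 4,
    allow_internal_mismatch: int = 0,
) -> MatchResult | None:
    """Best end-tolerant ungapped alignment of ``query`` to one reference.

    Over all offsets, finds the alignment minimising total terminal
    variants such that the core is 100% identical (up to
    ``allow_internal_mismatch`` internal substitutions), the core covers
    at least ``len(query) - tolerance`` query positions, and total
    terminal variants do not exceed ``tolerance``.  Returns None when no
    such alignment exists.
    """
    q = canonicalize(query)
    if not q:
        raise ValueError("empty query")
    r = canonicalize(reference.sequence)
    lq, lr = len(q), len(r)
    best: MatchResult | None = None
    # total terminal variants <= tolerance bounds the offset on both sides
    lo = max(-tolerance, lr - lq - tolerance)
    hi = min(tolerance, lr - lq + tolerance)
    for o in range(lo, hi + 1):
        # core q[a:b] aligned to r[o+a:o+b]; every query nucleotide outside
        # the core and every uncovered reference nucleotide counts once
        for a in range(0, tolerance + 1):
            if o + a < 0:
                continue
            for b in range(max(a + 1, lq - tolerance + a), lq + 1):
                if o + b > lr:
                    continue
                n5 = a + max(o, 0)
                n3 = (lq - b) + max(0, lr - (o + lq))
                core = b - a
                if n5 + n3 > tolerance or core < lq - tolerance:
                    continue
                if allow_internal_mismatch == 0:
                    if q[a:b] != r[o + a : o + b]:
                        continue
                else:
                    internal = sum(
                        1 for t in range(a, b) if q[t] != r[o + t]
                    )
                    if internal > allow_internal_mismatch:
                        continue
                cand = MatchResult(reference.mirna_id, o, n5, n3, core)
                if (
                    best is None
                    or (cand.cost, -cand.core_length, abs(cand.offset))
                    < (best.cost, -best.core_length, abs(best.offset))
                ):
                    best = cand
    return best


def match_best(
    query: str,
    references: list[MatureReference],
    tolerance: int = 4,
    allow_internal_mismatch: int = 0,
) -> MatchResult | None:
    """Best match over a reference set with the assignment priority rule.

    Ties between references matching at equal terminal-variant cost are
    broken by: porcine ("ssc") reference first, then longer core, then
    lexicographic id.
    """
    best: tuple | None = None
    for ref in references:
        m = match_end_tolerant(query, ref, tolerance, allow_internal_mismatch)
        if m is None:
            continue
        key = (m.cost, 0 if ref.species == "ssc" else 1, -m.core_length, m.mirna_id)
        if best is None or key < best[0]:
            best = (key, m)
    return best[1] if best else None


@dataclass
class MiRNACluster:
    """All isomiR tags annotated to one mature miRNA."""

    mirna_id: str
    reference_sequence: str
    members: list[UniqueTag] = field(default_factory=list)

    @property
    def cluster_cn(self) -> int:
        return sum(t.total_count for t in self.members)

    @property
    def isomir_count(self) -> int:
        return len(self.members)

    @property
    def predominant(self) -> UniqueTag:
        # max CN; ties broken by lexicographic sequence for determinism
        return min(self.members, key=lambda t: (-t.total_count, t.sequence))

    @property
    def diverges_from_reference(self) -> bool:
        return self.predominant.sequence != canonicalize(self.reference_sequence)

    def per_library_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for t in self.members:
            for lib, c in t.per_library_counts.items():
                totals[lib] = totals.get(lib, 0) + c
        return totals


def assign_tags(
    tags: list[UniqueTag],
    references: list[MatureReference],
    tolerance: int = 4,
    allow_internal_mismatch: int = 0,
) -> tuple[list[MiRNACluster], list[UniqueTag]]:
    """Assign each tag to at most one miRNA; return clusters + unannotated tags."""
    by_id = {r.mirna_id: r for r in references}
    clusters: dict[str, MiRNACluster] = {}
    unannotated: list[UniqueTag] = []
    for tag in tags:
        m = match_best(tag.sequence, references, tolerance, allow_internal_mismatch)
        if m is None:
            unannotated.append(tag)
            continue
        cl = clusters.setdefault(
            m.mirna_id,
            MiRNACluster(m.mirna_id, by_id[m.mirna_id].sequence),
        )
        cl.members.append(tag)
    ordered = sorted(clusters.values(), key=lambda c: (-c.cluster_cn, c.mirna_id))
    return ordered, unannotated


def build_profile(
    clusters: list[MiRNACluster],
    min_cluster_cn: int = 3,
    total_reads: int | None = None,
    library_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Profile table: one row per miRNA cluster with CN >= ``min_cluster_cn``.

    ``total_reads`` is the denominator for the percentage share (all
    length-filtered reads); it defaults to the summed CN of all clusters.
    """
    kept = [c for c in clusters if c.cluster_cn >= min_cluster_cn]
    if total_reads is None:
        total_reads = sum(c.cluster_cn for c in kept)
    libs = library_ids or sorted(
        {lib for c in kept for lib in c.per_library_totals()}
    )
    rows = []
    for c in kept:
        per_lib = c.per_library_totals()
        rows.append(
            {
                "mirna_id": c.mirna_id,
                "CN": c.cluster_cn,
                "pct_share": round(100.0 * c.cluster_cn / total_reads, 2)
                if total_reads
                else 0.0,
                "isomir_count": c.isomir_count,
                **{lib: per_lib.get(lib, 0) for lib in libs},
                "predominant": c.predominant.sequence,
                "diverges_from_reference": c.diverges_from_reference,
            }
        )
    cols = ["mirna_id", "CN", "pct_share", "isomir_count", *libs, "predominant",
            "diverges_from_reference"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["CN", "mirna_id"], ascending=[False, True]).reset_index(
        drop=True
    )


def per_group_predominance(
    cluster: MiRNACluster,
    group_map: dict[str, str],
    library_totals: dict[str, int],
) -> dict[str, str | None]:
    """Per breed group, the member with the highest summed normalised count.

    Counts are normalised per library (counts per thousand) before
    summing within the group, so deep libraries do not dominate.  Ties
    are broken by lexicographic sequence; a group with no counts at all
    maps to None.
    """
    groups = sorted(set(group_map.values()))
    out: dict[str, str | None] = {}
    for g in groups:
        libs = [lib for lib, gg in group_map.items() if gg == g]
        best_seq: str | None = None
        best_val = 0.0
        for t in sorted(cluster.members, key=lambda t: t.sequence):
            val = sum(
                1000.0 * t.per_library_counts.get(lib, 0) / library_totals[lib]
                for lib in libs
                if library_totals.get(lib)
            )
            if val > best_val:
                best_val, best_seq = val, t.sequence
        out[g] = best_seq
    return out


def isomir_detail_frame(clusters: list[MiRNACluster]) -> pd.DataFrame:
    """Alignment-style isomiR listing: every member of every cluster.

    Members are ordered by descending count and left-padded relative to
    the database mature so the 5'/3' end variability is visible in the
    ``aligned`` column.
    """
    rows = []
    for cl in clusters:
        ref = MatureReference(cl.mirna_id, cl.reference_sequence)
        members = sorted(cl.members, key=lambda t: (-t.total_count, t.sequence))
        matches = {t.sequence: match_end_tolerant(t.sequence, ref) for t in members}
        pad = max((-m.offset for m in matches.values() if m), default=0)
        for t in members:
            m = matches[t.sequence]
            rows.append(
                {
                    "mirna_id": cl.mirna_id,
                    "sequence": t.sequence,
                    "CN": t.total_count,
                    "offset": m.offset if m else None,
                    "n_5prime_variant": m.n_5prime_variant if m else None,
                    "n_3prime_variant": m.n_3prime_variant if m else None,
                    "is_database_sequence": t.sequence == cl.reference_sequence,
                    "aligned": " " * (pad + (m.offset if m else 0)) + t.sequence,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "sequence", "CN", "offset", "n_5prime_variant",
                 "n_3prime_variant", "is_database_sequence", "aligned"],
    )


def read_mature_fasta(path) -> list[MatureReference]:
    from Bio import SeqIO

    return [
        MatureReference(rec.id, canonicalize(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
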