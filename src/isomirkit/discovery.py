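"""Novel miRNA candidate discovery from unannotated tags.

Screening cascade, after annotation against the mature reference: a tag
is a candidate when it maps perfectly to exactly one genomic site, is
19-23 nt long, lies outside the annotation mask, and has copy number
above 2.  Candidates are clustered by single-linkage genomic overlap
(>= 1 nt, same strand); each cluster's most abundant member is its
reference sequence, whose locus +- 50 nt of flank forms the putative
precursor submitted to hairpin folding (see :mod:`isomirkit.fold`).

Coordinates are 0-based half-open internally; user-facing tables use
1-based inclusive positions (noted in their headers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .fold import HairpinFold, evaluate_hairpin
from .preprocess import UniqueTag
from .seqs import find_all, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicLocus:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def overlaps(self, other: "GenomicLocus") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def map_perfect(seq: str, genome: dict[str, str]) -> list[GenomicLocus]:
    """Every exact occurrence of ``seq`` on either strand, in plus coordinates."""
    loci: list[GenomicLocus] = []
    rc = revcomp(seq)
    for chrom in sorted(genome):
        s = genome[chrom]
        for pos in find_all(seq, s):
            loci.append(GenomicLocus(chrom, pos, pos + len(seq), "+"))
        for pos in find_all(rc, s):
            loci.append(GenomicLocus(chrom, pos, pos + len(seq), "-"))
    return loci


def _mask_trees(mask: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in mask:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def select_candidates(
    tags: list[UniqueTag],
    genome: dict[str, str],
    mask: list[tuple[str, int, int]],
    min_len: int = 19,
    max_len: int = 23,
    min_cn_exclusive: int = 2,
) -> list[tuple[UniqueTag, GenomicLocus]]:
    """Novel-candidate filter cascade.

    Kept iff: exactly one perfect genomic locus AND ``min_len <= length <=
    max_len`` AND the locus does not intersect the annotation mask AND
    CN strictly greater than ``min_cn_exclusive``.  The filters commute;
    they are applied in one pass.
    """
    trees = _mask_trees(mask)
    out: list[tuple[UniqueTag, GenomicLocus]] = []
    for tag in tags:
        if not (min_len <= len(tag) <= max_len):
            continue
        if tag.total_count <= min_cn_exclusive:
            continue
        loci = map_perfect(tag.sequence, genome)
        if len(loci) != 1:
            continue
        loc = loci[0]
        tree = trees.get(loc.chrom)
        if tree is not None and tree.overlap(loc.start, loc.end):
            continue
        out.append((tag, loc))
    return out


@dataclass
class NovelCandidateCluster:
    cluster_id: str
    members: list[tuple[UniqueTag, GenomicLocus]]
    precursor: str = ""
    mature_span: tuple[int, int] = (0, 0)
    fold: HairpinFold | None = None

    @property
    def reference(self) -> UniqueTag:
        """Max-CN member (ties by lexicographic sequence)."""
        return min(self.members, key=lambda m: (-m[0].total_count, m[0].sequence))[0]

    @property
    def reference_locus(self) -> GenomicLocus:
        return min(self.members, key=lambda m: (-m[0].total_count, m[0].sequence))[1]

    @property
    def cluster_cn(self) -> int:
        return sum(t.total_count for t, _ in self.members)

    @property
    def isomir_count(self) -> int:
        return len(self.members)

    @property
    def span(self) -> GenomicLocus:
        starts = [loc.start for _, loc in self.members]
        ends = [loc.end for _, loc in self.members]
        ref = self.reference_locus
        return GenomicLocus(ref.chrom, min(starts), max(ends), ref.strand)

    @property
    def validated(self) -> bool:
        return bool(self.fold and self.fold.passed)


def cluster_by_locus(
    candidates: list[tuple[UniqueTag, GenomicLocus]]
) -> list[NovelCandidateCluster]:
    """Single-linkage grouping of candidate loci (>=1 nt same-strand overlap)."""
    ordered = sorted(
        candidates, key=lambda m: (m[1].chrom, m[1].strand, m[1].start, m[1].end)
    )
    clusters: list[list[tuple[UniqueTag, GenomicLocus]]] = []
    cur: list[tuple[UniqueTag, GenomicLocus]] = []
    cur_end = -1
    cur_key: tuple[str, str] | None = None
    for tag, loc in ordered:
        key = (loc.chrom, loc.strand)
        if cur and key == cur_key and loc.start < cur_end:
            cur.append((tag, loc))
            cur_end = max(cur_end, loc.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [(tag, loc)]
            cur_end = loc.end
            cur_key = key
    if cur:
        clusters.append(cur)
    return [
        NovelCandidateCluster(cluster_id=f"Cl-{i + 1}", members=members)
        for i, members in enumerate(clusters)
    ]


def extract_precursor(
    cluster: NovelCandidateCluster,
    genome: dict[str, str],
    flank: int = 50,
) -> tuple[str, tuple[int, int]]:
    """Strand-oriented precursor = reference locus +- ``flank`` nt.

    Returns (precursor sequence, mature span within it, 0-based
    half-open).  Flanks are clipped (and logged) at chromosome ends.
    """
    loc = cluster.reference_locus
    if loc.chrom not in genome:
        raise KeyError(f"chromosome {loc.chrom!r} not in genome")
    chrom_seq = genome[loc.chrom]
    w_start = max(0, loc.start - flank)
    w_end = min(len(chrom_seq), loc.end + flank)
    if w_start != loc.start - flank or w_end != loc.end + flank:
        logger.info(
            "precursor flanks clipped to [%d, %d) for %s", w_start, w_end,
            cluster.cluster_id,
        )
    window = chrom_seq[w_start:w_end]
    if loc.strand == "+":
        span = (loc.start - w_start, loc.end - w_start)
        precursor = window
    else:
        precursor = revcomp(window)
        span = (w_end - loc.end, w_end - loc.start)
    cluster.precursor = precursor
    cluster.mature_span = span
    return precursor, span


def discover(
    unannotated: list[UniqueTag],
    genome: dict[str, str],
    mask: list[tuple[str, int, int]],
    min_len: int = 19,
    max_len: int = 23,
    min_cn_exclusive: int = 2,
    flank: int = 50,
    min_arm_pairs: int = 16,
    allow_gu: bool = True,
) -> list[NovelCandidateCluster]:
    """Full discovery cascade: filter, cluster, extract precursors, fold."""
    candidates = select_candidates(
        unannotated, genome, mask, min_len, max_len, min_cn_exclusive
    )
    clusters = cluster_by_locus(candidates)
    for cl in clusters:
        precursor, span = extract_precursor(cl, genome, flank)
        cl.fold = evaluate_hairpin(
            precursor, span, min_arm_pairs=min_arm_pairs, allow_gu=allow_gu
        )
    return clusters


def candidates_to_frame(clusters: list[NovelCandidateCluster]) -> pd.DataFrame:
    """Candidate report (1-based inclusive coordinates in the locus column)."""
    rows = []
    for cl in clusters:
        span = cl.span
        rows.append(
            {
                "cluster": cl.cluster_id,
                "locus_1based": f"{span.chrom}:{span.start + 1}:{span.end}:{span.strand}",
                "CN": cl.cluster_cn,
                "isomirs": cl.isomir_count,
                "reference_sequence": cl.reference.sequence,
                "mature_arm_pairs": cl.fold.mature_arm_pairs if cl.fold else 0,
                "fold_pass": cl.validated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "locus_1based", "CN", "isomirs", "reference_sequence",
            "mature_arm_pairs", "fold_pass",
        ],
    )
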