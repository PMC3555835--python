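"""Genome mapping, candidate filtering, locus clustering, precursors."""

import numpy as np
import pytest

from helpers import naive_scan, rc
from isomirkit.discovery import (
    GenomicLocus,
    NovelCandidateCluster,
    cluster_by_locus,
    extract_precursor,
    map_perfect,
    select_candidates,
)
from isomirkit.preprocess import UniqueTag


def _tag(seq, cn, lib="LD"):
    return UniqueTag(seq, {lib: cn})


def test_map_perfect_agrees_with_naive_scan(zero_noise_run):
    _, _, reference, truth = zero_noise_run
    genome = reference.genome["chr1"]
    for name, seq in truth.mature.items():
        loci = map_perfect(seq, reference.genome)
        plus = naive_scan(seq, genome)
        minus = naive_scan(rc(seq), genome)
        assert sorted(l.start for l in loci if l.strand == "+") == plus
        assert sorted(l.start for l in loci if l.strand == "-") == minus
        assert len(loci) == 1
        got = loci[0]
        want = truth.loci[name]
        assert (got.chrom, got.start, got.end, got.strand) == (
            want.chrom, want.start, want.end, want.strand,
        )


def test_absent_sequence_maps_nowhere():
    genome = {"chr1": "ACGT" * 100}
    assert map_perfect("TTTTTTTTTTTTTTTTTTT", genome) == []


def test_minus_strand_hit_reported_in_plus_coordinates():
    seq = "ATCACATTGCCAGGGATTTCC"
    genome = {"chr1": "A" * 30 + rc(seq) + "C" * 30}
    loci = map_perfect(seq, genome)
    assert len(loci) == 1
    assert (loci[0].start, loci[0].end, loci[0].strand) == (30, 51, "-")


def test_candidate_filter_cascade_boundaries():
    rng = np.random.default_rng(0)
    uniq = "".join(rng.choice(list("ACGT"), 21))
    long24 = "".join(rng.choice(list("ACGT"), 24))
    multi = "".join(rng.choice(list("ACGT"), 21))
    masked = "".join(rng.choice(list("ACGT"), 21))
    bg = "".join(rng.choice(list("ACGT"), 200))
    genome = {"chr1": bg + uniq + bg[::-1] + long24 + multi + "TT" + multi
              + "CC" + masked + bg[50:]}
    mask_start = genome["chr1"].find(masked)
    mask = [("chr1", mask_start, mask_start + len(masked))]
    tags = [
        _tag(uniq, 3),       # kept: unique, 21 nt, CN>2, unmasked
        _tag(long24, 10),    # excluded: length
        _tag(multi, 10),     # excluded: maps twice
        _tag(masked, 10),    # excluded: overlaps the annotation mask
        _tag(uniq, 2),       # excluded: CN not > 2 (boundary)
    ]
    kept = select_candidates(tags[:4], genome, mask)
    assert [t.sequence for t, _ in kept] == [uniq]
    assert select_candidates([tags[4]], genome, mask) == []


def test_candidate_filters_commute():
    """Applying the sub-filters sequentially in any order gives the same set."""
    rng = np.random.default_rng(3)
    seqs = ["".join(rng.choice(list("ACGT"), int(rng.integers(17, 26))))
            for _ in range(12)]
    genome = {"chr1": ("T" * 40).join(seqs[:9]) + "A" * 40 + seqs[0][:20]}
    mask = [("chr1", 0, 30)]
    tags = [_tag(s, int(rng.integers(1, 6))) for s in seqs]

    def f_len(items):
        return [t for t in items if 19 <= len(t) <= 23]

    def f_cn(items):
        return [t for t in items if t.total_count > 2]

    def f_map(items):
        return [t for t in items if len(map_perfect(t.sequence, genome)) == 1]

    def f_mask(items):
        out = []
        for t in items:
            loci = map_perfect(t.sequence, genome)
            if not loci or all(
                not (c == l.chrom and l.start < e and s < l.end)
                for l in loci for c, s, e in mask
            ):
                out.append(t)
        return out

    from itertools import permutations

    results = set()
    for perm in permutations([f_len, f_cn, f_map, f_mask]):
        items = list(tags)
        for f in perm:
            items = f(items)
        results.add(frozenset(t.sequence for t in items))
    assert len(results) == 1
    direct = select_candidates(tags, genome, mask)
    assert frozenset(t.sequence for t, _ in direct) == next(iter(results))


def test_overlapping_loci_cluster_with_max_cn_reference():
    a = (_tag("ACGTACGTACGTACGTACGTA", 10), GenomicLocus("chr1", 100, 121, "+"))
    b = (_tag("CGTACGTACGTACGTACGT", 5), GenomicLocus("chr1", 101, 120, "+"))
    c = (_tag("TTTTACGTACGTACGTACGTT", 7), GenomicLocus("chr1", 121, 142, "+"))
    clusters = cluster_by_locus([a, b, c])
    assert [cl.isomir_count for cl in clusters] == [2, 1]
    assert clusters[0].reference.sequence == a[0].sequence
    assert clusters[0].cluster_cn == 15


def test_opposite_strands_never_cluster():
    a = (_tag("ACGTACGTACGTACGTACGTA", 3), GenomicLocus("chr1", 100, 121, "+"))
    b = (_tag("TACGTACGTACGTACGTACGT", 3), GenomicLocus("chr1", 100, 121, "-"))
    assert len(cluster_by_locus([a, b])) == 2


def test_cluster_matches_reported_novel_cluster_shape():
    """A cluster like the validated novel miRNA Cl-38: CN 21 over 3 isomiRs
    with the max-CN member as reference."""
    ref_seq = "TCTCCGTTTGCCTGTTTTGCTGA"
    members = [
        (_tag(ref_seq, 15), GenomicLocus("chr1", 500, 523, "+")),
        (_tag(ref_seq[:-1], 4), GenomicLocus("chr1", 500, 522, "+")),
        (_tag(ref_seq[1:], 2), GenomicLocus("chr1", 501, 523, "+")),
    ]
    (cluster,) = cluster_by_locus(members)
    assert cluster.cluster_cn == 21
    assert cluster.isomir_count == 3
    assert cluster.reference.sequence == ref_seq


def test_precursor_arithmetic_with_full_flanks():
    rng = np.random.default_rng(1)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 400))}
    seq = genome["chr1"][150:171]
    cl = NovelCandidateCluster("Cl-1", [(_tag(seq, 5), GenomicLocus("chr1", 150, 171, "+"))])
    precursor, span = extract_precursor(cl, genome, flank=50)
    assert len(precursor) == 121
    assert span == (50, 71)
    assert precursor[50:71] == seq


def test_precursor_clipped_at_chromosome_start():
    rng = np.random.default_rng(2)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 300))}
    seq = genome["chr1"][10:31]
    cl = NovelCandidateCluster("Cl-1", [(_tag(seq, 5), GenomicLocus("chr1", 10, 31, "+"))])
    precursor, span = extract_precursor(cl, genome, flank=50)
    assert len(precursor) == 10 + 21 + 50
    assert span == (10, 31)


def test_minus_strand_precursor_is_reverse_complement_of_window():
    rng = np.random.default_rng(3)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 400))}
    loc = GenomicLocus("chr1", 200, 221, "-")
    seq = rc(genome["chr1"][200:221])
    cl = NovelCandidateCluster("Cl-1", [(_tag(seq, 5), loc)])
    precursor, span = extract_precursor(cl, genome, flank=50)
    assert precursor == rc(genome["chr1"][150:271])
    assert precursor[span[0] : span[1]] == seq


def test_missing_chromosome_raises():
    cl = NovelCandidateCluster(
        "Cl-1", [(_tag("ACGTACGTACGTACGTACGTA", 5), GenomicLocus("chr9", 0, 21, "+"))]
    )
    with pytest.raises(KeyError):
        extract_precursor(cl, {"chr1": "ACGT" * 100})
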