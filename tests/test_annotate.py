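"""End-tolerant matching, isomiR clustering and profile construction."""

import numpy as np
import pytest

from helpers import match_oracle, random_match_cases
from isomirkit.annotate import (
    MatureReference,
    MiRNACluster,
    assign_tags,
    build_profile,
    match_best,
    match_end_tolerant,
    per_group_predominance,
)
from isomirkit.preprocess import UniqueTag

MIR23A = MatureReference("ssc-miR-23a", "ATCACATTGCCAGGGATTTCC")


def test_identity_matches_with_zero_variants():
    m = match_end_tolerant(MIR23A.sequence, MIR23A)
    assert (m.n_5prime_variant, m.n_3prime_variant) == (0, 0)
    assert m.core_length == len(MIR23A.sequence)


def test_single_3prime_extension_counts_one_variant():
    """A 3'-extended variant of the mature matches with one terminal variant."""
    m = match_end_tolerant("ATCACATTGCCAGGGATTTCCA", MIR23A)
    assert m is not None
    assert m.n_5prime_variant == 0 and m.n_3prime_variant == 1


def test_five_nt_extension_exceeds_tolerance():
    assert match_end_tolerant(MIR23A.sequence + "ACGTA", MIR23A) is None


def test_truncation_counts_toward_tolerance():
    # drop the last two reference nucleotides: two 3' variants
    m = match_end_tolerant(MIR23A.sequence[:-2], MIR23A)
    assert m.n_3prime_variant == 2 and m.n_5prime_variant == 0


def test_internal_mismatch_not_tolerated_by_default():
    q = list(MIR23A.sequence)
    q[10] = "A" if q[10] != "A" else "C"
    assert match_end_tolerant("".join(q), MIR23A) is None
    assert match_end_tolerant("".join(q), MIR23A, allow_internal_mismatch=1) is not None


def test_empty_query_rejected():
    with pytest.raises(ValueError):
        match_end_tolerant("", MIR23A)


@pytest.mark.parametrize("seed", [0, 1])
def test_matcher_agrees_with_brute_force_oracle(seed):
    """Matcher == exhaustive (offset, trim) enumeration on random sequences."""
    rng = np.random.default_rng(seed)
    for q, r in random_match_cases(rng, 400):
        got = match_end_tolerant(q, MatureReference("ssc-x", r))
        key = None if got is None else (got.cost, -got.core_length, abs(got.offset))
        assert key == match_oracle(q, r), (q, r)


def test_raising_tolerance_never_loses_matches():
    rng = np.random.default_rng(7)
    cases = random_match_cases(rng, 200)
    for q, r in cases:
        ref = MatureReference("ssc-x", r)
        matched = [match_end_tolerant(q, ref, tolerance=t) is not None
                   for t in range(0, 7)]
        # once matched, stays matched at any higher tolerance
        assert matched == sorted(matched)


def test_porcine_reference_wins_ties():
    seq = "ATCACATTGCCAGGGATTTCC"
    refs = [MatureReference("bta-miR-23a", seq), MatureReference("ssc-miR-23a", seq)]
    m = match_best(seq, refs)
    assert m.mirna_id == "ssc-miR-23a"


def test_assignment_partitions_tag_copy_number():
    rng = np.random.default_rng(4)
    refs = [
        MatureReference(f"ssc-miR-{i}", "".join(rng.choice(list("ACGT"), 22)))
        for i in range(5)
    ]
    tags = []
    for i, ref in enumerate(refs):
        tags.append(UniqueTag(ref.sequence, {"LD": 5 + i}))
        tags.append(UniqueTag(ref.sequence + "A", {"ME": 3}))
    tags.append(UniqueTag("".join(rng.choice(list("ACGT"), 25)), {"LD": 9}))
    clusters, unannotated = assign_tags(tags, refs)
    total = sum(t.total_count for t in tags)
    assert sum(c.cluster_cn for c in clusters) + sum(
        t.total_count for t in unannotated
    ) == total
    seen = [t.sequence for c in clusters for t in c.members] + [
        t.sequence for t in unannotated
    ]
    assert len(seen) == len(set(seen)) == len(tags)


def test_predominant_isomir_and_divergence_flag():
    """The most expressed variant names the cluster and may diverge from the
    database sequence (e.g. a 3'-extended variant out-expressing the mature)."""
    cluster = MiRNACluster(
        "ssc-miR-23a",
        MIR23A.sequence,
        members=[
            UniqueTag("ATCACATTGCCAGGGATTTCCA", {"LD": 3116}),
            UniqueTag(MIR23A.sequence, {"LD": 622}),
        ],
    )
    assert cluster.predominant.sequence == "ATCACATTGCCAGGGATTTCCA"
    assert cluster.diverges_from_reference
    assert cluster.cluster_cn == 3738
    assert cluster.isomir_count == 2


def test_single_member_equal_to_database_does_not_diverge():
    cluster = MiRNACluster(
        "ssc-miR-23a", MIR23A.sequence, members=[UniqueTag(MIR23A.sequence, {"LD": 9})]
    )
    assert not cluster.diverges_from_reference


def test_profile_excludes_clusters_below_cn_three():
    small = MiRNACluster("ssc-a", "ACGT" * 5, [UniqueTag("ACGT" * 5, {"LD": 2})])
    big = MiRNACluster("ssc-b", "AAGT" * 5, [UniqueTag("AAGT" * 5, {"LD": 10})])
    prof = build_profile([small, big], min_cluster_cn=3, total_reads=100)
    assert list(prof["mirna_id"]) == ["ssc-b"]
    assert prof.loc[0, "pct_share"] == 10.0


def test_per_group_predominance_follows_group_skew():
    cluster = MiRNACluster(
        "ssc-x",
        "ACGTACGTACGTACGTACGT",
        members=[
            UniqueTag("ACGTACGTACGTACGTACGT", {"IB": 50, "ME": 2}),
            UniqueTag("ACGTACGTACGTACGTACG", {"IB": 1, "ME": 40}),
        ],
    )
    groups = {"IB": "EU", "ME": "AS"}
    totals = {"IB": 1000, "ME": 1000}
    pred = per_group_predominance(cluster, groups, totals)
    assert pred["EU"] == "ACGTACGTACGTACGTACGT"
    assert pred["AS"] == "ACGTACGTACGTACGTACG"


def test_per_group_predominance_tie_breaks_lexicographically():
    cluster = MiRNACluster(
        "ssc-x",
        "CCCCCCCCCCCCCCCCCCCC",
        members=[
            UniqueTag("CCCCCCCCCCCCCCCCCCCC", {"IB": 5}),
            UniqueTag("ACCCCCCCCCCCCCCCCCCC", {"IB": 5}),
        ],
    )
    pred = per_group_predominance(cluster, {"IB": "EU"}, {"IB": 100})
    assert pred["EU"] == "ACCCCCCCCCCCCCCCCCCC"


def test_group_with_no_counts_has_no_predominant():
    cluster = MiRNACluster(
        "ssc-x", "ACGT" * 5, [UniqueTag("ACGT" * 5, {"IB": 5})]
    )
    pred = per_group_predominance(
        cluster, {"IB": "EU", "ME": "AS"}, {"IB": 100, "ME": 100}
    )
    assert pred["AS"] is None


def test_isomir_detail_lists_members_aligned_to_database_sequence():
    from isomirkit.annotate import isomir_detail_frame

    cluster = MiRNACluster(
        "ssc-miR-23a",
        MIR23A.sequence,
        members=[
            UniqueTag("ATCACATTGCCAGGGATTTCCA", {"LD": 3116}),  # 3' +1
            UniqueTag(MIR23A.sequence, {"LD": 622}),
            UniqueTag("TCACATTGCCAGGGATTTCC", {"LD": 40}),  # 5' -1
        ],
    )
    detail = isomir_detail_frame([cluster])
    assert list(detail["CN"]) == [3116, 622, 40]  # descending
    assert detail["is_database_sequence"].tolist() == [False, True, False]
    # 5'-truncated member is padded one column right of the database mature
    aligned = dict(zip(detail["sequence"], detail["aligned"]))
    assert aligned["TCACATTGCCAGGGATTTCC"].startswith(" T")
    assert aligned[MIR23A.sequence].strip() == MIR23A.sequence
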