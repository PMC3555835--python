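"""Standard curves, geNorm reference stability and relative expression."""

import numpy as np
import pandas as pd
import pytest

from isomirkit.qpcr import (
    fit_standard_curve,
    genorm_m,
    genorm_stability,
    relative_expression,
    synthetic_curve,
)


def test_analytic_curve_gives_perfect_efficiency():
    """Cq = 30 - 3.321928 log10(d) corresponds to exact doubling (E = 100%)."""
    d = 10.0 ** -np.arange(5)
    cq = 30.0 - 3.321928 * np.log10(d)
    curve = fit_standard_curve(d, cq)
    assert curve.efficiency == pytest.approx(1.0, abs=1e-6)
    assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
    assert curve.qc_pass


@pytest.mark.parametrize("efficiency", [0.90, 1.00, 1.10])
def test_efficiency_round_trips_through_fit(efficiency):
    d, cq = synthetic_curve(efficiency)
    curve = fit_standard_curve(d, cq)
    assert curve.efficiency == pytest.approx(efficiency, abs=1e-6)
    assert curve.qc_pass  # 90% and 110% are inclusive QC boundaries


def test_slope_for_ninety_percent_efficiency():
    # inverting E = 10^(-1/slope) - 1 at E = 0.90: slope = -1/log10(1.9)
    d, cq = synthetic_curve(0.90)
    curve = fit_standard_curve(d, cq)
    assert curve.slope == pytest.approx(-1.0 / np.log10(1.9), rel=1e-9)


def test_noisy_curve_fails_qc_on_r_squared():
    rng = np.random.default_rng(0)
    d = 10.0 ** -np.arange(6)
    cq = 30.0 - 3.32 * np.log10(d) + rng.normal(0, 2.5, size=6)
    curve = fit_standard_curve(d, cq)
    assert curve.r_squared < 0.99
    assert not curve.qc_pass


def test_out_of_range_efficiency_fails_qc():
    d, cq = synthetic_curve(1.25)
    assert not fit_standard_curve(d, cq).qc_pass


def test_too_few_dilution_levels_rejected():
    with pytest.raises(ValueError):
        fit_standard_curve([1.0, 0.1], [20.0, 23.3])
    with pytest.raises(ValueError):
        fit_standard_curve([1.0, 1.0, 1.0], [20.0, 20.1, 19.9])


def test_proportional_references_have_zero_m():
    samples = [f"s{i}" for i in range(5)]
    base = np.array([1.0, 2.0, 0.5, 4.0, 1.5])
    q = pd.DataFrame([base, 3.0 * base], index=["ref_a", "ref_b"], columns=samples)
    m = genorm_m(q)
    assert np.allclose(m, 0.0)


def test_genorm_m_matches_direct_recomputation():
    """M for a 3x4 toy matrix equals a spreadsheet-style direct evaluation."""
    q = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 4.0],
            "s2": [2.0, 3.0, 1.0],
            "s3": [0.5, 1.0, 2.0],
            "s4": [1.5, 2.5, 8.0],
        },
        index=["a", "b", "c"],
    )
    logq = np.log2(q)
    expected = {}
    for j in ["a", "b", "c"]:
        sds = []
        for k in ["a", "b", "c"]:
            if k == j:
                continue
            ratios = logq.loc[j] - logq.loc[k]
            sds.append(ratios.std(ddof=1))
        expected[j] = np.mean(sds)
    m = genorm_m(q)
    for j in ["a", "b", "c"]:
        assert m[j] == pytest.approx(expected[j], rel=1e-12)


def test_single_retained_reference_nf_is_its_own_quantities():
    # construct three references whose pairwise log-ratio SDs are ~1, ~4, ~4.5,
    # so that exactly one M value falls below a 2.6 threshold
    y = np.array([-1.0, 0.0, 1.0])
    w = np.array([1.0, -2.0, 1.0])
    alpha, beta = -1.625, np.sqrt(13.359375 / 3.0)
    la, lb, lc = np.zeros(3), y, alpha * y + beta * w
    q = pd.DataFrame(
        np.exp2([la, lb, lc]), index=["a", "b", "c"], columns=["s1", "s2", "s3"]
    )
    m = genorm_m(q)
    assert m["a"] < 2.6 < min(m["b"], m["c"])
    res = genorm_stability(q, m_threshold=2.6)
    assert res.retained == ["a"]
    assert np.allclose(res.nf, q.loc["a"])


def test_iterative_mode_drops_least_stable_reference():
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(6)]
    stable = rng.uniform(1, 2, size=6)
    q = pd.DataFrame(
        {
            "good1": stable,
            "good2": stable * 2.0,
            "wild": np.exp2(rng.normal(0, 4, size=6)),
        }
    ).T
    q.columns = samples
    res = genorm_stability(q, m_threshold=1.5, iterative=True)
    assert set(res.retained) == {"good1", "good2"}


def test_relative_expression_min_reference_properties():
    samples = ["s1", "s2", "s3", "s4"]
    q = pd.DataFrame(
        [[1.0, 2.0, 4.0, 8.0], [2.0, 4.0, 8.0, 16.0]],
        index=["a", "b"], columns=samples,
    )
    res = genorm_stability(q)
    target = pd.Series([3.0, 6.0, 12.0, 24.0], index=samples)
    rel = relative_expression(target, res)
    assert np.allclose(rel["fc"].min(), 1.0)
    assert (rel["fc"] >= 1.0).all()
    assert rel["log2_fc"].min() == 0.0


def test_identical_samples_all_have_unit_fold_change():
    q = pd.DataFrame(
        [[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], index=["a", "b"],
        columns=["s1", "s2", "s3"],
    )
    res = genorm_stability(q)
    rel = relative_expression(pd.Series([5.0, 5.0, 5.0], index=q.columns), res)
    assert np.allclose(rel["fc"], 1.0)
    assert np.allclose(rel["log2_fc"], 0.0)


def test_doubled_sample_has_log2_fc_one():
    q = pd.DataFrame(
        [[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["s1", "s2"]
    )
    res = genorm_stability(q)
    rel = relative_expression(pd.Series([1.0, 2.0], index=["s1", "s2"]), res)
    assert rel.loc["s2", "fc"] == pytest.approx(2.0)
    assert rel.loc["s2", "log2_fc"] == pytest.approx(1.0)


def test_normalisation_is_scale_invariant():
    """Scaling one sample's references and target by c leaves fold changes
    between samples unchanged."""
    rng = np.random.default_rng(7)
    q = pd.DataFrame(
        rng.uniform(0.5, 4.0, size=(3, 5)),
        index=["a", "b", "c"], columns=[f"s{i}" for i in range(5)],
    )
    target = pd.Series(rng.uniform(0.5, 4.0, size=5), index=q.columns)
    res = genorm_stability(q, m_threshold=100.0)
    rel = relative_expression(target, res)

    c = 7.3
    q2, t2 = q.copy(), target.copy()
    q2["s2"] *= c
    t2["s2"] *= c
    res2 = genorm_stability(q2, m_threshold=100.0)
    assert res2.nf["s2"] == pytest.approx(res.nf["s2"] * c)
    rel2 = relative_expression(t2, res2)
    assert np.allclose(rel2["fc"], rel["fc"])


def test_genorm_invariant_to_relabeling():
    rng = np.random.default_rng(8)
    q = pd.DataFrame(
        rng.uniform(0.5, 4.0, size=(4, 5)),
        index=list("abcd"), columns=[f"s{i}" for i in range(5)],
    )
    m = genorm_m(q)
    perm = q.loc[["c", "a", "d", "b"], [f"s{i}" for i in (3, 1, 4, 0, 2)]]
    m2 = genorm_m(perm)
    for ref in "abcd":
        assert m2[ref] == pytest.approx(m[ref], rel=1e-12)


def test_nonpositive_quantities_rejected():
    q = pd.DataFrame([[1.0, 0.0], [1.0, 2.0]], index=["a", "b"], columns=["s1", "s2"])
    with pytest.raises(ValueError):
        genorm_m(q)


def test_analyze_cq_table_recovers_known_quantities():
    """Round trip: Cq values generated from known curves and quantities come
    back as the same quantities, geNorm screen included."""
    import itertools

    from isomirkit.qpcr import analyze_cq_table

    rng = np.random.default_rng(6)
    samples = [f"s{i}" for i in range(4)]
    assays = {"let7a": 1.0, "mir25": 0.95, "target": 1.05}  # efficiencies
    truth = {
        ("let7a", s): q for s, q in zip(samples, [1.0, 2.0, 0.5, 1.0])
    }
    truth |= {("mir25", s): 3.0 * truth[("let7a", s)] for s in samples}
    truth |= {
        ("target", s): q for s, q in zip(samples, [0.25, 0.5, 1.0, 2.0])
    }
    rows = []
    for assay, eff in assays.items():
        slope = -1.0 / np.log10(1.0 + eff)
        intercept = 28.0
        for d in 10.0 ** -np.arange(4):
            rows.append({"sample": "pool", "assay": assay, "replicate": 1,
                         "Cq": intercept + slope * np.log10(d), "dilution": d})
        for s, rep in itertools.product(samples, (1, 2)):
            q = truth[(assay, s)]
            rows.append({"sample": s, "assay": assay, "replicate": rep,
                         "Cq": intercept + slope * np.log10(q), "dilution": None})
    df = pd.DataFrame(rows)
    curves, genorm, expression = analyze_cq_table(df, ["let7a", "mir25"])
    assert curves.set_index("assay")["qc_pass"].all()
    assert np.allclose(genorm.m_values, 0.0, atol=1e-9)  # proportional refs
    # NF = gmean of the two references; target fc relative to its lowest sample
    tgt = expression[expression["assay"] == "target"].set_index("sample")
    fc = tgt.groupby("sample")["fc"].mean()
    nf_shape = {s: np.sqrt(truth[("let7a", s)] * truth[("mir25", s)]) for s in samples}
    want = {s: truth[("target", s)] / nf_shape[s] for s in samples}
    floor = min(want.values())
    for s in samples:
        assert fc[s] == pytest.approx(want[s] / floor, rel=1e-6)


def test_analyze_cq_table_requires_dilution_rows():
    from isomirkit.qpcr import analyze_cq_table

    df = pd.DataFrame(
        {"sample": ["s1"] * 2, "assay": ["a", "b"], "Cq": [20.0, 21.0]}
    )
    with pytest.raises(ValueError):
        analyze_cq_table(df, ["a"])
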