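"""Normality-gated descriptives, group comparisons, LOD censoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from synoquant import censor_below_lod, compare_group_values, describe, dunn_test
from synoquant.stats import compare_analytes, compare_groups


def test_describe_degenerate_sample_routes_to_median():
    res = describe({"a": [5, 5, 5, 5]})
    d = res.per_group["a"]
    assert d.sd == 0.0
    assert d.normal is None  # gate indeterminate
    assert res.form == "median_iqr"
    assert (d.median, d.q1, d.q3) == (5.0, 5.0, 5.0)


def test_describe_quantiles_linear_interpolation():
    res = describe({"a": [1, 2, 3, 4, 100]})
    d = res.per_group["a"]
    assert (d.median, d.q1, d.q3) == (3.0, 2.0, 4.0)


def test_describe_small_group_is_indeterminate():
    res = describe({"a": [1.0, 2.0]})
    assert res.per_group["a"].normal is None
    assert res.form == "median_iqr"


def test_describe_large_gaussian_passes_gate(rng):
    x = rng.normal(10.0, 2.0, size=200)
    res = describe({"a": x})
    d = res.per_group["a"]
    assert d.normal is True and res.form == "mean_sd"
    assert abs(d.mean - 10.0) < 3 * 2.0 / np.sqrt(200)


def test_constant_groups_skipped_degenerate():
    res = compare_group_values({"a": [3.0] * 5, "b": [3.0] * 5, "c": [3.0] * 5})
    assert res.omnibus_p == 1.0
    assert "degenerate" in res.note
    assert not any(p.significant for p in res.pairwise)
    assert "degenerate" in res.summary()


def test_shifted_group_detected_and_matches_permutation_oracle(rng):
    """One group shifted by 3 SD: its pairwise comparisons are significant,
    and the ANOVA omnibus p agrees with a 10^4 label-permutation oracle."""
    groups = {
        "a": rng.normal(0, 1, 10),
        "b": rng.normal(0, 1, 10),
        "c": rng.normal(3, 1, 10),
    }
    res = compare_group_values(groups)
    c_pairs = [p for p in res.pairwise if "c" in (p.group_a, p.group_b)]
    assert all(p.significant for p in c_pairs)

    pooled = np.concatenate(list(groups.values()))
    sizes = [len(v) for v in groups.values()]
    obs = sps.f_oneway(*groups.values()).statistic
    perm_rng = np.random.default_rng(0)
    count = 0
    n_perm = 10_000
    for _ in range(n_perm):
        perm = perm_rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if sps.f_oneway(*parts).statistic >= obs:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    assert abs(p_perm - res.omnibus_p) <= 0.02


def test_two_group_routes(rng):
    gauss = {"a": rng.normal(0, 1, 12), "b": rng.normal(0.2, 1, 12)}
    res = compare_group_values(gauss)
    assert res.omnibus_test == "Welch t-test"
    skewed = {"a": rng.lognormal(0, 1.5, 12), "b": rng.lognormal(0, 1.5, 12)}
    res2 = compare_group_values(skewed)
    assert res2.omnibus_test == "Mann-Whitney rank-sum"


def test_adjusted_p_never_below_unadjusted(rng):
    """Tukey and Dunn adjusted p-values dominate their raw counterparts on
    both test routes, across random datasets."""
    for rep in range(20):
        if rep % 2:
            groups = {g: rng.normal(rng.normal(), 1, 10) for g in "abc"}
        else:
            groups = {g: rng.lognormal(0, 1.6, 10) for g in "abc"}
        res = compare_group_values(groups)
        for pc in res.pairwise:
            assert pc.p_adjusted >= pc.p_unadjusted - 1e-12
            assert 0 <= pc.p_unadjusted <= 1 and 0 <= pc.p_adjusted <= 1


def test_dunn_hand_computed_example():
    """Groups [1..3], [4..6], [7..9]: mean ranks 2, 5, 8, no ties,
    var_base = 9*10/12 = 7.5, SE = sqrt(5)."""
    out = dunn_test([np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])])
    by_pair = {(i, j): (z, p, padj) for i, j, z, p, padj in out}
    se = math.sqrt(5.0)
    z12 = (2 - 5) / se
    assert by_pair[(0, 1)][0] == pytest.approx(z12)
    assert by_pair[(0, 1)][1] == pytest.approx(2 * sps.norm.sf(abs(z12)))
    assert by_pair[(0, 2)][0] == pytest.approx((2 - 8) / se)
    assert by_pair[(0, 2)][2] == pytest.approx(
        min(1.0, 3 * 2 * sps.norm.sf(6 / se))
    )


def test_gate_is_deterministic(rng):
    x = {g: rng.normal(0, 1, 10) for g in "abc"}
    r1 = compare_group_values(x)
    r2 = compare_group_values(x)
    assert r1.omnibus_test == r2.omnibus_test
    assert r1.omnibus_p == r2.omnibus_p


def test_compare_groups_on_long_table(rng):
    rows = []
    for g, mu in [("F", 0.0), ("CTRL", 0.0), ("OA", 4.0)]:
        for i, v in enumerate(rng.normal(mu, 1, 8)):
            rows.append(
                {"sample_id": f"{g}{i}", "group": g, "region": "ICL",
                 "variable": "x", "value": v, "flag": "ok"}
            )
    rows.append(
        {"sample_id": "F0", "group": "F", "region": "ICL", "variable": "x",
         "value": float("nan"), "flag": "missing"}
    )
    table = pd.DataFrame(rows)
    res = compare_groups(table, "x", region="ICL")
    assert res.significant
    assert {d.n for d in res.descriptives.per_group.values()} == {8}


def test_censoring_rules():
    rows = []
    for i in range(10):
        rows.append({"sample_id": f"s{i}", "group": "CTRL", "analyte": "low", "value": 2.0})
        rows.append({"sample_id": f"s{i}", "group": "CTRL", "analyte": "edge", "value": 5.0})
        rows.append(
            {"sample_id": f"s{i}", "group": "CTRL", "analyte": "mixed",
             "value": 1.0 if i < 4 else 10.0}
        )
    df = pd.DataFrame(rows)
    res = censor_below_lod(df, {"low": 5.0, "edge": 5.0, "mixed": 5.0})
    assert res.fully_censored == ["low"]
    assert res.censored_fraction["edge"] == 0.0  # exactly at LOD: not censored
    assert res.censored_fraction["mixed"] == pytest.approx(0.4)
    testable = res.testable()
    assert "low" not in set(testable["analyte"])
    assert (testable[testable["analyte"] == "mixed"]["value"] == 10.0).all()
    report = res.below_lod_report()
    assert report["below_lod_analytes"] == ["low"]


def test_missing_lod_names_analyte():
    df = pd.DataFrame(
        [{"sample_id": "s", "group": "g", "analyte": "A", "value": 1.0}]
    )
    with pytest.raises(ValueError, match="A"):
        censor_below_lod(df, {})
    with pytest.raises(ValueError, match="A"):
        censor_below_lod(df)


def test_compare_analytes_skips_fully_censored(rng):
    rows = []
    for g in ("F", "CTRL"):
        for i in range(6):
            rows.append({"sample_id": f"{g}{i}", "group": g, "analyte": "dead",
                         "value": 0.1, "lod": 1.0})
            rows.append({"sample_id": f"{g}{i}", "group": g, "analyte": "alive",
                         "value": float(rng.lognormal(2, 0.5)), "lod": 1.0})
    censored = censor_below_lod(pd.DataFrame(rows))
    results, report = compare_analytes(censored)
    assert [r.variable for r in results] == ["alive"]
    assert report["below_lod_analytes"] == ["dead"]
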