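"""Tests for the multiple-comparison machinery and selectivity classification."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grkbret.calibration import tukey_fwer
from grkbret.selectivity import (
    anova_oneway,
    call_precoupling,
    call_selectivity,
    canberra_distance,
    classify_matrix,
    dunnett_test,
    hierarchical_cluster,
    pairwise_bonferroni,
    transform_p_matrix,
    tukey_hsd,
)
from grkbret.types import ComparisonResult, ConfigurationError, DataError

from oracles import anova_closed_form, canberra_loop_oracle


class TestAnova:
    def test_two_groups_equals_squared_t(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        F, p = anova_oneway(a, b)
        t = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(float(t.statistic) ** 2, rel=1e-10)
        assert p == pytest.approx(float(t.pvalue), rel=1e-10)

    def test_all_equal(self):
        F, p = anova_oneway([1.0, 1.0], [1.0, 1.0, 1.0])
        assert F == 0.0 and p == 1.0

    def test_small_group_error(self):
        with pytest.raises(DataError):
            anova_oneway([1.0], [1.0, 2.0])

    def test_matches_textbook_closed_form(self, rng):
        groups = [rng.normal(i * 0.3, 1.0, size=n) for i, n in enumerate((4, 5, 3, 6))]
        F, p = anova_oneway(*groups)
        F2, p2 = anova_closed_form([list(g) for g in groups])
        assert F == pytest.approx(F2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)


class TestBonferroni:
    groups = {
        "ref": np.array([1.0, 1.05, 0.95]),
        "a": np.array([1.5, 1.55, 1.45]),
        "b": np.array([1.02, 0.97, 1.01]),
    }

    def test_single_contrast_unchanged(self):
        res = pairwise_bonferroni(self.groups, [("a", "ref")])
        assert res[0].p_adjusted == res[0].p_unadjusted

    def test_cap_at_one(self):
        res = pairwise_bonferroni(self.groups, [("b", "ref")] * 5)
        assert all(r.p_adjusted <= 1.0 for r in res)

    def test_adjusted_at_least_unadjusted(self, rng):
        groups = {k: rng.normal(size=4) for k in "abcd"}
        res = pairwise_bonferroni(groups, [("a", "b"), ("c", "d"), ("a", "d")])
        for r in res:
            assert r.p_unadjusted <= r.p_adjusted <= 1.0

    def test_unknown_condition(self):
        with pytest.raises(ConfigurationError):
            pairwise_bonferroni(self.groups, [("a", "zzz")])

    def test_direction_sign(self):
        res = pairwise_bonferroni(self.groups, [("a", "ref"), ("ref", "a")])
        assert res[0].direction == 1 and res[1].direction == -1


class TestDunnett:
    def test_single_comparison_reduces_to_t(self, rng):
        a = rng.normal(0.5, 1.0, 6)
        control = rng.normal(0.0, 1.0, 6)
        p = dunnett_test({"a": a}, control=control)["a"]
        ref = float(stats.ttest_ind(a, control, equal_var=True).pvalue)
        assert p == pytest.approx(ref, abs=1e-3)

    def test_adjusted_at_least_unadjusted(self, rng):
        groups = {k: rng.normal(size=4) for k in "abc"}
        control = rng.normal(size=4)
        adj = dunnett_test(groups, control=control)
        for k, p_adj in adj.items():
            p_raw = float(stats.ttest_ind(groups[k], control, equal_var=True).pvalue)
            assert p_adj >= p_raw - 1e-3

    def test_missing_control(self):
        with pytest.raises(ConfigurationError):
            dunnett_test({"a": [1, 2, 3]}, control="zzz")

    def test_one_sided_detects_elevation(self, rng):
        groups = {"up": rng.normal(1.0, 0.1, 4), "flat": rng.normal(0.0, 0.1, 4)}
        control = rng.normal(0.0, 0.1, 4)
        adj = dunnett_test(groups, control=control, sidedness="greater")
        assert adj["up"] < 0.01 < adj["flat"]


class TestTukey:
    def test_two_groups_equals_pooled_t(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        p = tukey_hsd({"a": a, "b": b})[("a", "b")]
        ref = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        assert p == pytest.approx(ref, rel=1e-6)

    def test_matches_scipy_reference(self, rng):
        groups = {k: rng.normal(size=4) for k in "abcd"}
        ours = tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups.values())
        names = list(groups)
        for i in range(4):
            for j in range(i + 1, 4):
                assert ours[(names[i], names[j])] == pytest.approx(
                    float(ref.pvalue[i, j]), abs=1e-6
                )

    def test_all_equal_noise_free(self):
        p = tukey_hsd({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert all(v == 1.0 for v in p.values())

    def test_fwer_decision_rule_matches_api(self, rng):
        # the vectorized calibration rule (q_max > crit) must agree with
        # "any adjusted p < alpha" from the per-call API
        k, n, alpha = 4, 3, 0.05
        df = k * (n - 1)
        crit = stats.studentized_range.ppf(1 - alpha, k, df)
        for _ in range(25):
            groups = {f"g{i}": rng.normal(size=n) for i in range(k)}
            pvals = tukey_hsd(groups)
            means = np.array([np.mean(v) for v in groups.values()])
            mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
            q_max = (means.max() - means.min()) / np.sqrt(mse / n)
            assert (min(pvals.values()) < alpha) == (q_max > crit)

    def test_fwer_helper_runs(self):
        assert 0.0 <= tukey_fwer(200, seed=1) <= 0.2


class TestTransform:
    def _res(self, p, direction, contrast=("g", "ref")):
        return ComparisonResult(label="x", contrast=contrast, direction=direction,
                                p_unadjusted=p, p_adjusted=min(1, 4 * p), method="m")

    def test_values(self):
        rows = {"r1": [self._res(0.01, 1)], "r2": [self._res(1.0, 1)],
                "r3": [self._res(1e-30, -1)]}
        m = transform_p_matrix(rows, [("g", "ref")])
        assert m.loc["r1"].iloc[0] == pytest.approx(2.0)
        assert m.loc["r2"].iloc[0] == pytest.approx(0.0)
        assert m.loc["r3"].iloc[0] == pytest.approx(-16.0)

    def test_missing_contrast_is_zero(self):
        m = transform_p_matrix({"r1": []}, [("g", "ref")])
        assert m.loc["r1"].iloc[0] == 0.0


class TestCanberra:
    def test_identical(self):
        assert canberra_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_value(self):
        assert canberra_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_zero_zero_convention(self):
        assert canberra_distance([0.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0 / 3.0)

    def test_loop_oracle(self, rng):
        for _ in range(50):
            u = rng.normal(size=6)
            v = rng.normal(size=6)
            assert canberra_distance(u, v) == pytest.approx(
                canberra_loop_oracle(u, v), abs=1e-12
            )

    def test_symmetry(self, rng):
        u, v = rng.normal(size=5), rng.normal(size=5)
        assert canberra_distance(u, v) == canberra_distance(v, u)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            canberra_distance([1.0], [1.0, 2.0])


class TestClustering:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, -5.0, 0.5]],
            index=["a", "b", "far"],
        )
        Z, order, newick = hierarchical_cluster(m)
        assert Z[0, 2] == 0.0  # first merge at distance 0
        assert abs(order.index("a") - order.index("b")) == 1  # pair stays adjacent
        assert "far" in newick

    def test_deterministic(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 4)),
                         index=[f"r{i}" for i in range(6)])
        out1 = hierarchical_cluster(m)
        out2 = hierarchical_cluster(m)
        assert out1[1] == out2[1] and out1[2] == out2[2]

    def test_single_row_trivial(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["only"])
        Z, order, newick = hierarchical_cluster(m)
        assert Z is None and order == ["only"]


def _contrast_results(sig_map, direction_map=None):
    direction_map = direction_map or {}
    out = []
    for g, sig in sig_map.items():
        out.append(ComparisonResult(
            label="pair", contrast=(f"dQ-GRK+{g}", "dQ-GRK+EV"),
            direction=direction_map.get(g, 1),
            p_unadjusted=0.001 if sig else 0.5,
            p_adjusted=0.004 if sig else 1.0, method="bonferroni",
        ))
    return out


class TestCallSelectivity:
    def test_all_significant(self):
        res = _contrast_results({"GRK2": True, "GRK3": True, "GRK5": True,
                                 "GRK6": True})
        assert call_selectivity(res) == "GRK2/3/5/6"

    def test_only_grk2_and_3(self):
        res = _contrast_results({"GRK2": True, "GRK3": True, "GRK5": False,
                                 "GRK6": False})
        assert call_selectivity(res) == "GRK2/3"

    def test_none_significant(self):
        res = _contrast_results({g: False for g in ("GRK2", "GRK3", "GRK5", "GRK6")})
        assert call_selectivity(res) == "unclassified"

    def test_significant_negative_does_not_count(self):
        res = _contrast_results(
            {"GRK2": True, "GRK3": False, "GRK5": True, "GRK6": False},
            direction_map={"GRK5": -1},
        )
        assert call_selectivity(res) == "GRK2/3"

    def test_order_invariance(self):
        res = _contrast_results({"GRK2": True, "GRK3": False, "GRK5": True,
                                 "GRK6": False})
        assert call_selectivity(res) == call_selectivity(list(reversed(res)))

    def test_missing_contrast(self):
        res = _contrast_results({"GRK2": True, "GRK3": True, "GRK5": True})
        with pytest.raises(ConfigurationError):
            call_selectivity(res)


class TestPrecoupling:
    def test_planted_elevation_flagged(self, rng):
        baselines = {
            "dQ-GRK+EV": rng.normal(1.0, 0.05, 3),
            "dQ-GRK+GRK2": rng.normal(1.5, 0.05, 3),
            "dQ-GRK+GRK3": rng.normal(1.0, 0.05, 3),
        }
        out = call_precoupling(baselines)
        assert out["flags"]["GRK2"] and not out["flags"]["GRK3"]

    def test_reference_not_flagged(self, rng):
        baselines = {"dQ-GRK+EV": rng.normal(1.0, 0.05, 3),
                     "dQ-GRK+GRK2": rng.normal(1.0, 0.05, 3)}
        out = call_precoupling(baselines)
        assert "dQ-GRK+EV" not in out["flags"]

    def test_missing_reference(self):
        with pytest.raises(ConfigurationError):
            call_precoupling({"dQ-GRK+GRK2": [1, 2, 3]})

    def test_dampened_flag(self, rng):
        baselines = {"dQ-GRK+EV": rng.normal(1.0, 0.02, 3),
                     "dQ-GRK+GRK2": rng.normal(1.4, 0.02, 3)}
        nets = {"dQ-GRK+EV": [1.10, 1.12, 1.11], "dQ-GRK+GRK2": [1.02, 1.03, 1.00]}
        out = call_precoupling(baselines, net_folds=nets)
        assert out["dampened"]["GRK2"]


class TestClassifyMatrix:
    def test_planted_groups_recovered_strong_effect(self):
        from grkbret.synth import generate_condition_matrix

        matrix, truth = generate_condition_matrix(3, seed=7, effect_sds=6.0)
        res = classify_matrix(matrix)
        for call in res["calls"]:
            assert call.group == truth[call.pair]

    def test_heatmap_columns_are_grk_contrasts(self):
        from grkbret.synth import generate_condition_matrix

        matrix, _ = generate_condition_matrix(2, seed=0)
        res = classify_matrix(matrix)
        assert res["heatmap"].shape == (4, 4)
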