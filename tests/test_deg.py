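import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ucptx import io
from ucptx.deg import (
    KalZDifferentialExpression,
    QuantileNormalizer,
    call_degs,
    intersect_degs,
    kal_z_test,
    log2_fold_change,
    quantile_normalize,
    rpkm,
    rpkm_table,
)


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (1000, 1000, 1_000_000, 1000.0),
            (0, 1234, 5_000_000, 0.0),
            (50, 2500, 5_000_000, 4.0),
        ],
    )
    def test_unit_cases(self, count, length, total, expected):
        assert rpkm(count, length, total) == pytest.approx(expected)

    @pytest.mark.parametrize("length,total", [(0, 1e6), (-10, 1e6), (1000, 0)])
    def test_invalid_inputs(self, length, total):
        with pytest.raises(ValueError):
            rpkm(10, length, total)

    @given(
        count=st.integers(0, 10_000),
        length=st.integers(200, 5386),
        total=st.integers(10_000, 10_000_000),
        factor=st.integers(2, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_joint_scaling(self, count, length, total, factor):
        """Scaling counts and library total by the same factor leaves RPKM fixed."""
        assert rpkm(count * factor, length, total * factor) == pytest.approx(
            rpkm(count, length, total)
        )


class TestQuantileNormalize:
    def test_two_column_hand_computation(self):
        table = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(table)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_identical_columns_are_fixed_point(self):
        table = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(table), table)

    def test_ties_get_mean_of_rank_positions(self):
        table = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 4.0]})
        out = quantile_normalize(table)
        # tied values share average rank 1.5 -> mean of the two rank means
        assert out["a"].tolist() == [2.0, 2.0]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_columns_share_sorted_values(self, seed):
        """Definitional postcondition: all columns identical after sorting
        (continuous inputs, so ties have probability zero)."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1e6, size=(7, 3))
        out = quantile_normalize(pd.DataFrame(values, columns=list("abc")))
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])
        # and each column's sorted values equal the mean of input sorted values
        mean_sorted = np.sort(values, axis=0).mean(axis=1)
        assert np.allclose(sorted_cols[:, 0], mean_sorted)

    def test_transformer_matches_function(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.uniform(0, 100, (20, 3)), columns=list("abc"))
        model = QuantileNormalizer().fit(table)
        pd.testing.assert_frame_equal(model.transform(table), quantile_normalize(table))


class TestKalZTest:
    def test_equal_proportions_give_zero(self):
        z, p = kal_z_test(10, 1000, 20, 2000)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        z, _ = kal_z_test(30, 10_000, 10, 10_000)
        assert z == pytest.approx(3.166, abs=1e-3)

    def test_antisymmetric_in_sample_order(self):
        z1, p1 = kal_z_test(37, 11_000, 12, 9_000)
        z2, p2 = kal_z_test(12, 9_000, 37, 11_000)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_double_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            kal_z_test(0, 1000, 0, 2000)

    def test_matches_pooled_two_proportion_oracle(self):
        """Agrees with statsmodels' pooled two-proportion z to 1e-10."""
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(42)
        for _ in range(1000):
            n1, n2 = rng.integers(1_000, 1_000_000, size=2)
            x1 = rng.integers(0, min(n1, 5000))
            x2 = rng.integers(0, min(n2, 5000))
            if x1 + x2 == 0:
                continue
            z, p = kal_z_test(x1, n1, x2, n2)
            z_ref, p_ref = proportions_ztest([x1, x2], [n1, n2])
            assert abs(z - z_ref) < 1e-10
            assert abs(p - p_ref) < 1e-10


class TestLog2FoldChange:
    def test_plain_ratio(self):
        assert log2_fold_change(8.0, 2.0) == pytest.approx(2.0)

    def test_pseudo_count_only_when_a_side_is_zero(self):
        assert log2_fold_change(3.0, 0.0) == pytest.approx(np.log2(4.0))
        assert log2_fold_change(0.0, 0.0) == pytest.approx(0.0)
        assert log2_fold_change(4.0, 1.0) == pytest.approx(2.0)


def _toy_table():
    counts = pd.DataFrame(
        {"WT": [100, 400, 0, 80], "OE1": [800, 420, 0, 10], "OE2": [700, 410, 0, 12]},
        index=["up1", "flat", "silent", "dn1"],
    )
    lengths = pd.Series([1000, 1000, 1000, 1000], index=counts.index)
    return io.CountTable(
        counts=counts, lengths=lengths,
        library_totals=pd.Series([100_000, 100_000, 100_000], index=counts.columns),
    )


class TestCallDegs:
    def test_threshold_logic_and_zero_count_exclusion(self):
        ct = _toy_table()
        expr = rpkm_table(ct)
        res = call_degs(ct, expr, "OE1", "WT")
        assert res.loc["up1", "call"] == "up"
        assert res.loc["dn1", "call"] == "down"
        assert res.loc["flat", "call"] == "none"
        assert res.loc["silent", "call"] == "none"
        assert np.isnan(res.loc["silent", "p"])

    def test_p_failure_blocks_call_despite_fold_change(self):
        ct = _toy_table()
        expr = rpkm_table(ct)
        res = call_degs(ct, expr, "OE1", "WT", p_cutoff=1e-300)
        assert res.loc["up1", "log2fc"] >= 1.0
        assert res.loc["up1", "call"] == "none"

    def test_fc_failure_blocks_call_despite_p(self):
        ct = _toy_table()
        expr = rpkm_table(ct)
        res = call_degs(ct, expr, "OE1", "WT", fc_cutoff=32.0)
        assert res.loc["up1", "call"] == "none"

    def test_missing_sample_rejected(self):
        ct = _toy_table()
        with pytest.raises(KeyError):
            call_degs(ct, rpkm_table(ct), "OE9", "WT")

    def test_call_invariants(self, fitted_deg):
        for res in fitted_deg.results_.values():
            up = res[res["call"] == "up"]
            down = res[res["call"] == "down"]
            assert (up["log2fc"] >= 1.0).all() and (up["p"] <= 0.001).all()
            assert (down["log2fc"] <= -1.0).all() and (down["p"] <= 0.001).all()


class TestIntersectDegs:
    @staticmethod
    def _res(calls):
        return pd.DataFrame({"call": calls}, index=[f"g{i}" for i in range(len(calls))])

    def test_direction_rules(self):
        a = self._res(["up", "up", "up", "none", "down"])
        b = self._res(["up", "down", "none", "up", "down"])
        common_up, common_down = intersect_degs(a, b)
        assert common_up == {"g0"}
        assert common_down == {"g4"}

    def test_mismatched_universes_rejected(self):
        a = self._res(["up"])
        b = pd.DataFrame({"call": ["up"]}, index=["other"])
        with pytest.raises(ValueError, match="universe"):
            intersect_degs(a, b)

    def test_common_sets_subset_of_per_comparison_calls(self, fitted_deg):
        r1, r2 = fitted_deg.results_.values()
        up1 = set(r1.index[r1["call"] == "up"])
        up2 = set(r2.index[r2["call"] == "up"])
        assert fitted_deg.common_up_ <= up1 and fitted_deg.common_up_ <= up2
        assert not (fitted_deg.common_up_ & fitted_deg.common_down_)


def test_estimator_follows_sklearn_param_protocol():
    model = KalZDifferentialExpression(fc_cutoff=4.0)
    assert model.get_params()["fc_cutoff"] == 4.0
    model.set_params(p_cutoff=0.01)
    assert model.p_cutoff == 0.01
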