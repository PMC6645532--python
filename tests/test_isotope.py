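"""Two-source mixing model: discrimination, lines, inversions, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietinfer import (TwoSourceMixingModel, discrimination, discrimination_at,
                       fraction_at, group_means, mixing_forward, mixing_line,
                       oneway_anova, welch_t)

finite = st.floats(-50, 50, allow_nan=False)


@pytest.mark.parametrize(
    "consumer, diet, expected",
    [(3.74, 2.13, 1.61), (7.0, 7.0, 0.0), (-25.5, -28.3, 2.8)],
)
def test_discrimination_is_consumer_minus_diet(consumer, diet, expected):
    assert discrimination(consumer, diet) == pytest.approx(expected)


class TestForwardModel:
    def test_pure_leaf_diet_reproduces_consumer_mean(self):
        assert mixing_forward(1.0, 2.13, 4.12, 1.61) == pytest.approx(3.74)

    def test_identity_cases(self):
        assert mixing_forward(0.0, 5.0, -3.0, 0.0) == pytest.approx(-3.0)
        assert mixing_forward(0.5, 2.0, 4.0, 0.0) == pytest.approx(3.0)

    def test_out_of_range_fraction_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            mixing_forward(1.5, 2.0, 4.0, 0.0)


class TestMixingLine:
    def test_nitrogen_line_from_printed_means(self):
        line = mixing_line(3.74, 2.13, 4.12, "N")
        assert line.intercept == pytest.approx(0.19, abs=0.005)
        assert line.slope == pytest.approx(0.50, abs=0.005)

    def test_carbon_line_from_printed_means(self):
        line = mixing_line(-25.5, -28.3, -26.5, "C")
        assert line.intercept == pytest.approx(-1 / 1.8)
        assert line.slope == pytest.approx(1 / 1.8)

    def test_equal_sources_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            mixing_line(3.0, 2.0, 2.0, "N")

    def test_consumer_equal_source2_gives_zero_fraction(self):
        line = mixing_line(4.12, 2.13, 4.12, "N")
        f, ok = fraction_at(line, 0.0)
        assert f == pytest.approx(0.0) and ok

    @given(c=finite, s1=finite, s2=finite, d=finite)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_line_satisfies_closed_form(self, c, s1, s2, d):
        if abs(s1 - s2) < 1e-6:
            return
        line = mixing_line(c, s1, s2, "N")
        f, _ = fraction_at(line, d)
        assert f == pytest.approx((c - s2 - d) / (s1 - s2), rel=1e-9, abs=1e-9)


class TestInversions:
    def setup_method(self):
        self.n_line = mixing_line(3.74, 2.13, 4.12, "N")
        self.c_line = mixing_line(-25.5, -28.3, -26.5, "C")

    def test_fraction_one_at_implied_discrimination(self):
        f, ok = fraction_at(self.n_line, 1.61)
        assert f == pytest.approx(1.0, abs=0.01) and ok

    def test_root_of_line(self):
        d0 = -self.n_line.intercept / self.n_line.slope
        f, _ = fraction_at(self.n_line, d0)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_literature_trophic_step_flagged_out_of_range(self):
        """At a full trophic-step discrimination of 3.4 permil the N line
        implies a fraction near 1.9 — diagnostic, returned unclamped."""
        f, ok = fraction_at(self.n_line, 3.4)
        assert f == pytest.approx(1.9, abs=0.02)
        assert not ok

    def test_implied_discriminations_match_reported_rounding(self):
        assert discrimination_at(self.n_line, 1.0) == pytest.approx(1.61, abs=1e-9)
        assert round(discrimination_at(self.n_line, 1.0), 1) == 1.6
        assert discrimination_at(self.c_line, 1.0) == pytest.approx(2.8, abs=1e-9)

    def test_fraction_at_intercept_gives_zero_discrimination(self):
        assert discrimination_at(self.n_line, self.n_line.intercept) == pytest.approx(0.0)

    @given(d=finite)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_discrimination(self, d):
        f, _ = fraction_at(self.n_line, d)
        assert discrimination_at(self.n_line, f) == pytest.approx(d, abs=1e-12)

    @given(p=st.floats(0, 1), d=st.floats(-5, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_noise_free_recovery_of_fraction(self, p, d):
        """forward -> line -> fraction_at(true Delta) returns the true fraction."""
        c = mixing_forward(p, 2.13, 4.12, d)
        line = mixing_line(c, 2.13, 4.12, "N")
        f, _ = fraction_at(line, d)
        assert f == pytest.approx(p, abs=1e-9)


class TestGroupMeans:
    def test_arithmetic(self):
        df = pd.DataFrame({"role": ["x", "x"], "d15N": [2.0, 4.0], "d13C": [-1.0, 1.0]})
        gm = group_means(df)
        assert gm.loc["x", "d15N_mean"] == pytest.approx(3.0)
        assert gm.loc["x", "d13C_mean"] == pytest.approx(0.0)

    def test_single_measurement_sd_zero(self):
        df = pd.DataFrame({"role": ["x"], "d15N": [2.0], "d13C": [-1.0]})
        gm = group_means(df)
        assert gm.loc["x", "d15N_sd"] == 0.0 and gm.loc["x", "n"] == 1

    def test_missing_role_named(self):
        df = pd.DataFrame({"role": ["x"], "d15N": [2.0], "d13C": [-1.0]})
        with pytest.raises(ValueError, match="'y'"):
            group_means(df, roles=["x", "y"])


class TestWelch:
    def test_identical_groups(self):
        r = welch_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_paired_zero_differences(self):
        r = welch_t([1, 2, 3], [1, 2, 3], paired=True)
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.df == 2

    def test_hand_computed_welch(self):
        """A=[0,0,1,1], B=[10,10,11,11]: both sample variances 1/3, so
        t = -10 / sqrt(1/6) = -10*sqrt(6) ~ -24.495 with WS df = 6."""
        r = welch_t([0, 0, 1, 1], [10, 10, 11, 11])
        assert r.statistic == pytest.approx(-10 * np.sqrt(6))
        assert r.df == pytest.approx(6.0)

    def test_fractional_df(self):
        rng = np.random.default_rng(0)
        r = welch_t(rng.normal(0, 1, 10), rng.normal(0, 3, 25))
        assert r.df != int(r.df)  # Welch-Satterthwaite is fractional

    def test_antisymmetric_in_group_order(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 9.0]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_pooled_flag(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 4, 20)
        assert welch_t(a, b, pooled=True).df == 26.0

    def test_paired_via_model_pairing_ids(self):
        df = pd.DataFrame({
            "sample_id": list("abcdef"),
            "role": ["consumer"] * 3 + ["leaves"] * 3,
            "d15N": [3.0, 4.0, 5.0, 1.0, 2.0, 3.0],
            "d13C": [-25.0] * 6,
            "pairing_id": ["t1", "t2", "t3", "t1", "t2", "t3"],
        })
        m = TwoSourceMixingModel(df)
        r = m.compare("consumer", "leaves", paired=True)
        assert r.df == 2.0
        assert r.statistic > 0  # consumer enriched by 2 permil in every pair

    def test_paired_unmatched_ids_listed(self):
        df = pd.DataFrame({
            "sample_id": list("abcd"),
            "role": ["consumer", "consumer", "leaves", "leaves"],
            "d15N": [3.0, 4.0, 1.0, 2.0],
            "d13C": [-25.0] * 4,
            "pairing_id": ["t1", "t2", "t1", "t9"],
        })
        with pytest.raises(ValueError, match="t2.*t9|t9.*t2"):
            TwoSourceMixingModel(df).compare("consumer", "leaves", paired=True)


class TestAnova:
    def test_identical_groups(self):
        r = oneway_anova({"a": [1, 2], "b": [1, 2], "c": [1, 2]})
        assert r.statistic == 0.0 and r.p_value == 1.0
        assert r.df == (2.0, 3.0)

    def test_zero_within_variance_guard(self):
        r = oneway_anova({"a": [0, 0], "b": [1, 1], "c": [2, 2]})
        assert np.isinf(r.statistic) and r.p_value == pytest.approx(0.0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            oneway_anova({"a": [1.0]})


class TestModelFit:
    def test_from_means_matches_direct_line(self):
        res = TwoSourceMixingModel.from_means((3.74, -25.5), (2.13, -28.3),
                                              (4.12, -26.5))
        assert res.line_n.intercept == pytest.approx(0.19, abs=0.005)
        assert res.implied_discrimination("C", 1.0) == pytest.approx(2.8, abs=1e-9)

    def test_summary_contains_rounded_coefficients(self):
        res = TwoSourceMixingModel.from_means((3.74, -25.5), (2.13, -28.3),
                                              (4.12, -26.5))
        s = res.summary()
        assert "+0.19" in s and "0.50" in s
        assert "1.6 permil" in s and "2.8 permil" in s

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing columns"):
            TwoSourceMixingModel(pd.DataFrame({"role": ["consumer"]}))

    def test_standard_errors_attached_from_data(self):
        rng = np.random.default_rng(3)
        rows = []
        for role, mu_n, mu_c, n in (("consumer", 3.74, -25.5, 30),
                                    ("leaves", 2.13, -28.3, 40),
                                    ("larvae", 4.12, -26.5, 25)):
            for i in range(n):
                rows.append({"sample_id": f"{role}{i}", "role": role,
                             "d15N": mu_n + rng.normal(0, 0.5),
                             "d13C": mu_c + rng.normal(0, 0.5)})
        res = TwoSourceMixingModel(pd.DataFrame(rows)).fit()
        assert res.line_n.intercept_se is not None and res.line_n.intercept_se > 0
        assert res.line_n.slope_se is not None

    def test_plot_returns_axes(self):
        import matplotlib
        matplotlib.use("Agg")
        res = TwoSourceMixingModel.from_means((3.74, -25.5), (2.13, -28.3),
                                              (4.12, -26.5))
        ax = res.plot()
        assert len(ax.lines) >= 2
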