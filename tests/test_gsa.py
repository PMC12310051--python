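"""Sensitivity engine: Saltelli design arithmetic, z-scoring, Jansen and
second-order estimators against closed-form and brute-force oracles,
bootstrap behaviour, ranking and conditional expectations."""

import numpy as np
import pandas as pd
import pytest

from apsens.gsa import (
    ParameterRanges, SobolSensitivity, bootstrap_intervals,
    conditional_expectation, estimate_sobol, generate_saltelli,
    grand_total_and_rank, zscore_standardize,
)
from apsens.validation import (
    g_test_function, ishigami, ishigami_test_function, linear_test_function,
)

BOX2 = ParameterRanges(names=("x1", "x2"), lo=np.zeros(2), hi=np.ones(2))


class TestSaltelliDesign:
    def test_evaluation_counts(self):
        s = generate_saltelli(BOX2, M=4, second_order=True, seed=0)
        assert s.n_evaluations == 4 * (2 * 2 + 2) == s.all_rows().shape[0]
        s = generate_saltelli(BOX2, M=4, second_order=False, seed=0)
        assert s.n_evaluations == 4 * (2 + 2)

    def test_rows_inside_ranges(self):
        box = ParameterRanges(names=("a", "b", "c"),
                              lo=np.array([-1.0, 5.0, 0.1]),
                              hi=np.array([2.0, 6.0, 0.2]))
        rows = generate_saltelli(box, M=64, seed=1).all_rows()
        assert np.all(rows >= box.lo) and np.all(rows <= box.hi)

    def test_deterministic_given_seed(self):
        a = generate_saltelli(BOX2, M=16, seed=42).all_rows()
        b = generate_saltelli(BOX2, M=16, seed=42).all_rows()
        assert np.array_equal(a, b)
        c = generate_saltelli(BOX2, M=16, seed=43).all_rows()
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("M", [3, 6, 1000])
    def test_non_power_of_two_rejected(self, M):
        with pytest.raises(ValueError, match="power of two"):
            generate_saltelli(BOX2, M=M)


class TestZScore:
    def test_mean_zero_sd_one(self):
        z, mu, sd = zscore_standardize([1.0, 2.0, 3.0])
        assert np.mean(z) == pytest.approx(0.0, abs=1e-15)
        assert np.std(z, ddof=1) == pytest.approx(1.0)
        assert (mu, sd) == (2.0, 1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_standardize(np.full(10, 3.3))

    def test_indices_affine_invariant(self):
        tf = linear_test_function()
        s = generate_saltelli(tf.ranges, M=256, seed=0)
        y = tf.func(s.all_rows())
        a = estimate_sobol(s, y)
        b = estimate_sobol(s, 3.7 * y - 11.0)
        assert np.allclose(a["S1"], b["S1"], atol=1e-12)
        assert np.allclose(a["ST"], b["ST"], atol=1e-12)


class TestJansenEstimators:
    def test_linear_function_closed_form(self):
        tf = linear_test_function()
        s = generate_saltelli(tf.ranges, M=1024, seed=7)
        est = estimate_sobol(s, tf.func(s.all_rows()))
        assert est["S1"] == pytest.approx(tf.S1, abs=0.03)
        assert est["ST"] == pytest.approx(tf.ST, abs=0.03)
        assert est["S2"][0, 1] == pytest.approx(0.0, abs=0.05)

    def test_ishigami_closed_form(self):
        tf = ishigami_test_function()
        s = generate_saltelli(tf.ranges, M=4096, seed=11)
        est = estimate_sobol(s, tf.func(s.all_rows()))
        assert est["S1"] == pytest.approx(tf.S1, abs=0.02)
        assert est["ST"] == pytest.approx(tf.ST, abs=0.02)
        assert est["S2"][0, 2] == pytest.approx(tf.S2[0, 2], abs=0.05)

    def test_second_order_matches_brute_force_oracle(self):
        # brute-force double-loop oracle for V13 of the Ishigami function:
        # quadrature of Var over (x1, x3) of E[f | x1, x3], minus V1 (V3 = 0)
        n = 401
        x1 = np.linspace(-np.pi, np.pi, n)
        x3 = np.linspace(-np.pi, np.pi, n)
        X1, X3 = np.meshgrid(x1, x3, indexing="ij")
        x2 = np.linspace(-np.pi, np.pi, 2001)
        inner = np.trapezoid(np.sin(x2) ** 2, x2) / (2 * np.pi)  # E[sin^2 x2]
        cond = np.sin(X1) + 7.0 * inner + 0.1 * X3 ** 4 * np.sin(X1)
        w = np.full(n, 2 * np.pi / (n - 1)); w[0] = w[-1] = np.pi / (n - 1)
        W = np.outer(w, w) / (2 * np.pi) ** 2
        mu = np.sum(cond * W)
        v_cond = np.sum((cond - mu) ** 2 * W)  # = V1 + V3 + V13
        tf = ishigami_test_function()
        V = 0.5 * (1 + 0.1 * np.pi ** 4 / 5) ** 2 / tf.S1[0]  # total variance
        s13_oracle = (v_cond - tf.S1[0] * V) / V
        s = generate_saltelli(tf.ranges, M=2048, seed=5)
        est = estimate_sobol(s, tf.func(s.all_rows()))
        assert est["S2"][0, 2] == pytest.approx(s13_oracle, abs=0.06)

    def test_g_function_ranking_follows_coefficients(self):
        tf = g_test_function([0.0, 9.0, 99.0])
        s = generate_saltelli(tf.ranges, M=2048, second_order=False, seed=2)
        est = estimate_sobol(s, tf.func(s.all_rows()), which=("first", "total"))
        assert est["S1"][0] > est["S1"][1] > est["S1"][2]
        assert est["ST"][0] > est["ST"][1] > est["ST"][2]

    def test_equal_g_coefficients_give_equal_influence(self):
        tf = g_test_function([0.0, 0.0, 0.0])
        s = generate_saltelli(tf.ranges, M=2048, second_order=False, seed=3)
        est = estimate_sobol(s, tf.func(s.all_rows()), which=("first", "total"))
        assert np.ptp(est["S1"]) < 0.03
        assert est["S1"].mean() == pytest.approx(tf.S1[0], abs=0.02)

    def test_additive_function_partition_of_unity(self):
        tf = linear_test_function()
        s = generate_saltelli(tf.ranges, M=2048, seed=9)
        est = estimate_sobol(s, tf.func(s.all_rows()))
        assert est["S1"].sum() == pytest.approx(1.0, abs=0.02)
        assert np.allclose(est["ST"] - est["S1"], 0.0, atol=0.02)

    def test_total_at_least_first_on_test_functions(self):
        for tf, M in ((ishigami_test_function(), 1024),
                      (g_test_function([0.0, 1.0, 4.5]), 1024)):
            s = generate_saltelli(tf.ranges, M=M, second_order=False, seed=13)
            est = estimate_sobol(s, tf.func(s.all_rows()), which=("first", "total"))
            assert np.all(est["ST"] >= est["S1"] - 0.03)

    def test_consistency_over_increasing_sample_size(self):
        # estimates at growing M converge: deviations from the closed form
        # shrink into ever-smaller bands
        tf = ishigami_test_function()
        errs = []
        for M in (64, 256, 1024, 4096):
            s = generate_saltelli(tf.ranges, M=M, second_order=False, seed=21)
            est = estimate_sobol(s, tf.func(s.all_rows()), which=("first", "total"))
            errs.append(np.abs(est["S1"] - tf.S1).max())
        assert errs[-1] < 0.02
        assert errs[-1] < errs[0]

    def test_failed_rows_raise_in_strict_mode(self):
        tf = linear_test_function()
        s = generate_saltelli(tf.ranges, M=64, seed=0)
        y = tf.func(s.all_rows())
        y[5] = np.nan
        with pytest.raises(ValueError, match="row 5"):
            estimate_sobol(s, y)

    def test_constant_output_raises_via_zscore(self):
        s = generate_saltelli(BOX2, M=64, seed=0)
        with pytest.raises(ValueError, match="constant"):
            estimate_sobol(s, np.zeros(s.n_evaluations))


class TestBootstrap:
    def test_replicate_count_and_determinism(self):
        tf = linear_test_function()
        s = generate_saltelli(tf.ranges, M=256, seed=0)
        y = tf.func(s.all_rows())
        a = bootstrap_intervals(s, y, B_reps=200, seed=4)
        b = bootstrap_intervals(s, y, B_reps=200, seed=4)
        assert a["n_replicates"] == 200
        assert np.array_equal(a["S1_half_width"], b["S1_half_width"])
        assert np.all(a["S1_half_width"] >= 0)
        assert np.allclose(a["S1_half_width"], 2.0 * a["S1_sd"])

    def test_minimum_replicates_enforced(self):
        tf = linear_test_function()
        s = generate_saltelli(tf.ranges, M=64, seed=0)
        with pytest.raises(ValueError, match="100"):
            bootstrap_intervals(s, tf.func(s.all_rows()), B_reps=50)

    def test_single_parameter_first_order_has_zero_width(self):
        # with N = 1 the AB block equals B, so S1 = 1 in every replicate
        box = ParameterRanges(names=("x",), lo=np.zeros(1), hi=np.ones(1))
        s = generate_saltelli(box, M=128, second_order=False, seed=0)
        y = s.all_rows()[:, 0] ** 2
        out = bootstrap_intervals(s, y, B_reps=200, seed=0)
        assert out["S1_half_width"][0] == pytest.approx(0.0, abs=1e-12)

    def test_half_width_shrinks_roughly_as_sqrt_m(self):
        tf = linear_test_function()
        widths = {}
        for M in (256, 1024):
            s = generate_saltelli(tf.ranges, M=M, second_order=False, seed=17)
            out = bootstrap_intervals(s, tf.func(s.all_rows()), B_reps=300, seed=17)
            widths[M] = out["ST_half_width"].mean()
        ratio = widths[1024] / widths[256]
        assert 0.3 < ratio < 0.75  # ~1/2 expected for 4x the sample


class TestRankingAndConditional:
    def test_all_ones_matrix_ties_break_alphabetically(self):
        st_mat = pd.DataFrame(
            np.ones((3, 6)), index=["pKr", "pCaL", "pClb"],
            columns=[f"y{k}" for k in range(6)],
        )
        r = grand_total_and_rank(st_mat)
        assert np.allclose(r.SG, 6.0)
        assert r.names == ("pCaL", "pClb", "pKr")

    def test_zero_weights_rank_purely_by_tie_break(self):
        st_mat = pd.DataFrame([[0.9, 0.1], [0.2, 0.3]],
                              index=["b", "a"], columns=["y0", "y1"])
        r = grand_total_and_rank(st_mat, weights=[0.0, 0.0])
        assert np.allclose(r.SG, 0.0)
        assert r.names == ("a", "b")

    def test_missing_biomarker_column_raises(self):
        st_mat = pd.DataFrame([[0.9, np.nan], [0.2, 0.3]],
                              index=["b", "a"], columns=["y0", "y1"])
        with pytest.raises(ValueError, match="missing"):
            grand_total_and_rank(st_mat)

    def test_weight_length_checked(self):
        st_mat = pd.DataFrame([[0.9], [0.2]], index=["b", "a"], columns=["y0"])
        with pytest.raises(ValueError, match="weights"):
            grand_total_and_rank(st_mat, weights=[1.0, 2.0])

    def test_conditional_expectation_linear_unit_slope(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 1.0, (20_000, 2))
        y = x[:, 0] + x[:, 1]
        ce = conditional_expectation(x, y, param_index=0, n_bins=10)
        assert ce["count"].sum() == 20_000
        fit = np.polyfit(ce["bin_center"], ce["mean"], 1)
        assert fit[0] == pytest.approx(1.0, abs=0.05)

    def test_constant_output_gives_flat_curve(self):
        x = np.linspace(0.0, 1.0, 500)[:, None]
        ce = conditional_expectation(x, np.full(500, 2.5), 0, n_bins=5)
        assert np.allclose(ce["mean"], 2.5)

    def test_empty_bin_reported_as_gap(self):
        x = np.concatenate([np.linspace(0, 0.3, 50), np.linspace(0.7, 1.0, 50)])
        # rescaling maps the gap to the middle bins
        ce = conditional_expectation(x[:, None], x, 0, n_bins=10)
        assert ce["count"].sum() == 100
        assert np.isnan(ce.loc[ce["count"] == 0, "mean"]).all()
        assert (ce["count"] == 0).any()


class TestModelResultsInterface:
    def test_fit_summary_and_drop_policy(self):
        tf = ishigami_test_function()

        def flaky(rows):
            y = tf.func(rows)
            y[::97] = np.nan  # a few failed evaluations
            return y

        sens = SobolSensitivity(flaky, tf.ranges, M=512, second_order=True,
                                failure_policy="drop", bootstrap_reps=150)
        res = sens.fit(seed=8)
        assert res.n_failed > 0
        d = res.per_output["y0"]
        assert d["S1"] == pytest.approx(tf.S1, abs=0.06)
        tab = res.summary()
        assert set(tab.columns) >= {"biomarker", "parameter", "S1", "ST"}
        assert len(tab) == 3

    def test_strict_policy_raises_with_sample_attached(self):
        tf = linear_test_function()

        def flaky(rows):
            y = tf.func(rows)
            y[3] = np.nan
            return y

        sens = SobolSensitivity(flaky, tf.ranges, M=64, failure_policy="strict")
        with pytest.raises(ValueError, match="row 3"):
            sens.fit(seed=0)
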