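"""Tests of the causal estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.errors import SingularDesignError, UndefinedRatioError
from mrscreen.estimators import (
    egger,
    estimate_all,
    ivw,
    mode_estimate,
    mvmr_ivw,
    wald_ratio,
    wald_ratios,
    weighted_median,
)
from mrscreen.instruments import HarmonizedInstrument

from conftest import build_iset, clean_sim_iset, random_iset


class TestWaldRatio:
    def test_direct_formula(self):
        inst = HarmonizedInstrument("rs1", 0.1, 0.005, 0.02, 0.01, 0.3)
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        inst = HarmonizedInstrument("rs1", 0.1, 0.005, 0.0, 0.01, 0.3)
        assert wald_ratio(inst).beta == 0.0

    def test_negative_exposure_beta_sign_rule(self):
        inst = HarmonizedInstrument("rs1", -0.1, 0.005, 0.02, 0.01, 0.3)
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_beta_errors(self):
        inst = HarmonizedInstrument("rs1", 0.0, 0.005, 0.02, 0.01, 0.3)
        with pytest.raises(UndefinedRatioError):
            wald_ratio(inst)


class TestIvw:
    def test_equal_weight_mean(self):
        iset = build_iset([0.1, 0.1], [0.005, 0.005], [0.01, 0.03], [0.01, 0.01])
        assert ivw(iset).beta == pytest.approx(0.2)

    def test_single_snp_directs_to_wald(self):
        iset = build_iset([0.1], [0.005], [0.02], [0.01])
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(iset)

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            iset = random_iset(rng)
            sw = 1.0 / iset.se_out
            slope, *_ = np.linalg.lstsq(
                (sw * iset.beta_exp)[:, None], sw * iset.beta_out, rcond=None
            )
            assert ivw(iset).beta == pytest.approx(float(slope[0]), abs=1e-12)

    def test_fixed_se_never_exceeds_random_se(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            iset = random_iset(rng)
            fixed = ivw(iset, "fixed")
            rand = ivw(iset, "multiplicative_random")
            assert fixed.se <= rand.se + 1e-15
            q = rand.extra["Q"]
            if q <= len(iset) - 1:
                assert fixed.se == pytest.approx(rand.se)
            else:
                assert rand.se > fixed.se

    def test_ci_brackets_estimate(self):
        iset = random_iset(np.random.default_rng(2))
        est = ivw(iset)
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.ci_high - est.beta == pytest.approx(1.959963985 * est.se, rel=1e-6)


class TestEgger:
    def test_three_point_exact_fit(self):
        # collinear construction: Gamma = 0.01 + 0.2 * gamma
        iset = build_iset([0.1, 0.2, 0.3], [0.005] * 3, [0.03, 0.05, 0.07], [0.01] * 3)
        est = egger(iset)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.extra["egger_intercept"] == pytest.approx(0.01, abs=1e-12)

    def test_orientation_invariance(self):
        iset = build_iset([0.1, 0.2, 0.3, 0.15], [0.005] * 4, [0.03, 0.05, 0.07, 0.02], [0.01] * 4)
        flipped = build_iset(
            [-0.1, 0.2, -0.3, 0.15], [0.005] * 4, [-0.03, 0.05, -0.07, 0.02], [0.01] * 4
        )
        a, b = egger(iset), egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.extra["egger_intercept"] == pytest.approx(b.extra["egger_intercept"])

    def test_no_spread_is_singular(self):
        iset = build_iset([0.1, 0.1, 0.1], [0.005] * 3, [0.01, 0.02, 0.03], [0.01] * 3)
        with pytest.raises(SingularDesignError):
            egger(iset)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        """A hidden constrained fit (origin-forced WLS in the oriented frame)
        equals the IVW estimate."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            iset = random_iset(rng)
            x, y, so = iset.beta_exp, iset.beta_out, iset.se_out
            sgn = np.where(x >= 0, 1.0, -1.0)
            xa, ya = np.abs(x), sgn * y
            sw = 1.0 / so
            slope, *_ = np.linalg.lstsq((sw * xa)[:, None], sw * ya, rcond=None)
            assert ivw(iset).beta == pytest.approx(float(slope[0]), abs=1e-12)

    def test_intercept_near_zero_without_pleiotropy(self):
        intercepts = []
        for seed in range(40):
            iset, _ = clean_sim_iset(30, 0.1, seed=seed, n=100_000)
            intercepts.append(egger(iset).extra["egger_intercept"])
        assert abs(np.mean(intercepts)) < 5e-4


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        iset = build_iset([0.1] * 3, [0.005] * 3, [0.01, 0.02, 0.09], [0.01] * 3)
        assert weighted_median(iset, n_boot=100, seed=0).beta == pytest.approx(0.2)

    def test_interpolation_matches_brute_force_scan(self):
        # weights proportional to (0.5, 0.25, 0.25) on ratios (0.1, 0.2, 0.3)
        iset = build_iset(
            [0.1, 0.1, 0.1],
            [0.005] * 3,
            [0.01, 0.02, 0.03],
            [0.01 / np.sqrt(2), 0.01, 0.01],
        )
        b, sb = wald_ratios(iset)
        w = 1.0 / sb**2
        w = w / w.sum()
        order = np.argsort(b)
        bs, ws = b[order], w[order]
        s = np.cumsum(ws) - ws / 2
        # brute-force scan of the piecewise-linear weighted CDF for p = 0.5
        grid = np.linspace(bs[0], bs[-1], 200_001)
        cdf = np.interp(grid, bs, s)
        expected = grid[np.argmin(np.abs(cdf - 0.5))]
        est = weighted_median(iset, n_boot=100, seed=0)
        assert est.beta == pytest.approx(expected, abs=1e-5)
        np.testing.assert_allclose(ws, [0.5, 0.25, 0.25])

    def test_robust_to_invalid_instruments(self):
        """With a minority of strongly pleiotropic instruments the weighted
        median stays near the truth while IVW is dragged away."""
        rng = np.random.default_rng(7)
        wm_err, ivw_err = [], []
        for seed in range(30):
            iset, truth = clean_sim_iset(30, 0.2, seed=seed, n=200_000, gamma_sd=0.05)
            bad = rng.choice(30, size=6, replace=False)
            for j in bad:
                # large pleiotropic offset, directional in the oriented frame
                iset.instruments[j].beta_out += 0.03 * np.sign(iset.instruments[j].beta_exp)
            iset = build_iset(  # rebuild to refresh cached arrays
                [i.beta_exp for i in iset.instruments],
                [i.se_exp for i in iset.instruments],
                [i.beta_out for i in iset.instruments],
                [i.se_out for i in iset.instruments],
            )
            wm_err.append(abs(weighted_median(iset, n_boot=50, seed=seed).beta - 0.2))
            ivw_err.append(abs(ivw(iset).beta - 0.2))
        assert np.mean(wm_err) < 0.5 * np.mean(ivw_err)


class TestModes:
    def test_degenerate_ratios_return_common_value(self):
        iset = build_iset([0.1] * 3, [0.005] * 3, [0.02] * 3, [0.01] * 3)
        est = mode_estimate(iset, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)
        assert est.se > 0

    def test_dense_cluster_dominates(self):
        iset = build_iset(
            [0.1] * 4, [0.005] * 4, [0.019, 0.020, 0.021, 0.09], [0.01] * 4
        )
        est = mode_estimate(iset, weighted=False, n_boot=50, seed=0)
        assert abs(est.beta - 0.20) < 0.02

    def test_weighted_equals_simple_with_equal_weights(self):
        iset = build_iset([0.1] * 4, [0.005] * 4, [0.01, 0.02, 0.025, 0.05], [0.01] * 4)
        a = mode_estimate(iset, weighted=False, n_boot=50, seed=0)
        b = mode_estimate(iset, weighted=True, n_boot=50, seed=0)
        assert a.beta == pytest.approx(b.beta)


class TestMvmr:
    def test_zero_second_column_reduces_to_univariable(self):
        rng = np.random.default_rng(4)
        iset = random_iset(rng, L=10)
        X = np.column_stack([iset.beta_exp, np.zeros(10)])
        res = mvmr_ivw(iset.beta_out, iset.se_out, X)
        assert res[0].beta == pytest.approx(ivw(iset).beta, abs=1e-12)
        assert np.isnan(res[1].beta)

    def test_matches_normal_equations_oracle(self):
        y = np.array([0.02, 0.05, 0.01, 0.04])
        so = np.array([0.01, 0.02, 0.01, 0.015])
        X = np.array([[0.1, 0.02], [0.2, 0.01], [0.05, 0.03], [0.15, 0.02]])
        w = 1.0 / so**2
        expected = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ np.diag(w) @ y)
        res = mvmr_ivw(y, so, X)
        assert res[0].beta == pytest.approx(expected[0], abs=1e-12)
        assert res[1].beta == pytest.approx(expected[1], abs=1e-12)

    def test_collinear_columns_raise_named_error(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.1, 0.02, 8)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularDesignError, match="exposure_1~exposure_2"):
            mvmr_ivw(rng.normal(0, 0.01, 8), np.full(8, 0.01), X)

    def test_too_few_snps_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            mvmr_ivw([0.1, 0.2, 0.1], [0.01] * 3, np.ones((3, 2)))

    def test_recovers_conditional_effects(self):
        rng = np.random.default_rng(6)
        L, se = 60, 0.004
        X = rng.normal(0.0, 0.03, (L, 2))
        betas = []
        for rep in range(50):
            y = X @ np.array([0.1, 0.05]) + rng.normal(0, se, L)
            res = mvmr_ivw(y, np.full(L, se), X)
            betas.append([res[0].beta, res[1].beta])
        mean = np.mean(betas, axis=0)
        assert mean[0] == pytest.approx(0.1, abs=0.005)
        assert mean[1] == pytest.approx(0.05, abs=0.005)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.2, 5.0), st.booleans())
def test_scale_equivariance(seed, mag, negate):
    """Rescaling the exposure by c divides every causal estimate by c."""
    c = -mag if negate else mag
    rng = np.random.default_rng(seed)
    iset = random_iset(rng, L=12)
    scaled = build_iset(c * iset.beta_exp, abs(c) * iset.se_exp, iset.beta_out, iset.se_out)
    assert ivw(scaled).beta * c == pytest.approx(ivw(iset).beta, rel=1e-9)
    assert egger(scaled).beta * c == pytest.approx(egger(iset).beta, rel=1e-9)
    a = weighted_median(iset, n_boot=50, seed=1)
    b = weighted_median(scaled, n_boot=50, seed=1)
    assert b.beta * c == pytest.approx(a.beta, rel=1e-9)
    if c > 0:  # identical bootstrap noise draws only in the same orientation
        assert b.se * abs(c) == pytest.approx(a.se, rel=1e-9)
    m1 = mode_estimate(iset, n_boot=10, seed=1)
    m2 = mode_estimate(scaled, n_boot=10, seed=1)
    assert m2.beta * c == pytest.approx(m1.beta, rel=1e-6)


class TestEstimateAll:
    def test_single_instrument_falls_back_to_wald(self):
        iset = build_iset([0.1], [0.005], [0.02], [0.01])
        out = estimate_all(iset, n_boot=50)
        assert out["wald_ratio"].beta == pytest.approx(0.2)
        assert all(out[m] is None for m in ["ivw", "egger", "weighted_median"])

    def test_two_instruments_skip_three_snp_methods(self):
        iset = build_iset([0.1, 0.2], [0.005] * 2, [0.02, 0.04], [0.01] * 2)
        out = estimate_all(iset, n_boot=50)
        assert out["ivw"] is not None
        assert out["egger"] is None and out["weighted_median"] is None
        assert out["simple_mode"] is None and out["weighted_mode"] is None
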