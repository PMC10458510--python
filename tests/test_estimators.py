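"""Causal estimators: Wald, IVW, Egger, weighted median, modes."""
import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from tsmr.estimators import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    all_estimates,
    ivw,
    kernel_mode_estimate,
    mode_estimate,
    mr_egger,
    ratio_estimates,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_estimate,
)
from tsmr.gwas_io import HarmonizedInstrumentSet

F = HarmonizedInstrumentSet.from_arrays


@st.composite
def instrument_sets(draw, min_size=3, max_size=12):
    n = draw(st.integers(min_size, max_size))
    f = st.floats(-0.5, 0.5).filter(lambda v: abs(v) > 0.01)
    se = st.floats(0.005, 0.2)
    bx = draw(st.lists(f, min_size=n, max_size=n, unique=True))
    by = [draw(st.floats(-0.5, 0.5)) for _ in range(n)]
    sx = [draw(se) for _ in range(n)]
    sy = [draw(se) for _ in range(n)]
    assume(float(np.std(np.abs(bx))) > 1e-3)  # non-collinear Egger design
    return F(bx, sx, by, sy)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(F([0.1], [0.01], [0.05], [0.01]))
        assert est.b == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert wald_ratio(F([0.1], [0.01], [0.0], [0.01])).b == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(F([0.0], [0.01], [0.05], [0.01]))


class TestIVW:
    def test_single_instrument_routes_to_wald(self):
        one = F([0.1], [0.01], [0.05], [0.01])
        assert ivw(one).b == pytest.approx(wald_ratio(one).b)

    def test_two_identical_instruments_give_common_ratio(self):
        est = ivw(F([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01]))
        assert est.b == pytest.approx(0.5)
        assert est.n_snp == 2

    @given(instrument_sets(min_size=2))
    def test_equals_fixed_effect_meta_of_wald_ratios(self, h):
        """IVW is the inverse-variance meta-analysis of per-SNP ratios."""
        r = ratio_estimates(h)
        w = 1.0 / r.ses ** 2
        b_meta = float(np.sum(w * r.ratios) / np.sum(w))
        se_meta = float(np.sqrt(1.0 / np.sum(w)))
        est = ivw(h)
        assert est.b == pytest.approx(b_meta, rel=1e-10, abs=1e-12)
        assert est.se == pytest.approx(se_meta, rel=1e-10)

    def test_random_effects_never_shrinks_se(self):
        h = F([0.1, 0.2, 0.15], [0.01] * 3, [0.05, -0.1, 0.2], [0.01] * 3)
        assert ivw(h, random_effects=True).se >= ivw(h).se


class TestEgger:
    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(F([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))

    def test_noiseless_no_pleiotropy_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.08, 0.12, 0.2, 0.31])
        theta = -0.25
        h = F(bx, [0.01] * 4, theta * bx, [0.01] * 4)
        fit = mr_egger(h)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope.b == pytest.approx(theta, abs=1e-12)
        assert fit.slope.b == pytest.approx(ivw(h).b, abs=1e-12)

    def test_noiseless_constant_pleiotropy_lands_in_intercept(self):
        bx = np.array([0.08, 0.12, 0.2, 0.31])
        h = F(bx, [0.01] * 4, 0.1 * bx + 0.02, [0.01] * 4)
        fit = mr_egger(h)
        assert fit.intercept == pytest.approx(0.02, abs=1e-12)
        assert fit.slope.b == pytest.approx(0.1, abs=1e-12)

    @given(instrument_sets())
    def test_matches_weighted_regression_oracle(self, h):
        """Egger fit equals statsmodels WLS with bx>=0 orientation and
        residual-SD inflation floored at 1."""
        import statsmodels.api as sm

        sign = np.where(h.beta_exposure < 0, -1.0, 1.0)
        x = h.beta_exposure * sign
        y = h.beta_outcome * sign
        w = 1.0 / h.se_outcome ** 2
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        sigma = np.sqrt(res.mse_resid)
        fit = mr_egger(h)
        assert fit.slope.b == pytest.approx(res.params[1], rel=1e-8, abs=1e-10)
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-8, abs=1e-10)
        assert fit.slope.se == pytest.approx(res.bse[1] / min(sigma, 1.0),
                                             rel=1e-8)
        assert fit.intercept_se == pytest.approx(res.bse[0] / min(sigma, 1.0),
                                                 rel=1e-8)


class TestWeightedMedian:
    def test_identical_ratios_return_common_value(self):
        h = F([0.1, 0.2, 0.4], [0.001] * 3, [0.05, 0.10, 0.20], [0.001] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.b == pytest.approx(0.5, abs=1e-12)

    def test_robust_to_single_outlier(self):
        # equal weights, ratios {1, 2, 100} -> median 2
        h = F([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 100.0], [1.0] * 3)
        r = ratio_estimates(h)
        assert weighted_median_estimate(r.ratios, r.weights) == pytest.approx(2.0)

    def test_bootstrap_se_shrinks_with_outcome_noise(self):
        tight = F([0.1] * 5, [0.001] * 5, [0.05] * 5, [0.0001] * 5)
        loose = F([0.1] * 5, [0.001] * 5, [0.05] * 5, [0.05] * 5)
        assert (weighted_median(tight, n_boot=200, seed=2).se
                < weighted_median(loose, n_boot=200, seed=2).se)

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.01, 5)),
                    min_size=3, max_size=15))
    def test_matches_weighted_quantile_oracle(self, pairs):
        """Estimate equals a direct scan of the weighted empirical quantile."""
        ratios = np.array([r for r, _ in pairs])
        weights = np.array([w for _, w in pairs])
        merged: dict = {}
        for r, w in pairs:  # ties merge, independently of the implementation
            merged[r] = merged.get(r, 0.0) + w
        r_s = np.array(sorted(merged))
        w_s = np.array([merged[r] for r in r_s]) / sum(merged.values())
        cum = np.cumsum(w_s) - 0.5 * w_s
        if cum[0] >= 0.5:
            expected = r_s[0]
        elif cum[-1] < 0.5:
            expected = r_s[-1]
        else:
            k = int(np.searchsorted(cum, 0.5, side="right")) - 1
            frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
            expected = r_s[k] + frac * (r_s[k + 1] - r_s[k])
        got = weighted_median_estimate(ratios, weights)
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestModes:
    def test_mode_ignores_minority(self):
        got = kernel_mode_estimate(np.array([1.0, 1.0, 1.0, 5.0]),
                                   np.ones(4))
        assert got == pytest.approx(1.0, abs=0.35)

    def test_simple_equals_weighted_under_equal_weights(self):
        h = F([0.1, 0.11, 0.12, 0.3], [0.01] * 4,
              [0.05, 0.06, 0.05, 0.2], [0.01] * 4)
        simple = mode_estimate(h, weighted=False, n_boot=50, seed=5)
        r = ratio_estimates(h)
        assert simple.b == pytest.approx(
            kernel_mode_estimate(r.ratios, np.ones_like(r.ratios)), abs=1e-9)

    def test_identical_ratios_degenerate(self):
        h = F([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.01] * 3)
        est = mode_estimate(h, n_boot=100, seed=7)
        assert est.b == pytest.approx(0.5, abs=1e-12)

    @given(instrument_sets(min_size=4, max_size=10))
    def test_matches_grid_argmax_oracle(self, h):
        """Mode location agrees with a dense-grid argmax of the kernel density."""
        from tsmr.estimators import _mode_bandwidth

        r = ratio_estimates(h)
        for weights in (np.ones(len(h)), r.weights):
            w = weights / weights.sum()
            hbw = _mode_bandwidth(r.ratios, 1.0)
            if hbw == 0:
                continue
            grid = np.sort(np.concatenate([
                np.linspace(r.ratios.min() - 3 * hbw,
                            r.ratios.max() + 3 * hbw, 40_001), r.ratios]))
            with np.errstate(over="ignore"):
                dens = (w[:, None]
                        * np.exp(-0.5 * ((grid[None] - r.ratios[:, None]) / hbw) ** 2)
                        ).sum(axis=0)
            expected = grid[int(np.argmax(dens))]
            got = kernel_mode_estimate(r.ratios, w)
            with np.errstate(over="ignore"):
                d_got = np.exp(-0.5 * ((got - r.ratios) / hbw) ** 2) @ w
                d_exp = np.exp(-0.5 * ((expected - r.ratios) / hbw) ** 2) @ w
            # refinement may only improve on the grid argmax
            assert d_got >= d_exp * (1 - 1e-9)
            step = (grid[-1] - grid[0]) / 40_000
            if step < hbw:  # grid resolves the kernel: locations must agree
                assert abs(got - expected) <= max(2 * step, 1e-3 * hbw)


class TestOddsRatio:
    def test_published_ivw_row(self):
        or_, lo, hi = to_odds_ratio(-0.118, 0.039)
        assert or_ == pytest.approx(0.889, abs=5e-4)
        assert hi == pytest.approx(0.959, abs=5e-4)

    def test_published_egger_row(self):
        assert to_odds_ratio(0.125, 0.208)[0] == pytest.approx(1.133, abs=5e-4)

    def test_null_effect_symmetric_on_log_scale(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)


class TestEquivariance:
    @given(instrument_sets())
    def test_negating_outcome_flips_sign_fixed_se(self, h):
        """Analytic estimators: b -> -b, SE unchanged, under by -> -by."""
        neg = F(h.beta_exposure, h.se_exposure, -h.beta_outcome, h.se_outcome)
        for fn in (ivw, lambda s: mr_egger(s).slope):
            a, b = fn(h), fn(neg)
            assert b.b == pytest.approx(-a.b, rel=1e-9, abs=1e-12)
            assert b.se == pytest.approx(a.se, rel=1e-9)
        r, rn = ratio_estimates(h), ratio_estimates(neg)
        assert weighted_median_estimate(rn.ratios, rn.weights) == pytest.approx(
            -weighted_median_estimate(r.ratios, r.weights), rel=1e-9, abs=1e-12)
        assert kernel_mode_estimate(rn.ratios, rn.weights) == pytest.approx(
            -kernel_mode_estimate(r.ratios, r.weights), abs=1e-6)

    @given(instrument_sets(), st.floats(0.1, 10))
    def test_rescaling_exposure_divides_estimates(self, h, c):
        scaled = F(c * h.beta_exposure, c * h.se_exposure,
                   h.beta_outcome, h.se_outcome)
        assert ivw(scaled).b == pytest.approx(ivw(h).b / c, rel=1e-9, abs=1e-12)
        assert mr_egger(scaled).slope.b == pytest.approx(
            mr_egger(h).slope.b / c, rel=1e-8, abs=1e-12)
        r, rs = ratio_estimates(h), ratio_estimates(scaled)
        assert weighted_median_estimate(rs.ratios, rs.weights) == pytest.approx(
            weighted_median_estimate(r.ratios, r.weights) / c,
            rel=1e-9, abs=1e-12)


class TestAllEstimates:
    def test_counts_by_instrument_number(self):
        one = F([0.1], [0.01], [0.05], [0.01])
        assert [e.method for e in all_estimates(one)] == ["Wald ratio"]
        two = F([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        assert [e.method for e in all_estimates(two)] == ["IVW"]
        three = F([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.14], [0.01] * 3)
        methods = [e.method for e in all_estimates(three, n_boot=50)]
        assert methods == ["IVW", "MR Egger", "Weighted median",
                           "Simple mode", "Weighted mode"]

    def test_estimate_invariants(self):
        three = F([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.14], [0.01] * 3)
        for est in all_estimates(three, n_boot=50, seed=11):
            assert est.ci_low <= est.or_ <= est.ci_high
            assert 0 < est.pvalue <= 1
            assert est.or_ == pytest.approx(np.exp(est.b), rel=1e-12)
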