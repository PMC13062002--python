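"""Causal estimators against independent oracles and their invariants."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrkit.estimators import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    egger,
    ivw,
    simple_median,
    to_odds_ratio,
    two_sided_p,
    wald_ratio,
    wald_ratio_exposure_aware,
)
from mrkit.synthetic import evaluate, strong_instrument_scenario

from conftest import make_instrument


def wls_through_origin(bx, by, sy):
    """Independent IVW oracle: weighted least squares of beta_outcome on
    beta_exposure through the origin, weights 1/se_outcome^2, solved by the
    closed-form normal equation."""
    w = 1.0 / np.asarray(sy) ** 2
    bx, by = np.asarray(bx), np.asarray(by)
    slope = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = 1.0 / np.sqrt(np.sum(w * bx**2))
    return slope, se


def wls_with_intercept(x, y, w):
    """Independent Egger oracle: the 2x2 weighted normal equations solved
    directly, with fixed-weight (known-variance) standard errors."""
    x, y, w = (np.asarray(a, dtype=float) for a in (x, y, w))
    xtx = np.array([[np.sum(w), np.sum(w * x)],
                    [np.sum(w * x), np.sum(w * x**2)]])
    xty = np.array([np.sum(w * y), np.sum(w * x * y)])
    coef = np.linalg.solve(xtx, xty)
    cov = np.linalg.inv(xtx)
    return coef, np.sqrt(np.diag(cov))


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,theta,se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (-2.0, 1.0, 0.2, -0.5, 0.1)],
    )
    def test_ratio_and_delta_method_se(self, bx, by, sy, theta, se):
        assert wald_ratio(bx, by, sy) == (pytest.approx(theta), pytest.approx(se))

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.5, 0.1)

    def test_delta_method_matches_monte_carlo_ratio_sd(self, rng):
        """With a strong instrument (|beta|/se > 10 on the exposure side)
        the first-order SE agrees with both the exposure-aware second-order
        SE and a brute-force Monte-Carlo ratio SD to within ~1%."""
        bx, sx, by, sy = 0.5, 0.004, 0.15, 0.02
        draws = rng.normal(by, sy, 400_000) / rng.normal(bx, sx, 400_000)
        mc_sd = draws.std(ddof=1)
        _, se1 = wald_ratio(bx, by, sy)
        _, se2 = wald_ratio_exposure_aware(bx, sx, by, sy)
        assert se2 == pytest.approx(mc_sd, rel=0.01)
        assert se1 == pytest.approx(se2, rel=0.01)


class TestIVW:
    def test_identical_ratios_are_returned_exactly(self):
        instruments = [
            make_instrument(f"rs{k}", bx=b, by=0.4 * b, sy=0.01 * b)
            for k, b in enumerate([0.5, 1.0, 2.0])
        ]
        fixed, het_fixed = ivw(instruments, model="fixed")
        random, het_random = ivw(instruments, model="random")
        assert fixed.theta == pytest.approx(0.4, rel=1e-12)
        assert het_fixed.q_stat == pytest.approx(0.0, abs=1e-20)
        assert fixed.se == pytest.approx(random.se)  # Q = 0: no inflation

    def test_matches_weighted_regression_oracle(self, random_instruments):
        instruments = random_instruments(j=5, seed=101)
        estimate, _ = ivw(instruments, model="fixed")
        bx = [i.beta_exposure for i in instruments]
        by = [i.beta_outcome for i in instruments]
        sy = [i.se_outcome for i in instruments]
        slope, se = wls_through_origin(bx, by, sy)
        assert estimate.theta == pytest.approx(slope, rel=1e-12)
        assert estimate.se == pytest.approx(se, rel=1e-12)

    def test_random_effects_only_inflate_se(self, random_instruments):
        instruments = random_instruments(j=12, seed=3)
        fixed, _ = ivw(instruments, model="fixed")
        random, _ = ivw(instruments, model="random")
        assert random.theta == fixed.theta
        assert random.se >= fixed.se

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([make_instrument()])

    def test_order_invariance(self, random_instruments):
        instruments = random_instruments(j=9, seed=8)
        a, _ = ivw(instruments)
        b, _ = ivw(list(reversed(instruments)))
        assert a.theta == pytest.approx(b.theta, rel=1e-14)
        assert a.se == pytest.approx(b.se, rel=1e-14)

    def test_scale_equivariance(self, random_instruments):
        """Multiplying exposure betas (and SEs) by c divides theta by c."""
        instruments = random_instruments(j=7, seed=21)
        c = 3.7
        scaled = [make_instrument(i.variant_id, bx=c * i.beta_exposure,
                                  sx=c * i.se_exposure, by=i.beta_outcome,
                                  sy=i.se_outcome, maf=i.maf)
                  for i in instruments]
        base, _ = ivw(instruments)
        scl, _ = ivw(scaled)
        assert scl.theta == pytest.approx(base.theta / c, rel=1e-12)


class TestEgger:
    def test_exact_line_recovered_with_zero_residual(self):
        a, theta = 0.03, 0.55
        instruments = []
        for k, bx in enumerate([0.05, 0.08, 0.11, 0.15]):
            instruments.append(
                make_instrument(f"rs{k}", bx=bx, by=a + theta * bx, sy=0.02)
            )
        result = egger(instruments)
        assert result.slope.theta == pytest.approx(theta, rel=1e-10)
        assert result.intercept == pytest.approx(a, rel=1e-10)
        assert result.q_stat == pytest.approx(0.0, abs=1e-16)

    def test_matches_normal_equations_oracle(self, random_instruments):
        instruments = random_instruments(j=4, seed=55)
        result = egger(instruments, model="fixed")
        sign = np.array([1 if i.beta_exposure >= 0 else -1 for i in instruments])
        x = sign * np.array([i.beta_exposure for i in instruments])
        y = sign * np.array([i.beta_outcome for i in instruments])
        w = 1.0 / np.array([i.se_outcome for i in instruments]) ** 2
        coef, se = wls_with_intercept(x, y, w)
        assert result.intercept == pytest.approx(coef[0], rel=1e-12)
        assert result.slope.theta == pytest.approx(coef[1], rel=1e-12)
        assert result.intercept_se == pytest.approx(se[0], rel=1e-12)
        assert result.slope.se == pytest.approx(se[1], rel=1e-12)

    def test_invariant_to_allele_recoding_of_any_instrument(self, random_instruments):
        """The beta_exposure >= 0 orientation makes Egger invariant to how
        each variant's effect allele was coded."""
        instruments = random_instruments(j=6, seed=13)
        recoded = [make_instrument(i.variant_id, bx=-i.beta_exposure,
                                   sx=i.se_exposure, by=-i.beta_outcome,
                                   sy=i.se_outcome, maf=i.maf)
                   for i in instruments]
        a = egger(instruments)
        b = egger(recoded)
        assert a.slope.theta == pytest.approx(b.slope.theta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([make_instrument("rs1"), make_instrument("rs2")])

    def test_constant_exposure_effects_degenerate(self):
        instruments = [make_instrument(f"rs{k}", bx=0.1, by=0.01 * k)
                       for k in range(4)]
        with pytest.raises(DegenerateDesignError):
            egger(instruments)

    def test_balanced_pleiotropy_intercept_centred_and_test_near_nominal(self):
        """Under balanced pleiotropy (InSIDE holds) the intercept estimate
        is centred on zero and its test rejects near the nominal 5%; the
        multiplicative random-effects convention is mildly anti-conservative
        under additive pleiotropy variance."""
        scenario = strong_instrument_scenario(
            0.263, seed=202, pleiotropy_mode="balanced", alpha_sd=0.02
        )
        metrics = evaluate(400, scenario, methods=("egger",), n_boot=100)
        row = metrics.iloc[0]
        # slope centred on the causal effect (dilution << pleiotropy noise)
        assert abs(row.mean_bias) < 3 * row.bias_mc_se + 0.02
        assert 0.03 <= row.intercept_rejection_rate <= 0.09

    def test_directional_pleiotropy_shifts_intercept_toward_mean(self):
        mu = 0.02
        scenario = strong_instrument_scenario(
            0.3, seed=404, pleiotropy_mode="directional",
            alpha_mean=mu, alpha_sd=0.005, n_instruments=100,
        )
        from mrkit.synthetic import simulate_arrays

        intercepts = []
        for r in range(60):
            a = simulate_arrays(scenario, np.random.default_rng(scenario.seed + r))
            res = egger((a["beta_exposure"], a["se_exposure"],
                         a["beta_outcome"], a["se_outcome"]))
            intercepts.append(res.intercept)
        assert np.mean(intercepts) == pytest.approx(mu, abs=0.005)


class TestSimpleMedian:
    def test_odd_count_middle_order_statistic(self):
        instruments = [make_instrument(f"rs{k}", bx=1.0, by=b, sy=0.1)
                       for k, b in enumerate([0.1, 0.5, 0.9])]
        assert simple_median(instruments, n_boot=100).theta == pytest.approx(0.5)

    def test_even_count_mean_of_central_two(self):
        instruments = [make_instrument(f"rs{k}", bx=1.0, by=b, sy=0.1)
                       for k, b in enumerate([0.0, 0.2, 0.4, 1.0])]
        assert simple_median(instruments, n_boot=100).theta == pytest.approx(0.3)

    def test_same_seed_bit_identical_se(self, random_instruments):
        instruments = random_instruments(j=10, seed=31)
        a = simple_median(instruments, n_boot=500, seed=7)
        b = simple_median(instruments, n_boot=500, seed=7)
        assert a.se == b.se and a.pvalue == b.pvalue

    def test_different_seeds_agree_within_bootstrap_noise(self, random_instruments):
        instruments = random_instruments(j=10, seed=31)
        ses = [simple_median(instruments, n_boot=2000, seed=s).se for s in range(5)]
        spread = np.std(ses, ddof=1)
        assert max(ses) - min(ses) <= 6 * spread + 0.05 * np.mean(ses)

    def test_requires_three_instruments_and_warns_on_tiny_bootstrap(self):
        instruments = [make_instrument("rs1"), make_instrument("rs2")]
        with pytest.raises(InsufficientInstrumentsError):
            simple_median(instruments)
        three = instruments + [make_instrument("rs3")]
        with pytest.warns(UserWarning, match="n_boot"):
            simple_median(three, n_boot=50)

    def test_permutation_invariant(self, random_instruments):
        instruments = random_instruments(j=8, seed=61)
        a = simple_median(instruments, n_boot=100, seed=1).theta
        b = simple_median(list(reversed(instruments)), n_boot=100, seed=1).theta
        assert a == pytest.approx(b)


class TestReportingTransforms:
    def test_null_effect_gives_unit_or_and_symmetric_ci(self):
        or_point, lo, hi = to_odds_ratio(0.0, 0.3, 0.95)
        assert or_point == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_ci_level_changes_width(self):
        _, lo95, hi95 = to_odds_ratio(0.2, 0.1, 0.95)
        _, lo99, hi99 = to_odds_ratio(0.2, 0.1, 0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_zero_theta_gives_p_one(self):
        assert two_sided_p(0.0, 0.5) == 1.0

    def test_p_consistent_with_z_square_chi2(self):
        from scipy import stats

        theta, se = 0.37, 0.11
        assert two_sided_p(theta, se) == pytest.approx(
            stats.chi2.sf((theta / se) ** 2, 1)
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.0)
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.1, confidence=1.0)
        with pytest.raises(ValueError):
            two_sided_p(0.1, -1.0)


def test_ivw_estimates_from_statsmodels_wls_cross_check(random_instruments):
    """Second independent route: statsmodels WLS through the origin must
    agree with the precision-weighted-average implementation."""
    instruments = random_instruments(j=20, seed=99)
    estimate, _ = ivw(instruments, model="fixed")
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    w = 1.0 / np.array([i.se_outcome for i in instruments]) ** 2
    fit = sm.WLS(by, bx[:, None], weights=w).fit()
    assert estimate.theta == pytest.approx(float(fit.params[0]), rel=1e-12)
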