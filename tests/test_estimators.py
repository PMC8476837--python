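"""The five MR estimators: worked instances, oracles, and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabmr.estimators import (ALL_METHODS, ivw, mr_egger, run_all,
                                simple_mode, wald_ratio, weighted_median,
                                weighted_mode)
from metabmr.exceptions import (InsufficientInstrumentsError,
                                UndefinedRatioError)
from metabmr.io import HarmonizedSet
from conftest import random_harmonized


def hs(gamma, Gamma, sigma_y, sigma_x=None):
    gamma = np.asarray(gamma, dtype=float)
    sx = np.full_like(gamma, 0.05) if sigma_x is None else sigma_x
    return HarmonizedSet.from_arrays(gamma, sx, Gamma, sigma_y)


def from_theta(theta, se=0.1):
    """Unit-gamma set whose Wald ratios are exactly `theta` with SE `se`."""
    theta = np.asarray(theta, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), theta.shape)
    return hs(np.ones_like(theta), theta, se)


class TestWaldRatio:
    def test_direct_formula(self):
        r = wald_ratio(gamma=0.20, sigma_x=0.02, Gamma=0.10, sigma_y=0.05)
        assert r.theta == pytest.approx(0.50)
        assert r.se == pytest.approx(0.25)
        assert r.weight == pytest.approx(1 / 0.25 ** 2)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        assert wald_ratio(0.2, 0.02, 0.0, 0.05).theta == 0.0

    def test_joint_negation_symmetry(self):
        a = wald_ratio(0.2, 0.02, 0.1, 0.05)
        b = wald_ratio(-0.2, 0.02, -0.1, 0.05)
        assert a.theta == b.theta and a.se == b.se

    def test_zero_gamma_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.02, 0.1, 0.05)


class TestIVW:
    def test_hand_computed_instance(self, h_two):
        fixed = ivw(h_two, variance_model="fixed")
        rand = ivw(h_two)
        assert fixed.beta == pytest.approx(2.0)
        assert fixed.se == pytest.approx(1 / np.sqrt(2))
        assert rand.extra["Q"] == pytest.approx(2.0)
        assert rand.extra["phi2"] == pytest.approx(2.0)
        assert rand.se == pytest.approx(1.0)

    def test_zero_dispersion_models_coincide(self):
        h = from_theta([0.5, 0.5, 0.5])
        fixed, rand = ivw(h, "fixed"), ivw(h)
        assert rand.beta == pytest.approx(0.5)
        assert rand.extra["Q"] == pytest.approx(0.0, abs=1e-12)
        assert fixed.se == pytest.approx(rand.se)

    def test_equals_weighted_mean_of_ratios(self, rng):
        for _ in range(50):
            h = random_harmonized(rng, J=int(rng.integers(2, 30)))
            theta = h.Gamma / h.gamma
            w = h.gamma ** 2 / h.sigma_y ** 2
            expected = (w * theta).sum() / w.sum()
            assert ivw(h).beta == pytest.approx(expected, rel=1e-12)

    def test_single_instrument_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(from_theta([1.0]))

    def test_unbiased_under_no_pleiotropy(self, rng):
        # 400 replicates, J=20: mean estimate within 3 MC SEs of truth
        beta_true, J, reps = 0.2, 20, 400
        est = np.empty(reps)
        for r in range(reps):
            gamma = rng.uniform(0.08, 0.2, J)
            sy = np.full(J, 0.01)
            Gamma = beta_true * gamma + rng.normal(0, sy)
            est[r] = ivw(hs(gamma, Gamma, sy)).beta
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - beta_true) < 3 * mc_se


class TestEgger:
    def test_exact_line(self, h_line):
        r = mr_egger(h_line)
        assert r.beta == pytest.approx(0.5)
        assert r.extra["intercept"] == pytest.approx(0.1)
        assert r.extra["Q"] == pytest.approx(0.0, abs=1e-10)

    def test_needs_three_instruments(self, h_two):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h_two)

    def test_intercept_recovers_directional_pleiotropy(self, rng):
        # all instruments carry mean-0.05 direct effects
        J, reps, alpha0 = 50, 300, 0.05
        intercepts = np.empty(reps)
        for r in range(reps):
            gamma = rng.uniform(0.05, 0.3, J)
            sy = np.full(J, 0.01)
            Gamma = 0.2 * gamma + alpha0 + rng.normal(0, 0.01, J) \
                + rng.normal(0, sy)
            intercepts[r] = mr_egger(hs(gamma, Gamma, sy)).extra["intercept"]
        mc_se = intercepts.std(ddof=1) / np.sqrt(reps)
        assert abs(intercepts.mean() - alpha0) < 3 * mc_se


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        r = weighted_median(from_theta([1.0, 2.0, 3.0]), n_boot=100, seed=0)
        assert r.beta == pytest.approx(2.0)

    def test_outlier_cannot_drag_estimate(self):
        r = weighted_median(from_theta([1.0, 2.0, 3.0, 100.0]),
                            n_boot=100, seed=0)
        assert 2.0 <= r.beta <= 3.0
        assert r.beta == pytest.approx(2.5)  # interpolation midpoint

    def test_dominant_weight_pins_estimate(self):
        theta = np.array([1.0, 2.0, 3.0])
        se = np.array([1e3, 1e-3, 1e3])  # middle SNP carries all weight
        r = weighted_median(from_theta(theta, se), n_boot=100, seed=0)
        assert r.beta == pytest.approx(2.0, abs=1e-3)

    def test_brute_force_cdf_inversion_oracle(self, rng):
        for _ in range(25):
            J = int(rng.integers(2, 15))
            h = random_harmonized(rng, J=J)
            theta = h.Gamma / h.gamma
            w = h.gamma ** 2 / h.sigma_y ** 2
            # oracle: invert the piecewise-linear weighted CDF on a fine grid
            order = np.argsort(theta)
            t, wn = theta[order], w[order] / w.sum()
            ps = np.cumsum(wn) - wn / 2
            grid = np.linspace(t[0], t[-1], 200_001)
            cdf = np.interp(grid, t, ps)
            expected = grid[np.searchsorted(cdf, 0.5)]
            got = weighted_median(h, n_boot=10, seed=0).beta
            assert got == pytest.approx(expected, abs=(t[-1] - t[0]) / 1e4)


class TestModes:
    def test_majority_cluster_wins(self):
        r = simple_mode(from_theta([0.5, 0.5, 0.5, 3.0]), n_boot=50, seed=0)
        assert r.beta == pytest.approx(0.5, abs=0.1)

    def test_all_equal_ratios(self):
        r = simple_mode(from_theta([0.7, 0.7, 0.7]), n_boot=50, seed=0)
        assert r.beta == pytest.approx(0.7)

    def test_equal_weights_match_simple_mode(self):
        h = from_theta([0.4, 0.5, 0.6, 1.5], se=0.1)  # equal se -> equal w
        s = simple_mode(h, n_boot=50, seed=3)
        w = weighted_mode(h, n_boot=50, seed=3)
        assert w.beta == pytest.approx(s.beta, rel=1e-9)

    def test_dominant_weight_pulls_weighted_mode(self):
        theta = np.array([0.5, 0.52, 0.48, 2.0])
        se = np.array([1.0, 1.0, 1.0, 1e-3])  # last SNP dominates weights
        h = from_theta(theta, se)
        assert weighted_mode(h, n_boot=50, seed=0).beta == \
            pytest.approx(2.0, abs=0.05)
        assert simple_mode(h, n_boot=50, seed=0).beta == \
            pytest.approx(0.5, abs=0.1)

    def test_grid_search_oracle_with_varied_bandwidth(self, rng):
        for phi in (0.5, 1.0, 2.0):
            h = random_harmonized(rng, J=12)
            theta = h.Gamma / h.gamma
            J = len(theta)
            sd = theta.std(ddof=1)
            mad = np.median(np.abs(theta - np.median(theta))) * 1.4826
            s = min(x for x in (sd, mad) if x > 0)
            bw = phi * 1.06 * s * J ** (-0.2)
            grid = np.linspace(theta.min() - 3 * bw, theta.max() + 3 * bw,
                               200_001)
            dens = np.exp(-0.5 * ((grid[:, None] - theta) / bw) ** 2).sum(1)
            expected = grid[np.argmax(dens)]
            got = simple_mode(h, bandwidth_factor=phi, n_boot=10, seed=0).beta
            assert got == pytest.approx(expected, abs=bw / 100)

    def test_planted_seventy_percent_valid_recovery(self, rng):
        # 70% valid instruments around theta=0.2, 30% pleiotropic spread
        beta_true, J = 0.2, 40
        gamma = rng.uniform(0.1, 0.3, J)
        sy = np.full(J, 0.004)
        Gamma = beta_true * gamma + rng.normal(0, sy)
        bad = rng.choice(J, 12, replace=False)
        Gamma[bad] += rng.uniform(0.05, 0.2, 12) * gamma[bad]
        r = weighted_mode(hs(gamma, Gamma, sy), n_boot=100, seed=0)
        assert r.beta == pytest.approx(beta_true, abs=0.05)


class TestCrossCuttingProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.1, 5.0))
    def test_scale_equivariance(self, seed, c):
        """Scaling Gamma and sigma_y by c scales every beta and se by c."""
        rng = np.random.default_rng(seed)
        h = random_harmonized(rng, J=8)
        h2 = HarmonizedSet.from_arrays(h.gamma, h.sigma_x, c * h.Gamma,
                                       c * h.sigma_y)
        r1 = run_all(h, n_boot=80, seed=5)
        r2 = run_all(h2, n_boot=80, seed=5)
        for m in ALL_METHODS:
            assert r2[m].beta == pytest.approx(c * r1[m].beta, rel=1e-6,
                                               abs=1e-9)
            assert r2[m].se == pytest.approx(c * r1[m].se, rel=1e-6, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_orientation_invariance(self, seed):
        """Jointly negating (gamma, Gamma) of any SNP changes no estimate."""
        rng = np.random.default_rng(seed)
        h = random_harmonized(rng, J=8)
        flip = rng.random(8) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        h2 = HarmonizedSet.from_arrays(sign * h.gamma, h.sigma_x,
                                       sign * h.Gamma, h.sigma_y)
        r1 = run_all(h, n_boot=80, seed=5)
        r2 = run_all(h2, n_boot=80, seed=5)
        for m in ALL_METHODS:
            assert r2[m].beta == pytest.approx(r1[m].beta, rel=1e-9, abs=1e-12)

    def test_bootstrap_reproducible_with_seed(self, rng):
        h = random_harmonized(rng, J=10)
        a = weighted_median(h, n_boot=200, seed=11)
        b = weighted_median(h, n_boot=200, seed=11)
        c = weighted_median(h, n_boot=200, seed=12)
        assert a.se == b.se
        assert a.se != c.se

    def test_or_ci_identity(self, rng):
        h = random_harmonized(rng, J=10)
        for r in run_all(h, n_boot=50, seed=0).values():
            assert r.or_ == pytest.approx(np.exp(r.beta), rel=1e-15)
            assert r.ci_low < r.or_ < r.ci_high

    def test_estimators_agree_without_pleiotropy_large_j(self, rng):
        # J=200 valid instruments: all five converge on the same effect
        J, beta_true = 200, 0.2
        gamma = rng.uniform(0.05, 0.3, J)
        sy = np.full(J, 0.003)
        Gamma = beta_true * gamma + rng.normal(0, sy)
        res = run_all(hs(gamma, Gamma, sy), n_boot=100, seed=0)
        betas = [res[m].beta for m in ALL_METHODS]
        assert max(betas) - min(betas) < 0.03
        for b in betas:
            assert b == pytest.approx(beta_true, abs=0.03)
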