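import math

import numpy as np
import pytest
from scipy import stats as sps

from polardfe.dfe import (
    DFEParams, DemographyModel, binomial_sojourn, discretize_gamma,
    effect_bins, expected_sfs, fixation_rate, lrt, lrt_partition,
    sojourn_density,
)

from _oracles import wf_expected_sfs


class TestSojournDensity:
    def test_neutral_limit(self):
        x = np.linspace(0.01, 0.99, 50)
        assert np.allclose(sojourn_density(x, 0.0), 2.0 / x)
        assert np.allclose(sojourn_density(x, 1e-12), 2.0 / x, rtol=1e-6)

    def test_strong_selection_vanishes(self):
        assert sojourn_density(0.5, -200.0) < 1e-10
        assert sojourn_density(0.5, -5000.0) == pytest.approx(0.0, abs=1e-30)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                sojourn_density(bad, -1.0)

    def test_matches_wright_fisher_stationary_flux(self):
        """tau(x; S) at x = 0.3, S = -5 agrees with an independent
        2N = 200 transition-matrix stationary density within 2%.

        Unit influx per generation gives an equilibrium density of
        tau(j/2N) / 2N sites at copy number j."""
        from _oracles import wf_stationary_density

        M, S = 200, -5.0
        v = wf_stationary_density(M, S)
        k = int(0.3 * M) - 1  # grid point at x = 0.3
        assert v[k] * M == pytest.approx(sojourn_density(0.3, S), rel=0.02)

    def test_advantageous_exceeds_neutral_at_high_frequency(self):
        assert sojourn_density(0.9, 10.0) > sojourn_density(0.9, 0.0)


class TestFixationRate:
    def test_limits(self):
        assert fixation_rate(0.0) == 1.0
        assert fixation_rate(1e-12) == pytest.approx(1.0)
        assert fixation_rate(-100.0) == pytest.approx(0.0, abs=1e-40)
        assert fixation_rate(50.0) == pytest.approx(50.0, rel=1e-10)
        assert fixation_rate(-1000.0) == 0.0  # deep clamp, no overflow


class TestExpectedSfs:
    def test_neutral_watterson(self):
        """Segregating classes are exactly proportional to 1/i."""
        n, L, theta = 12, 50_000, 0.001
        e = expected_sfs(n, [(0.0, 1.0)], theta, 2.0, L)
        i = np.arange(1, n)
        assert np.allclose(e[1:n], L * theta * 2.0 / i, rtol=1e-6)
        assert e[0] == pytest.approx(L - e[1:].sum())

    def test_purifying_selection_skews_to_singletons(self):
        n = 12
        e_neu = expected_sfs(n, [(0.0, 1.0)], 0.001, 2.0, 10_000)
        e_del = expected_sfs(n, [(-100.0, 1.0)], 0.001, 2.0, 10_000)
        share = lambda e: e[1] / e[1:n].sum()
        assert share(e_del) > share(e_neu)

    def test_matches_wf_matrix_oracle(self):
        """Full segregating vector at n = 6, S = -2 agrees with the dense
        2N = 200 Wright-Fisher oracle within 2% per entry."""
        n, S = 6, -2.0
        e = expected_sfs(n, [(S, 1.0)], 0.001, 1.0, 10_000)
        shape = e[1:n] / e[1:n].sum()
        oracle = wf_expected_sfs(n, S, two_n=200)
        assert np.all(np.abs(shape / oracle - 1.0) < 0.02)

    def test_total_segregating_decreasing_in_selection_strength(self):
        n = 12
        totals = [expected_sfs(n, [(S, 1.0)], 0.001, 1.0, 10_000)[1:n].sum()
                  for S in (0.0, -1.0, -5.0, -25.0, -125.0)]
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            expected_sfs(12, [(0.0, 0.4)], 0.001, 1.0, 1000)

    def test_two_epoch_r1_is_exactly_constant(self):
        """On the grid, size_ratio = 1 is the constant model exactly: any
        change time leaves the equilibrium untouched (exact nesting of the
        demography LRT)."""
        from polardfe.wright_fisher import TwoEpochExpectation

        model = TwoEpochExpectation(100)
        b0, bn0 = model.sampled_bins(12, 1.0, 0.0, 0.0)
        b1, bn1 = model.sampled_bins(12, 1.0, 0.4, 0.0)
        assert np.array_equal(b0, b1) and bn0 == bn1

    def test_grid_converges_to_diffusion_spectrum(self):
        """The grid spectrum shape approaches the closed-form constant-size
        spectrum as the grid is refined."""
        from polardfe.wright_fisher import TwoEpochExpectation

        n = 12
        e1 = expected_sfs(n, [(0.0, 1.0)], 0.001, 2.0, 10_000)
        target = e1[1:n] / e1[1:n].sum()

        def dev(M):
            b, _ = TwoEpochExpectation(M).sampled_bins(n, 1.0, 0.0, 0.0)
            s = b / b.sum()
            return np.abs(s / target - 1.0).max()

        assert dev(400) < dev(100) < dev(40)
        assert dev(400) < 0.01

    def test_expansion_produces_singleton_excess(self):
        n = 12
        demog = DemographyModel(kind="two_epoch", size_ratio=5.0,
                                change_time=0.1, grid_size=100)
        e2 = expected_sfs(n, [(0.0, 1.0)], 0.001, 2.0, 50_000, demography=demog)
        e1 = expected_sfs(n, [(0.0, 1.0)], 0.001, 2.0, 50_000)
        assert e2[1] / e2[1:n].sum() > e1[1] / e1[1:n].sum()


class TestDiscretizeGamma:
    def test_single_point(self):
        s, w = discretize_gamma(140.3, 0.28, K=1)
        assert np.array_equal(s, [-140.3]) and np.array_equal(w, [1.0])

    @pytest.mark.parametrize("K", [2, 10, 50, 200])
    def test_weights_sum_to_one(self, K):
        _, w = discretize_gamma(140.3, 0.28, K)
        assert w.sum() == pytest.approx(1.0)

    def test_moment_match(self):
        """K = 200 mixture mean reproduces the analytic mean within 1%
        (the tail slab is clamped, so slightly low)."""
        s, w = discretize_gamma(140.3, 0.28, K=200)
        assert abs(-(s @ w) / 140.3 - 1.0) < 0.01

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            discretize_gamma(-1.0, 0.3)
        with pytest.raises(ValueError):
            discretize_gamma(10.0, 0.3, K=0)


class TestEffectBins:
    def test_printed_reference_totals(self):
        b = effect_bins(DFEParams(deleterious_kind="gamma",
                                  NeSd_mean=140.3, beta_d=0.28))
        assert b.p_gt100 == pytest.approx(0.32, abs=0.01)
        assert b.p_lt1 == pytest.approx(0.20, abs=0.01)

    def test_equal_effects_point_mass(self):
        b = effect_bins(DFEParams(deleterious_kind="equal", NeSd_mean=50.0))
        assert b.as_array().tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_boundary_mean_all_strong(self):
        b = effect_bins(DFEParams(deleterious_kind="gamma",
                                  NeSd_mean=math.inf, beta_d=0.05))
        assert b.as_array().tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_none_kind_errors(self):
        with pytest.raises(ValueError):
            effect_bins(DFEParams(deleterious_kind="none"))

    def test_sum_to_one_and_quadrature_invariance(self):
        """Proportions come from the gamma CDF directly, so they sum to 1
        and cannot depend on the likelihood quadrature K."""
        rng = np.random.default_rng(1)
        for _ in range(25):
            p = DFEParams(deleterious_kind="gamma",
                          NeSd_mean=10 ** rng.uniform(-1, 4),
                          beta_d=10 ** rng.uniform(-1.3, 1.3))
            assert effect_bins(p).as_array().sum() == pytest.approx(1.0)


class TestLRT:
    def test_pooled_vs_partitioned_reference_arithmetic(self):
        res = lrt_partition((-2666.78, 1), [(-1995.85, 1), (-590.47, 1)])
        assert res.statistic == pytest.approx(160.92, abs=5e-3)
        assert res.df == 1

    def test_identical_likelihoods(self):
        res = lrt((-100.0, 1), (-100.0, 2))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_tail_probability(self):
        res = lrt((-100.0, 2), (-100.0 + 82.86 / 2, 40))
        assert res.df == 38
        assert res.p_value == pytest.approx(3.5e-5, abs=0.5e-5)

    def test_negative_statistic_raises(self):
        with pytest.raises(ValueError):
            lrt((-99.0, 1), (-100.0, 2))
        with pytest.raises(ValueError):
            lrt((-100.0, 2), (-99.0, 2))
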