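import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import helpers
from geosfs import (
    ModelParams,
    PanmicticParams,
    SamplingKernel,
    characteristic_length,
    effective_params,
    expected_sfs,
    panmictic_density,
    sampling_effect_scalar,
    scaled_exp_e1,
    sfs_ratio_to_uniform,
    small_theta_sfs,
    summary_expectations,
)

FOUR_PI = 4.0 * math.pi


class TestCharacteristicLength:
    @pytest.mark.parametrize(
        "sigma,s,expected", [(10, 0.01, 100.0), (10, 1.0, 10.0), (20, 0.04, 100.0)]
    )
    def test_known_values(self, sigma, s, expected):
        assert characteristic_length(sigma, s) == pytest.approx(expected)

    def test_monotone_in_selection_and_dispersal(self):
        assert characteristic_length(10, 0.04) < characteristic_length(10, 0.01)
        assert characteristic_length(5, 0.01) < characteristic_length(10, 0.01)

    @pytest.mark.parametrize("sigma,s", [(0, 0.1), (-1, 0.1), (10, 0), (10, 1.5)])
    def test_domain_errors(self, sigma, s):
        with pytest.raises(ValueError):
            characteristic_length(sigma, s)


class TestScaledExpE1:
    def test_matches_quadrature_at_moderate_x(self):
        for x in [0.1, 0.5, 1.0, 3.0, 20.0]:
            assert scaled_exp_e1(x) == pytest.approx(
                math.exp(x) * helpers.e1_quadrature(x), rel=1e-9
            )

    def test_unit_value(self):
        # e * E1(1) with E1(1) = 0.219384 from the defining integral
        assert scaled_exp_e1(1.0) == pytest.approx(0.59634736, abs=1e-8)

    def test_small_x_series(self):
        x = 1e-12
        assert scaled_exp_e1(x) == pytest.approx(helpers.e1_small_series(x), rel=1e-10)
        assert scaled_exp_e1(x) == pytest.approx(27.054, abs=5e-4)

    def test_large_x_asymptote(self):
        for x in [1e6, 1e8, 1e9]:
            assert scaled_exp_e1(x) == pytest.approx(helpers.scaled_e1_asymptotic(x), rel=1e-12)
        assert scaled_exp_e1(1e8) == pytest.approx(1e-8, rel=1e-7)

    @given(st.floats(min_value=1e-12, max_value=1e9))
    def test_sandwich_bounds(self, x):
        # classical sandwich: 0.5*ln(1 + 2/x) < e^x E1(x) < ln(1 + 1/x) <= 1/x
        val = scaled_exp_e1(x)
        lo = 0.5 * math.log1p(2.0 / x)
        hi = min(math.log1p(1.0 / x), 1.0 / x)
        assert lo * (1 - 1e-12) <= val <= hi * (1 + 1e-12)

    def test_monotone_decreasing(self):
        xs = np.logspace(-10, 9, 150)
        vals = scaled_exp_e1(xs)
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("x", [0.0, -1.0, np.inf, np.nan])
    def test_domain_errors(self, x):
        with pytest.raises(ValueError):
            scaled_exp_e1(x)


class TestSamplingEffectScalar:
    def test_depends_only_on_ratio(self):
        assert sampling_effect_scalar(10, 100) == sampling_effect_scalar(1, 10)
        assert sampling_effect_scalar(35.0, 7.0) == sampling_effect_scalar(5.0, 1.0)

    def test_broad_sampling_asymptote(self):
        # lambda -> 4*pi*(w/ell_c)^2 for broad sampling
        lam = sampling_effect_scalar(100.0, 1.0)
        assert lam == pytest.approx(FOUR_PI * 1e4, rel=2e-4)

    def test_narrow_sampling_asymptote(self):
        # lambda -> -2*pi/ln(w/ell_c) for narrow sampling
        lam = sampling_effect_scalar(1e-6, 1.0)
        assert lam == pytest.approx(-2 * math.pi / math.log(1e-6), rel=0.03)

    def test_strictly_increasing_in_breadth(self):
        ws = np.logspace(-8, 4, 200)
        lams = sampling_effect_scalar(ws, 1.0)
        assert np.all(np.diff(lams) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sampling_effect_scalar(-1.0, 1.0)
        with pytest.raises(ValueError):
            sampling_effect_scalar(1.0, 0.0)


class TestEffectiveParams:
    def test_selection_mutation_ratio_cancellation(self, reference_regime):
        # gamma_E / theta_E = s / mu exactly, for any kernel
        for kernel in [
            SamplingKernel.uniform(),
            SamplingKernel.gaussian(3.0),
            SamplingKernel.gaussian(100.0),
            SamplingKernel.gaussian(5000.0),
        ]:
            eff = effective_params(reference_regime, kernel)
            assert eff.gamma_E / eff.theta_E == pytest.approx(
                reference_regime.s / reference_regime.mu, rel=1e-12
            )

    def test_uniform_kernel_census_values(self):
        p = ModelParams(sigma=10, s=0.01, mu=1e-9, rho=20, L=1000)
        eff = effective_params(p, SamplingKernel.uniform())
        assert eff.theta_E == pytest.approx(0.02)  # N*mu = 2e7 * 1e-9
        assert eff.gamma_E == pytest.approx(2e5)  # N*s

    def test_gaussian_kernel_worked_example(self, reference_regime, gaussian_w100):
        # w = ell_c = 100: lambda = 4*pi / (e * E1(1)), via the quadrature oracle
        lam_oracle = FOUR_PI / (math.exp(1) * helpers.e1_quadrature(1.0))
        eff = effective_params(reference_regime, gaussian_w100)
        assert eff.ell_c == pytest.approx(100.0)
        assert eff.lam == pytest.approx(lam_oracle, rel=1e-8)
        assert eff.theta_E == pytest.approx(1e-9 * 20 * 100**2 * lam_oracle, rel=1e-8)
        assert eff.gamma_E == pytest.approx(0.01 * 20 * 100**2 * lam_oracle, rel=1e-8)

    def test_effective_population_capped_at_census(self, reference_regime):
        # very broad kernels cannot sample more than the whole population
        wide = effective_params(reference_regime, SamplingKernel.gaussian(10 * reference_regime.L))
        unif = effective_params(reference_regime, SamplingKernel.uniform())
        assert wide.theta_E == pytest.approx(unif.theta_E)
        assert wide.gamma_E == pytest.approx(unif.gamma_E)
        for w in [10.0, 100.0, 400.0, 2000.0]:
            eff = effective_params(reference_regime, SamplingKernel.gaussian(w))
            assert eff.theta_E <= unif.theta_E * (1 + 1e-12)
            assert eff.gamma_E <= unif.gamma_E * (1 + 1e-12)


class TestExpectedSFS:
    def test_zero_class_closed_form(self, reference_regime, gaussian_w100):
        eff = effective_params(reference_regime, gaussian_w100)
        sfs = expected_sfs(eff, n=10_000, k_max=10)
        xi0 = (eff.gamma_E / (eff.gamma_E + 10_000)) ** eff.theta_E
        assert sfs.xi[0] == pytest.approx(xi0, rel=1e-12)

    def test_matches_gamma_poisson_quadrature(self, reference_regime, gaussian_w100):
        eff = effective_params(reference_regime, gaussian_w100)
        sfs = expected_sfs(eff, n=10_000, k_max=5)
        for k in range(6):
            oracle = helpers.xi_gamma_poisson(k, eff.theta_E, eff.gamma_E, 10_000)
            assert sfs.xi[k] == pytest.approx(oracle, abs=1e-10)
        assert sfs.xi[1] == pytest.approx(8.08e-4, rel=2e-3)

    def test_mean_identity_and_normalization(self, reference_regime):
        for kernel in [SamplingKernel.gaussian(30.0), SamplingKernel.uniform()]:
            eff = effective_params(reference_regime, kernel)
            sfs = expected_sfs(eff, n=10_000, k_max=400)
            assert sfs.tail_mass < 1e-12
            total = sfs.xi.sum() + sfs.tail_mass
            assert total == pytest.approx(1.0, abs=1e-12)
            mean = (np.arange(401) * sfs.xi).sum()
            assert mean == pytest.approx(10_000 * reference_regime.mu / reference_regime.s, rel=1e-10)

    def test_extreme_parameters_do_not_overflow(self):
        from geosfs.params import EffectiveParams

        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=1e-2, gamma_E=1e12)
        sfs = expected_sfs(eff, n=10_000_000, k_max=50)
        assert np.all(np.isfinite(sfs.xi))
        assert sfs.xi[0] == pytest.approx(1.0, abs=1e-3)

    def test_invalid_sizes(self, reference_regime, gaussian_w100):
        eff = effective_params(reference_regime, gaussian_w100)
        with pytest.raises(ValueError):
            expected_sfs(eff, n=0, k_max=10)
        with pytest.raises(ValueError):
            expected_sfs(eff, n=100, k_max=0)


class TestSmallThetaSFS:
    def test_singleton_closed_form(self, reference_regime, gaussian_w100):
        eff = effective_params(reference_regime, gaussian_w100)
        n = 10_000
        expected = eff.theta_E * n / (eff.gamma_E + n)
        assert small_theta_sfs(eff, n, 1) == pytest.approx(expected, rel=1e-12)
        # within 0.1% of the exact NegBin value in this regime
        exact = expected_sfs(eff, n=n, k_max=1).xi[1]
        assert small_theta_sfs(eff, n, 1) == pytest.approx(exact, rel=1e-3)

    def test_relative_error_vanishes_for_small_theta(self):
        from geosfs.params import EffectiveParams

        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=1e-6, gamma_E=3e4)
        n = 10_000
        ks = np.arange(1, 51)
        approx = small_theta_sfs(eff, n, ks)
        exact = expected_sfs(eff, n=n, k_max=50).xi[1:]
        assert np.max(np.abs(approx / exact - 1.0)) < 1e-4

    def test_monomorphic_class_rejected(self, reference_regime, gaussian_w100):
        eff = effective_params(reference_regime, gaussian_w100)
        with pytest.raises(ValueError):
            small_theta_sfs(eff, 100, 0)


class TestPanmicticDensity:
    def test_neutral_flat_case(self):
        pan = PanmicticParams(gamma=0.0, theta=1.0)
        xs = np.array([0.01, 0.3, 0.9])
        assert np.allclose(panmictic_density(pan, xs), 1.0)

    def test_midpoint_value(self):
        pan = PanmicticParams(gamma=8.0, theta=1.0)
        assert panmictic_density(pan, 0.5) == pytest.approx(math.exp(-4.0))

    def test_log_and_direct_evaluation_agree(self):
        pan = PanmicticParams(gamma=100.0, theta=0.5)
        ratio_direct = panmictic_density(pan, 0.1) / panmictic_density(pan, 0.01)
        ratio_log = math.exp(panmictic_density(pan, 0.1, log=True) - panmictic_density(pan, 0.01, log=True))
        assert ratio_direct == pytest.approx(ratio_log, rel=1e-12)

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.1, 1.5])
    def test_frequency_domain(self, x):
        with pytest.raises(ValueError):
            panmictic_density(PanmicticParams(gamma=1.0, theta=1.0), x)


class TestSummaryExpectations:
    def test_mean_frequency_independent_of_kernel(self, reference_regime):
        kernels = [SamplingKernel.gaussian(10.0), SamplingKernel.gaussian(100.0), SamplingKernel.uniform()]
        vals = [
            summary_expectations(effective_params(reference_regime, k), reference_regime, 10_000)["mean_freq_all"]
            for k in kernels
        ]
        assert vals[0] == vals[1] == vals[2] == pytest.approx(1e-7)

    def test_variant_probability_complement(self, reference_regime, gaussian_w100):
        eff = effective_params(reference_regime, gaussian_w100)
        rec = summary_expectations(eff, reference_regime, 10_000)
        xi0 = (eff.gamma_E / (eff.gamma_E + 10_000)) ** eff.theta_E
        assert rec["prop_variant"] == pytest.approx(1.0 - xi0, rel=1e-12)
        assert rec["prop_variant"] == pytest.approx(8.97e-4, rel=2e-3)

    def test_heterozygosity_from_negbin_moments(self, reference_regime, gaussian_w100):
        eff = effective_params(reference_regime, gaussian_w100)
        n = 10_000
        rec = summary_expectations(eff, reference_regime, n)
        sfs = expected_sfs(eff, n=n, k_max=600)
        ks = np.arange(601)
        het = (2 * ks / n * (1 - ks / n) * sfs.xi).sum()
        assert rec["expected_het_all"] == pytest.approx(het, rel=1e-9)


class TestSFSRatioToUniform:
    def test_uniform_self_ratio(self, reference_regime):
        ratio, crossing = sfs_ratio_to_uniform(reference_regime, None, 10_000, 50)
        assert np.allclose(ratio, 1.0)
        assert crossing is None

    def test_narrow_kernel_deficit_then_excess(self, reference_regime):
        ratio, crossing = sfs_ratio_to_uniform(reference_regime, 50.0, 10_000, 200)
        assert ratio[0] < 1.0
        assert crossing is not None
        assert np.all(ratio[crossing :] >= 1.0 - 1e-9)

    def test_crossing_index_grows_with_sample_size(self, reference_regime):
        crossings = []
        for n in [1_000, 10_000, 100_000]:
            _, crossing = sfs_ratio_to_uniform(reference_regime, 50.0, n, 3000)
            assert crossing is not None
            crossings.append(crossing)
        assert crossings == sorted(crossings)
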