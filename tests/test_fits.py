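"""Law fitting and hypothesis tests, checked against brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats

import mycelia as m
from mycelia import fits, laws
from mycelia.published import M2_D_H2_PER_MM2, M0_D_H2_PER_MM2, M2_OMEGA_PER_H

LN2 = math.log(2.0)


class TestBase2ExponentialFit:
    def test_exact_series_recovered_to_machine_precision(self):
        t = np.arange(0.0, 10.5, 0.5)
        y = 3.0 * 2.0 ** (0.4 * t)
        fit = m.fit_base2_exponential(t, y)
        assert fit.C == pytest.approx(3.0, abs=1e-9)
        assert fit.omega == pytest.approx(0.4, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_gives_zero_rate(self):
        fit = m.fit_base2_exponential([0, 1, 2, 3], [5, 5, 5, 5])
        assert fit.omega == pytest.approx(0.0, abs=1e-12)

    def test_poisson_noise_recovery(self, rng):
        t = np.arange(0.3, 15.0, 0.3)
        est = []
        for _ in range(60):
            y = np.maximum(rng.poisson(4.0 * 2.0 ** (0.48 * t)), 1)
            est.append(m.fit_base2_exponential(t, y).omega)
        assert abs(np.mean(est) - 0.48) < 0.02

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            m.fit_base2_exponential([0, 1, 2], [1.0, 0.0, 2.0])


class TestShiftedExponentialFit:
    def test_exact_cdf_samples_near_perfect_linearized_fit(self):
        q = np.linspace(0.0005, 0.9995, 5000)
        L = 180.0 - np.log(1 - q) / (10.4e-3 * LN2)
        fit = m.fit_shifted_exponential_cdf(L)
        assert fit.quality.r2 > 0.999
        assert fit.alpha_per_um == pytest.approx(10.4e-3, rel=0.05)
        assert 180.0 <= fit.L0_maxslope_um <= 200.0

    def test_small_collection_coverage_matches_printed_uncertainty(self, rng):
        """At the experimental scale (n=109) the fitted rate lands within
        the printed +-3.9e-3 band in at least 90% of replicates."""
        hits = 0
        for _ in range(200):
            L = 180.0 + laws.exp2(rng, 10.4e-3, size=109)
            fit = m.fit_shifted_exponential_cdf(L)
            hits += abs(fit.alpha_per_um - 10.4e-3) <= 3.9e-3
        assert hits >= 180

    def test_too_few_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            m.fit_shifted_exponential_cdf(np.arange(10.0))


class TestMixtureFit:
    def test_pure_exponential_has_no_uniform_floor(self, rng):
        dl = laws.exp2(rng, 2.3e-3, size=10_000)
        fit = m.fit_mixture_exponential_uniform(dl)
        assert fit.uniform_fraction < 0.05
        assert fit.gamma1_per_um == pytest.approx(2.3e-3, abs=0.3e-3)

    def test_pure_uniform_is_all_uniform(self, rng):
        dl = rng.uniform(0, 3000.0, size=5000)
        fit = m.fit_mixture_exponential_uniform(dl)
        assert fit.uniform_fraction > 0.8

    def test_printed_mixture_recovered(self, rng):
        """78%/22% exponential/uniform mixture at the printed parameters."""
        n = 10_000
        dl = laws.exp2(rng, 2.3e-3, size=n)
        iso = rng.random(n) < 0.22
        dl[iso] = rng.uniform(0.0, 5000.0, size=int(iso.sum()))
        fit = m.fit_mixture_exponential_uniform(dl)
        assert fit.gamma1_per_um == pytest.approx(2.3e-3, abs=2 * 0.3e-3)
        assert fit.uniform_fraction == pytest.approx(0.22, abs=2 * 0.11)
        assert fit.Gamma1 > 0 and fit.r_uniform > 0

    def test_exact_exponential_counts_recovered_to_tolerance(self):
        # noise-free binned counts of a pure base-2 exponential
        centers = np.arange(25.0, 3000.0, 50.0)
        counts = np.rint(1000.0 * 2.0 ** (-2.3e-3 * centers)).astype(int)
        dl = np.repeat(centers, counts)
        fit = m.fit_mixture_exponential_uniform(dl, bin_width_um=50.0)
        assert fit.gamma1_per_um == pytest.approx(2.3e-3, rel=0.02)

    def test_experimental_scale_two_population_detection(self, rng):
        n = 156
        dl = laws.exp2(rng, 2.3e-3, size=n)
        iso = rng.random(n) < 0.22
        dl[iso] = rng.uniform(0.0, 5000.0, size=int(iso.sum()))
        fit = m.fit_mixture_exponential_uniform(dl, bin_width_um=145.0)
        assert 0.11 - 0.11 <= fit.uniform_fraction <= 0.33 + 0.11


class TestDensityModel:
    def test_simulation_rate_gives_five_hours(self):
        assert m.t_min(0.59, 2) == pytest.approx(4.890, abs=0.01)
        assert round(m.t_min(0.59, 2)) == 5

    def test_mean_standard_medium_rate_gives_six_hours(self):
        omega = float(np.mean(M2_OMEGA_PER_H))
        assert m.t_min(omega, 2) == pytest.approx(6.05, abs=0.01)

    def test_t_min_linear_in_polynomial_order(self):
        assert m.t_min(0.5, 4) == pytest.approx(2 * m.t_min(0.5, 2))

    def test_density_model_assembly(self):
        model = m.density_model(C=4.0, omega=0.47, B1=0.098, B2=0.107)
        assert model.D == pytest.approx(4.0 / (0.098 * 0.107))
        assert model.t_min_h == pytest.approx(2.0 / (0.47 * LN2))
        with pytest.raises(ValueError):
            m.density_model(0.0, 0.5, 1.0, 1.0)


class TestIsolatedHalflength:
    def test_printed_rate_gives_eighty_micrometres(self):
        L = m.isolated_halflength(6e-3)
        assert L == pytest.approx(83.33, abs=0.01)
        assert round(L, -1) == 80.0  # one significant figure

    def test_scaling(self):
        assert m.isolated_halflength(0.5) == pytest.approx(1.0)
        assert m.isolated_halflength(3e-3) == pytest.approx(
            2 * m.isolated_halflength(6e-3))


class TestEarlyPowerLaw:
    def test_exact_power_law(self):
        t = np.arange(0.3, 8.0, 0.3)
        rho = 5.0 * t ** -2.0
        fit = m.fit_early_power(t, rho, t_min_h=6.0)
        assert fit.alpha_early == pytest.approx(2.0, abs=1e-9)
        assert fit.quality.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.beta == pytest.approx(5.0, rel=1e-9)

    def test_model_curve_fits_below_two(self):
        # early in D 2^(wt)/t^2 the exponential is ~1 and pulls the
        # apparent exponent below 2
        t = np.arange(0.3, 5.2, 0.3)
        rho = 200.0 * 2.0 ** (0.5 * t) / t ** 2
        fit = m.fit_early_power(t, rho, t_min_h=2.0 / (0.5 * LN2))
        assert 1.0 < fit.alpha_early < 2.0

    def test_emulated_standard_medium_series(self, rng):
        """Constant early apex count with linearly spreading cloud: the
        decay exponent sits in the measured 2.1 +- 0.3 band."""
        t = np.arange(0.3, 5.5, 0.3)
        est = []
        for _ in range(30):
            n1 = np.maximum(rng.poisson(6.0, size=t.size), 1)
            rho = n1 / (0.098 * 0.107 * t ** 2)
            est.append(m.fit_early_power(t, rho, t_min_h=6.0).alpha_early)
        assert 1.8 <= np.mean(est) <= 2.4

    def test_fixed_exponent_never_beats_free_fit(self, rng):
        t = np.arange(0.3, 5.5, 0.3)
        for _ in range(10):
            rho = np.exp(rng.normal(0, 0.3, t.size)) * t ** -rng.uniform(1, 3)
            free = m.fit_early_power(t, rho, t_min_h=6.0)
            fixed = m.fit_early_power(t, rho, t_min_h=6.0, fixed_alpha=2.0)
            assert fixed.quality.r2 <= free.quality.r2 + 1e-12


def _binom_two_sided_oracle(k, n, p0=0.5):
    pk = stats.binom.pmf(k, n, p0)
    return sum(stats.binom.pmf(i, n, p0) for i in range(n + 1)
               if stats.binom.pmf(i, n, p0) <= pk * (1 + 1e-12))


class TestBinomialOrientation:
    def test_balanced_outcome(self):
        assert m.binomial_orientation_test(99, 198).p_value == pytest.approx(1.0)

    def test_printed_fifty_four_percent_case(self):
        res = m.binomial_orientation_test(107, 198)
        assert 0.27 <= res.p_value <= 0.29

    def test_eighty_two_percent_clearly_rejects(self):
        assert m.binomial_orientation_test(163, 198).p_value < 1e-10

    def test_bonferroni_adjustment(self):
        res = m.binomial_orientation_test(107, 198, m_comparisons=3)
        assert res.p_adjusted == pytest.approx(min(1.0, 3 * res.p_value))

    @pytest.mark.parametrize("k,n", [(107, 198), (163, 198), (40, 100), (0, 7)])
    def test_matches_enumeration_oracle(self, k, n):
        res = m.binomial_orientation_test(k, n)
        assert res.p_value == pytest.approx(_binom_two_sided_oracle(k, n),
                                            abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            m.binomial_orientation_test(5, 3)


def _anova_oracle(*groups):
    """Explicit sums-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, stats.f.sf(f, df1, df2)


class TestMediaComparison:
    def test_identical_groups(self):
        f, df1, df2, p = m.one_way_anova([1, 2, 3], [1, 2, 3])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_printed_table_values(self):
        f, df1, df2, p = m.one_way_anova(M2_D_H2_PER_MM2, M0_D_H2_PER_MM2)
        assert (df1, df2) == (1, 4)
        assert f == pytest.approx(45.72, abs=0.05)
        assert p == pytest.approx(0.0025, abs=0.001)
        w, pl = m.levene_mean_centered(M2_D_H2_PER_MM2, M0_D_H2_PER_MM2)
        assert pl == pytest.approx(0.8411, abs=0.01)
        assert np.mean(M2_D_H2_PER_MM2) == pytest.approx(222, abs=1)
        assert np.mean(M0_D_H2_PER_MM2) == pytest.approx(442, abs=1)

    def test_anova_matches_explicit_sums_oracle(self, rng):
        for _ in range(5):
            g1 = rng.normal(0, 1, size=6)
            g2 = rng.normal(0.5, 1.5, size=8)
            g3 = rng.normal(-0.2, 0.8, size=5)
            f, _, _, p = m.one_way_anova(g1, g2, g3)
            f0, p0 = _anova_oracle(g1, g2, g3)
            assert f == pytest.approx(f0, abs=1e-9)
            assert p == pytest.approx(p0, abs=1e-9)

    def test_levene_is_anova_on_mean_deviations(self, rng):
        g1 = rng.normal(0, 1, size=7)
        g2 = rng.normal(0, 2, size=9)
        w, p = m.levene_mean_centered(g1, g2)
        z1 = np.abs(g1 - g1.mean())
        z2 = np.abs(g2 - g2.mean())
        f0, p0 = _anova_oracle(z1, z2)
        assert w == pytest.approx(f0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            m.one_way_anova([1, 2, 3])
        with pytest.raises(ValueError):
            m.levene_mean_centered([1], [2, 3])


class TestEigenGrowth:
    def test_linear_law_exact(self):
        t = np.arange(1.0, 10.0, 0.5)
        fit = m.fit_eigen_growth(t, 0.103 * t)
        assert fit.B_um_per_h == pytest.approx(0.103, abs=1e-9)
        assert fit.quality.r2 == pytest.approx(1.0, abs=1e-12)

    def test_saturating_law_exact(self):
        t = np.arange(0.5, 20.0, 0.5)
        r = 1500.0 * (1.0 - 2.0 ** (-0.12 * t))
        fit = m.fit_eigen_growth(t, r, law="saturating")
        assert fit.A_um == pytest.approx(1500.0, rel=1e-6)
        assert fit.a_per_h == pytest.approx(0.12, rel=1e-6)

    def test_time_shift_applied(self):
        t = np.arange(2.0, 12.0, 0.5)
        fit = m.fit_eigen_growth(t, 0.1 * (t - 1.0), t0_shift_h=1.0)
        assert fit.B_um_per_h == pytest.approx(0.1, abs=1e-9)
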