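import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from neokurt.io import SchemeError
from neokurt.phantom import (CompartmentParams, TissueRegime,
                             _add_rician_noise, analytic_cumulants,
                             default_regimes, forward_signal, generate_cohort,
                             generate_phantom, make_scheme)

from conftest import random_compartment_params


class TestMakeScheme:
    def test_study_layout_counts(self, scheme18):
        assert len(scheme18) == 55  # 1 + 3 x 18
        np.testing.assert_array_equal(scheme18.shells, [500, 1000, 2000])

    def test_minimal_layout_counts(self):
        assert len(make_scheme(6, (1000.0,))) == 7

    def test_directions_spread_at_least_20_degrees(self, scheme18):
        dirs = scheme18.unique_directions()
        assert dirs.shape[0] == 18
        angles = [
            np.degrees(np.arccos(min(1.0, abs(a @ b))))
            for a, b in itertools.combinations(dirs, 2)
        ]
        assert min(angles) >= 20.0

    def test_deterministic(self):
        s1, s2 = make_scheme(18), make_scheme(18)
        np.testing.assert_array_equal(s1.directions, s2.directions)

    def test_too_few_directions(self):
        with pytest.raises(SchemeError):
            make_scheme(5)


class TestForwardSignal:
    def test_b0_equals_s0_and_positive_decreasing(self, scheme18, worked_params):
        s = forward_signal(worked_params, scheme18)
        assert s[0] == worked_params.S0
        assert np.all(s > 0)
        # along any fixed direction the signal is non-increasing in b
        dirs = scheme18.unique_directions()
        for n in dirs[:5]:
            row = [forward_signal(worked_params, _one_dir_scheme(b, n))[-1]
                   for b in (0.0, 500.0, 1000.0, 2000.0)]
            assert np.all(np.diff(row) <= 0)

    def test_single_compartment_limit_is_monoexponential(self, scheme18):
        p = CompartmentParams(f=0.0, Da_axial=1e-3, De_par=1.9e-3,
                              De_perp=1.0e-3, axis=[1, 0, 0])
        s = forward_signal(p, scheme18)
        _, De_n = _dirdiff(p, scheme18.directions)
        np.testing.assert_allclose(
            s, p.S0 * np.exp(-scheme18.bvalues * De_n), rtol=1e-12)

    def test_worked_substitution(self, worked_params):
        sch = _one_dir_scheme(1000.0, [1, 0, 0])
        s = forward_signal(worked_params, sch)
        expected = 0.5 * np.exp(-1.2) + 0.5 * np.exp(-1.9)
        assert s[-1] / worked_params.S0 == pytest.approx(expected, rel=1e-12)

    def test_low_b_expansion_matches_cumulants(self, worked_params):
        # ln(S/S0) + b D - b^2 D^2 K / 6 must vanish faster than b^2
        p = worked_params
        n = np.array([0.3, 0.5, 0.8])
        n /= np.linalg.norm(n)
        D, K = analytic_cumulants(p, n)
        Da_n, De_n = _dirdiff(p, n[None, :])
        resid = []
        for b in (1.0, 10.0, 100.0):  # below the scanner b=0 threshold on purpose
            s = p.f * np.exp(-b * Da_n[0]) + (1 - p.f) * np.exp(-b * De_n[0])
            r = np.log(s) + b * D - b ** 2 * D ** 2 * K / 6
            resid.append(abs(r) / b ** 2)
        assert resid[0] < resid[1] < resid[2]  # o(b^2): ratio shrinks as b -> 0


class TestAnalyticCumulants:
    def test_worked_axial_and_radial_values(self, worked_params):
        D1, K1 = analytic_cumulants(worked_params, [1, 0, 0])
        assert D1 == pytest.approx(1.55e-3, rel=1e-12)
        assert K1 == pytest.approx(0.15297, abs=5e-6)
        D2, K2 = analytic_cumulants(worked_params, [0, 1, 0])
        assert D2 == pytest.approx(0.5e-3, rel=1e-12)
        assert K2 == pytest.approx(3.0, rel=1e-12)

    def test_gaussian_limit_has_zero_kurtosis(self, scheme18):
        p = CompartmentParams(f=0.0, Da_axial=1e-3, De_par=2e-3,
                              De_perp=1e-3, axis=[0, 0, 1])
        for n in scheme18.unique_directions():
            assert analytic_cumulants(p, n)[1] == 0.0

    @pytest.mark.parametrize("i", range(5))
    def test_matches_numerical_moments_of_the_mixture(self, rng, i):
        """Independent oracle: 2nd/4th moments of the 1-D Gaussian-mixture
        displacement distribution by numerical integration."""
        p = random_compartment_params(np.random.default_rng(100 + i))
        n = np.random.default_rng(200 + i).standard_normal(3)
        n /= np.linalg.norm(n)
        D, K = analytic_cumulants(p, n)
        Da_n, De_n = _dirdiff(p, n[None, :])
        # displacement variance 2*D*t per compartment; t = 1 (K is t-free)
        s2a, s2e = 2 * Da_n[0] + 1e-30, 2 * De_n[0]

        def pdf(x):
            ga = np.exp(-x ** 2 / (2 * s2a)) / np.sqrt(2 * np.pi * s2a)
            ge = np.exp(-x ** 2 / (2 * s2e)) / np.sqrt(2 * np.pi * s2e)
            return p.f * ga + (1 - p.f) * ge

        lim = 8 * np.sqrt(s2e)
        m2 = quad(lambda x: x ** 2 * pdf(x), -lim, lim, limit=200)[0]
        m4 = quad(lambda x: x ** 4 * pdf(x), -lim, lim, limit=200)[0]
        assert m2 / 2 == pytest.approx(D, rel=1e-8)
        assert m4 / m2 ** 2 - 3 == pytest.approx(K, rel=1e-6, abs=1e-9)

    def test_kurtosis_maximal_perpendicular_to_fiber(self, worked_params):
        # with zero intra radial diffusivity K peaks in the plane _|_ axis
        rng = np.random.default_rng(0)
        dirs = rng.standard_normal((100, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        _, K = analytic_cumulants(worked_params, dirs)
        _, K_perp = analytic_cumulants(worked_params, [0, 1, 0])
        assert np.all(K <= K_perp + 1e-12)


class TestGeneratePhantom:
    def test_noise_free_equals_forward_signal(self, scheme18, worked_params):
        dwi, truth = generate_phantom([TissueRegime("x", worked_params)],
                                      (2, 2, 2), scheme18, snr=None, seed=0)
        np.testing.assert_array_equal(dwi.signal[0, 0, 0],
                                      forward_signal(worked_params, scheme18))
        assert truth.f[0, 0, 0] == 0.5

    def test_seed_reproducibility(self, scheme18, worked_params):
        a, _ = generate_phantom([TissueRegime("x", worked_params)], (3, 3, 3),
                                scheme18, snr=20, seed=11)
        b, _ = generate_phantom([TissueRegime("x", worked_params)], (3, 3, 3),
                                scheme18, snr=20, seed=11)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_rician_mean_of_zero_signal(self):
        # E|0 + sigma*(e1 + i e2)| = sigma * sqrt(pi/2)
        rng = np.random.default_rng(5)
        sigma = 3.7
        draws = _add_rician_noise(np.zeros(10_000), sigma, rng)
        assert draws.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2),
                                             rel=0.02)

    def test_nonpositive_snr_rejected(self, scheme18, worked_params):
        with pytest.raises(ValueError):
            generate_phantom([TissueRegime("x", worked_params)], (2, 2, 2),
                             scheme18, snr=-1, seed=0)


class TestRegimes:
    def test_fig1_ordering_holds_in_premyelination_rois(self):
        regs = default_regimes("fullterm")
        for roi in ("SCR", "EC"):
            c = regs["control"][roi].param_mean
            s = regs["simple_T2h"][roi].param_mean
            h = regs["complex_T2h_HIE"][roi].param_mean
            assert s.De_par > c.De_par and s.De_perp > c.De_perp
            assert s.Da_axial == c.Da_axial  # intra-axonal untouched
            assert h.Da_axial < s.Da_axial  # axonal damage
            assert h.De_perp > s.De_perp

    def test_awf_values_physical(self):
        for group, rois in default_regimes("fullterm").items():
            for roi, reg in rois.items():
                assert 0.05 < reg.param_mean.f < 0.5, (group, roi)


class TestGenerateCohort:
    def test_study_group_sizes(self):
        c = generate_cohort({"control": 21, "simple_T2h": 41}, seed=0)
        assert len(c) == 62
        assert (c["group"] == "control").sum() == 21

    def test_covariates_match_demographics_table(self):
        # the GA <= PMA rejection step shifts the marginals by a few tenths
        # of a week relative to the nominal group means
        c = generate_cohort({"control": 400}, seed=1)
        assert c["GA_weeks"].mean() == pytest.approx(39.75, abs=0.5)
        assert c["PMA_weeks"].mean() == pytest.approx(41.08, abs=0.5)
        assert c["BW_grams"].mean() == pytest.approx(3243, rel=0.03)
        assert (c["GA_weeks"] <= c["PMA_weeks"]).all()

    def test_seed_reproducibility(self):
        a = generate_cohort({"control": 10}, seed=9)
        b = generate_cohort({"control": 10}, seed=9)
        assert a.equals(b)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            generate_cohort({"martian": 5}, seed=0)


# helpers ------------------------------------------------------------------

def _one_dir_scheme(b, n):
    from neokurt.io import GradientScheme
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    return GradientScheme([0.0, float(b)] if b > 0 else [0.0, 0.0],
                          np.vstack([[0, 0, 0], n]))


def _dirdiff(p, dirs):
    from neokurt.phantom import _directional_diffusivities
    return _directional_diffusivities(p, dirs)
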