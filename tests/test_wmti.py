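import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neokurt.dki import fit_cwlls
from neokurt.io import DWIVolume
from neokurt.phantom import (analytic_cumulants, default_regimes,
                             generate_phantom)
from neokurt.wmti import (WhiteMatterModel, awf_from_kmax,
                          build_compartment_tensors,
                          compartment_diffusivities, invert_from_directional)

from conftest import cumulant_voxel_volume, random_compartment_params


class TestAWF:
    def test_gaussian_voxel_has_zero_fraction(self):
        f, clipped = awf_from_kmax(0.0)
        assert f == 0.0 and not clipped

    def test_kmax_three_gives_half(self):
        assert awf_from_kmax(3.0)[0] == pytest.approx(0.5)

    def test_round_trips_forward_relation(self):
        # forward: K_max = 3 f / (1 - f); at f = 0.3 that is 9/7
        f, _ = awf_from_kmax(9.0 / 7.0)
        assert f == pytest.approx(0.3, abs=1e-15)
        for f_true in (0.1, 0.25, 0.5, 0.7):
            K = 3 * f_true / (1 - f_true)
            assert awf_from_kmax(K)[0] == pytest.approx(f_true, abs=1e-14)

    def test_negative_input_clipped_and_flagged(self):
        f, clipped = awf_from_kmax(-0.5)
        assert f == 0.0 and clipped

    def test_monotone(self):
        ks = np.linspace(0, 50, 200)
        fs, _ = awf_from_kmax(ks)
        assert np.all(np.diff(fs) > 0) and np.all((fs >= 0) & (fs < 1))


class TestCompartmentSplit:
    def test_zero_kurtosis_means_identical_compartments(self):
        Da, De, flags = compartment_diffusivities(1.1e-3, 0.0, 0.4)
        assert Da == pytest.approx(1.1e-3) and De == pytest.approx(1.1e-3)
        assert not flags

    def test_worked_radial_split(self):
        Da, De, _ = compartment_diffusivities(0.5e-3, 3.0, 0.5)
        assert Da == pytest.approx(0.0, abs=1e-18)
        assert De == pytest.approx(1.0e-3, rel=1e-12)

    def test_worked_axial_split(self):
        D, K = 1.55e-3, 0.15296566077  # analytic axial cumulants at f=0.5
        Da, De, _ = compartment_diffusivities(D, K, 0.5)
        assert Da == pytest.approx(1.20e-3, rel=1e-9)
        assert De == pytest.approx(1.90e-3, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(D=st.floats(0.3e-3, 3e-3), K=st.floats(0.0, 10.0),
           f=st.floats(0.01, 0.99))
    def test_mixture_mean_conserved(self, D, K, f):
        Da, De, flags = compartment_diffusivities(D, K, f)
        if not flags:  # clipping (by design) breaks exact conservation
            assert f * Da + (1 - f) * De == pytest.approx(D, rel=1e-12)
        assert Da <= D <= De

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            compartment_diffusivities(1e-3, 1.0, 0.0)
        with pytest.raises(ValueError):
            compartment_diffusivities(1e-3, 1.0, 1.0)


class TestCompartmentTensors:
    def _direction_set(self, scheme):
        return np.vstack([scheme.unique_directions(), np.eye(3)])

    def test_recovers_generating_tensors(self, scheme18, worked_params):
        p = worked_params
        dirs = self._direction_set(scheme18)
        Dn, Kn = analytic_cumulants(p, dirs)
        Da_n, De_n, _ = compartment_diffusivities(Dn, Kn, p.f)
        Da_t, De_t = build_compartment_tensors(dirs, Da_n, De_n)
        np.testing.assert_allclose(Da_t, p.Da_tensor, atol=1e-11)
        np.testing.assert_allclose(De_t, p.De_tensor, atol=1e-11)
        ev = np.linalg.eigvalsh(De_t)[::-1]
        np.testing.assert_allclose(ev, [p.De_par, p.De_perp, p.De_perp],
                                   rtol=1e-8)

    def test_zero_kurtosis_yields_equal_tensors(self, scheme18):
        dirs = self._direction_set(scheme18)
        D = np.diag([1.5e-3, 1.0e-3, 0.8e-3])
        Dn = np.einsum("ki,ij,kj->k", dirs, D, dirs)
        Da_t, De_t = build_compartment_tensors(dirs, Dn, Dn)
        np.testing.assert_allclose(Da_t, De_t, atol=1e-15)
        np.testing.assert_allclose(Da_t, D, atol=1e-12)

    def test_matches_direct_normal_equations(self, scheme18, rng):
        from neokurt.dki import quadratic_design
        from neokurt.metrics import matrix_to_d6
        dirs = self._direction_set(scheme18)
        vals = rng.uniform(0.5e-3, 2e-3, dirs.shape[0])
        Da_t, _ = build_compartment_tensors(dirs, vals, vals)
        B = quadratic_design(dirs)
        ref = np.linalg.solve(B.T @ B, B.T @ vals)  # independent 6x6 solve
        np.testing.assert_allclose(matrix_to_d6(Da_t), ref, rtol=1e-9)

    def test_rank_deficient_direction_set_rejected(self):
        coplanar = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0], [1, -1, 0],
                             [2, 1, 0], [1, 2, 0]], dtype=float)
        coplanar /= np.linalg.norm(coplanar, axis=1, keepdims=True)
        with pytest.raises(ValueError, match="rank"):
            build_compartment_tensors(coplanar, np.ones(6), np.ones(6))


class TestExactInversion:
    def test_analytic_cumulants_invert_to_machine_precision(self, scheme18):
        """The module's primary correctness surface: exact cumulants in,
        generating parameters out, to 1e-10."""
        rng = np.random.default_rng(2016)
        dirs = np.vstack([scheme18.unique_directions(), np.eye(3)])
        for p in random_compartment_params(rng, n=50):
            Dn, Kn = analytic_cumulants(p, dirs)
            perp = np.cross(p.axis, [0.917, 0.241, -0.312])
            perp /= np.linalg.norm(perp)
            K_max = analytic_cumulants(p, perp)[1]  # radial = maximal
            res = invert_from_directional(dirs, Dn, Kn, K_max)
            assert res["f"] == pytest.approx(p.f, abs=1e-10)
            assert res["D_a"] == pytest.approx(p.Da_axial, rel=1e-10)
            assert res["De_par"] == pytest.approx(p.De_par, rel=1e-10)
            assert res["De_perp"] == pytest.approx(p.De_perp, rel=1e-10)


class TestWhiteMatterModel:
    def test_noise_free_worked_example_recovered(self, scheme18, worked_params):
        fit = fit_cwlls(cumulant_voxel_volume(worked_params, scheme18))
        wm = WhiteMatterModel(fit).fit_maps()
        p = worked_params
        assert wm.f[0, 0, 0] == pytest.approx(p.f, rel=1e-6)
        assert wm.D_a[0, 0, 0] == pytest.approx(p.Da_axial, rel=1e-6)
        assert wm.De_par[0, 0, 0] == pytest.approx(p.De_par, rel=1e-6)
        assert wm.De_perp[0, 0, 0] == pytest.approx(p.De_perp, rel=1e-6)
        np.testing.assert_allclose(
            wm.lambda_e[0, 0, 0], [p.De_par, p.De_perp, p.De_perp], rtol=1e-6)

    def test_pure_gaussian_region_flagged_undefined(self, scheme18):
        b = scheme18.bvalues
        sig = 1000.0 * np.exp(-b * 1.0e-3)  # isotropic Gaussian, K = 0
        fit = fit_cwlls(DWIVolume(sig[None, None, None, :], scheme18))
        wm = WhiteMatterModel(fit).fit_maps()
        assert wm.f[0, 0, 0] == pytest.approx(0.0, abs=1e-6)
        assert not wm.valid[0, 0, 0]
        assert np.isnan(wm.D_a[0, 0, 0])
        assert wm.flags[0, 0, 0] & 1

    def test_snr30_monte_carlo_recovery(self, scheme18):
        """Median AWF recovered within 0.05 on a 500-voxel-per-region
        myelinated-tract (PLIC-like) phantom at SNR 30, and the radial
        kurtosis (the quantity the inversion consumes) within 10% of its
        analytic value.  Cumulant-form signals isolate the noise behaviour
        from the separate finite-b truncation effect; the along-fiber
        kurtosis is *not* asserted — at b = 2000 the axial signal sits at
        the Rician noise floor and is known to be inflated there.
        """
        regs = default_regimes()
        slabs = [regs[g]["PLIC"] for g in regs]
        dwi, truth = generate_phantom(slabs, (10, 10, 15), scheme18,
                                      snr=30, seed=42, signal_model="cumulant")
        fit = fit_cwlls(dwi)
        wm = WhiteMatterModel(fit).fit_maps()
        scal = fit.scalar_maps()
        for i, (lab, _) in enumerate(sorted(truth.atlas.name_map.items())):
            region = truth.atlas.labels == lab
            assert abs(np.nanmedian(wm.f[region]) - truth.f[region].mean()) < 0.05
            p = slabs[i].param_mean
            perp = np.cross(p.axis, [1.0, 0.0, 0.0])
            perp /= np.linalg.norm(perp)
            K_radial_true = analytic_cumulants(p, perp)[1]
            assert np.nanmedian(scal.RK[region]) == pytest.approx(
                K_radial_true, rel=0.10)

    def test_awf_recovery_biexponential_signal(self, scheme18):
        """With the physical (biexponential) signal the finite-b truncation
        adds a small positive f bias; the PLIC regime stays within 0.05."""
        regs = default_regimes()
        slabs = [regs[g]["PLIC"] for g in regs]
        dwi, truth = generate_phantom(slabs, (10, 10, 15), scheme18,
                                      snr=30, seed=42)
        wm = WhiteMatterModel(fit_cwlls(dwi)).fit_maps()
        for lab in truth.atlas.name_map:
            region = truth.atlas.labels == lab
            assert abs(np.nanmedian(wm.f[region]) - truth.f[region].mean()) < 0.05

    def test_regime_separation_noise_free(self, scheme18):
        """Delayed myelination moves only the extra-axonal diffusivities;
        axonal damage lowers the intra-axonal one (premyelination ROIs)."""
        regs = default_regimes()
        for roi in ("SCR", "EC"):
            rec = {}
            for g in ("control", "simple_T2h", "complex_T2h_HIE"):
                dwi, _ = generate_phantom([regs[g][roi]], (3, 3, 3), scheme18,
                                          snr=None, seed=0,
                                          signal_model="cumulant")
                wm = WhiteMatterModel(fit_cwlls(dwi)).fit_maps()
                rec[g] = {k: np.nanmedian(v) for k, v in wm.as_dict().items()}
            assert rec["simple_T2h"]["de_par"] > rec["control"]["de_par"]
            assert rec["simple_T2h"]["de_perp"] > rec["control"]["de_perp"]
            assert abs(rec["simple_T2h"]["da"] - rec["control"]["da"]) < 1e-6
            assert rec["complex_T2h_HIE"]["da"] < rec["simple_T2h"]["da"]
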