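"""OSEM reconstruction and the window-based downscatter correction."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import duospect as ds
from duospect.phantom import with_activities
from duospect.recon import window_scatter_estimate


@pytest.fixture(scope="module")
def small_noiseless(small_setup):
    ph, prot = small_setup["phantom"], small_setup["protocol"]
    return ds.simulate_acquisition(ph, prot, seed=0, noise=False)


class TestScatterEstimate:
    def test_zero_k_gives_zero_estimate(self, small_noiseless):
        s = window_scatter_estimate(small_noiseless, "118", k=0.0)
        assert not s.any()

    def test_unsmoothed_estimate_is_k_times_counts(self, small_noiseless):
        s = window_scatter_estimate(small_noiseless, "118", k=1.15, smoothing_fwhm_mm=0)
        np.testing.assert_allclose(s, 1.15 * small_noiseless.counts["118"], rtol=1e-12)

    def test_smoothing_conserves_total(self, small_noiseless):
        """The smoothing kernel is normalized, so the total estimate stays
        k times the estimation-window total (object support is interior)."""
        s0 = window_scatter_estimate(small_noiseless, "118", k=1.15, smoothing_fwhm_mm=0)
        s1 = window_scatter_estimate(small_noiseless, "118", k=1.15, smoothing_fwhm_mm=20)
        assert s1.sum() == pytest.approx(s0.sum(), rel=1e-6)
        assert (s1 >= 0).all()

    def test_missing_window_raises(self, small_noiseless):
        with pytest.raises(KeyError):
            window_scatter_estimate(small_noiseless, "999", k=1.0)


class TestOsem:
    def test_mlem_count_conservation_on_noiseless_cylinder(self, small_setup):
        """Noiseless data, no attenuation, no scatter, 1 subset: MLEM
        preserves total activity within 0.5% after 10 iterations."""
        prot = small_setup["protocol"]
        shape = (32, 32, 24)
        x_true = np.zeros(shape)
        ii, jj = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        cyl = ((ii - 15.5) ** 2 + (jj - 15.5) ** 2) < 8**2
        x_true[cyl, 6:18] = 3.0
        model = ds.SystemModel(None, prot, psf_fwhm_mm=0.0)
        y = model.forward(x_true)
        cfg = ds.ReconConfig(n_iterations=10, n_subsets=1, k_factor=0.0, psf_fwhm_mm=0.0)
        rec = ds.osem_reconstruct(y, np.zeros_like(y), None, prot, cfg)
        assert rec.values.data.sum() == pytest.approx(x_true.sum(), rel=0.005)

    def test_em_fixed_point_at_true_solution(self, small_setup, small_noiseless):
        """Initialized at the truth with the true downscatter as the additive
        term, one EM update leaves the volume unchanged."""
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        terms = small_noiseless.terms["81"]
        primary = terms[("ho", "primary")]
        true_scatter = sum(t for (iso, kind), t in terms.items() if kind == "downscatter")
        sens = ds.default_crosstalk().primary[("ho", "81")]
        cfg = ds.ReconConfig(n_iterations=1, n_subsets=1, psf_fwhm_mm=10.0)
        rec = ds.osem_reconstruct(
            primary + true_scatter, true_scatter, ph.mu_81, prot, cfg,
            sensitivity_cps_per_bq=sens, init=ph.ho_activity.data,
        )
        delta = np.abs(rec.values.data - ph.ho_activity.data).sum()
        assert delta / ph.ho_activity.data.sum() < 1e-6

    def test_osem_matches_mlem_at_matched_update_count(self, small_setup, small_noiseless):
        """8 subsets x 10 iterations ~ 1 subset x 80 iterations: VOI means
        agree within 2%."""
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        sens = ds.default_crosstalk().primary[("ho", "81")]
        osem = ds.reconstruct_ho(
            small_noiseless, ph.mu_81, prot,
            ds.ReconConfig(n_iterations=10, n_subsets=8), sensitivity_cps_per_bq=sens,
        )
        mlem = ds.reconstruct_ho(
            small_noiseless, ph.mu_81, prot,
            ds.ReconConfig(n_iterations=80, n_subsets=1), sensitivity_cps_per_bq=sens,
        )
        for mask in (ph.healthy_liver_mask, ph.mask("tumor")):
            a = osem.values.data[mask].mean()
            b = mlem.values.data[mask].mean()
            assert a == pytest.approx(b, rel=0.02)

    def test_mlem_loglikelihood_monotone_on_noiseless_data(self, small_setup, small_noiseless):
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        sens = ds.default_crosstalk().primary[("ho", "81")]
        rec = ds.reconstruct_ho(
            small_noiseless, ph.mu_81, prot,
            ds.ReconConfig(n_iterations=6, n_subsets=1), sensitivity_cps_per_bq=sens,
        )
        lls = [e["loglik_subset"] for e in rec.convergence]
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_nonnegativity_on_noisy_data(self, small_setup):
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        proj = ds.simulate_acquisition(ph, prot, seed=11)
        rec = ds.reconstruct_ho(proj, ph.mu_81, prot, ds.ReconConfig(n_iterations=2))
        assert (rec.values.data >= 0).all()

    def test_all_zero_photopeak_warns_and_returns_zero(self, small_setup):
        prot = small_setup["protocol"]
        y = np.zeros((prot.n_angles, *prot.detector_shape))
        with pytest.warns(UserWarning, match="all-zero"):
            rec = ds.osem_reconstruct(
                y, np.zeros_like(y), small_setup["phantom"].mu_81, prot, ds.ReconConfig()
            )
        assert not rec.values.data.any()

    def test_negative_counts_rejected(self, small_setup):
        prot = small_setup["protocol"]
        y = -np.ones((prot.n_angles, *prot.detector_shape))
        with pytest.raises(ValueError, match="negative"):
            ds.osem_reconstruct(
                y, np.zeros_like(y), small_setup["phantom"].mu_81, prot, ds.ReconConfig()
            )


class TestIsotopeReconstructions:
    def test_di_with_zero_tc_equals_ho_only(self, small_setup):
        """Removing the second isotope makes the DI pipeline literally the
        Ho-only pipeline: identical counts, identical reconstruction."""
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        ho_only = with_activities(ph, tc_scale=0)
        p1 = ds.simulate_acquisition(ho_only, prot, seed=2)
        p2 = ds.simulate_acquisition(ho_only, prot, seed=2)
        r1 = ds.reconstruct_ho(p1, ph.mu_81, prot, ds.ReconConfig(n_iterations=3))
        r2 = ds.reconstruct_ho(p2, ph.mu_81, prot, ds.ReconConfig(n_iterations=3))
        np.testing.assert_array_equal(r1.values.data, r2.values.data)

    def test_correction_reduces_crosstalk_bias(self, small_setup):
        """With Tc present, the corrected healthy-liver mean is closer to
        the Ho-only reconstruction's than the uncorrected one."""
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        cfg = ds.ReconConfig(n_iterations=5)
        proj_ho = ds.simulate_acquisition(with_activities(ph, tc_scale=0), prot, seed=4)
        proj_di = ds.simulate_acquisition(ph, prot, seed=4)
        ref = ds.reconstruct_ho(proj_ho, ph.mu_81, prot, cfg)
        corr = ds.reconstruct_ho(proj_di, ph.mu_81, prot, cfg)
        unc = ds.reconstruct_ho(proj_di, ph.mu_81, prot, replace(cfg, k_factor=0.0))
        mask = ph.healthy_liver_mask
        # compare shape-normalized means (clinical rescaling removes totals)
        rel = lambda r: r.values.data[mask].mean() / r.values.data.sum()  # noqa: E731
        assert abs(rel(corr) - rel(ref)) < abs(rel(unc) - rel(ref))

    def test_tc_recon_unaffected_by_correction_without_ho(self, small_setup):
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        tc_only = with_activities(ph, ho_scale=0)
        proj = ds.simulate_acquisition(tc_only, prot, seed=6)
        cfg = ds.ReconConfig(n_iterations=3)
        on = ds.reconstruct_tc(proj, ph.mu_140, prot, cfg)
        off = ds.reconstruct_tc(proj, ph.mu_140, prot, replace(cfg, k_factor=0.0))
        np.testing.assert_allclose(on.values.data, off.values.data, rtol=1e-12)

    def test_tc_total_recovery(self, standard_noiseless):
        """Calibrated Tc reconstruction recovers the simulated 50 MBq."""
        total = standard_noiseless["recon_tc"].values.integrate() / 1e6
        assert total == pytest.approx(50.0, rel=0.15)

    def test_tc_support_lies_in_healthy_liver(self, standard_noiseless):
        ph = standard_noiseless["phantom"]
        vol = standard_noiseless["recon_tc"].values
        m = vol.data > 0.05 * vol.data.max()
        frac = vol.data[m & ph.healthy_liver_mask].sum() / vol.data[m].sum()
        assert frac >= 0.90


class TestPostfilter:
    def test_sigma_zero_is_identity(self, standard_noiseless):
        rec = standard_noiseless["recon_ho"]
        out = ds.gaussian_postfilter(rec, 0.0)
        np.testing.assert_array_equal(out.values.data, rec.values.data)

    def test_total_conserved(self, standard_noiseless):
        rec = standard_noiseless["recon_ho"]
        out = ds.gaussian_postfilter(rec, 4.2)
        assert out.values.data.sum() == pytest.approx(rec.values.data.sum(), rel=1e-6)

    def test_delta_spreads_with_requested_sigma(self):
        vol = ds.VoxelVolume(np.zeros((33, 33, 33)), (4.8, 4.8, 4.8))
        vol.data[16, 16, 16] = 1.0
        rec = ds.ReconVolume(vol, ds.ReconConfig())
        out = ds.gaussian_postfilter(rec, 4.2).values.data
        x = (np.arange(33) - 16) * 4.8
        var = (out.sum(axis=(1, 2)) * x**2).sum() / out.sum()
        assert np.sqrt(var) == pytest.approx(4.2, rel=0.02)
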