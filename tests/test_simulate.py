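"""Forward model and four-window acquisition simulator."""

import numpy as np
import pytest

import duospect as ds
from duospect.phantom import with_activities
from duospect.simulate import expected_window_terms


def brute_force_point_projection(value, scale):
    """Independent oracle: a point source at the rotation center with no
    attenuation and no PSF projects its full intensity into every angle."""
    return value * scale


class TestProjector:
    def test_adjointness(self, small_setup):
        """<P x, y> == <x, P^T y> to float precision (OSEM depends on it)."""
        model = ds.SystemModel(small_setup["phantom"].mu_81, small_setup["protocol"], 10.0)
        rng = np.random.default_rng(42)
        x = rng.random(model.shape)
        y = rng.random((5, *small_setup["protocol"].detector_shape))
        idx = [0, 7, 19, 33, 50]
        lhs = float((model.forward(x, idx) * y).sum())
        rhs = float((x * model.adjoint(y, idx)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_zero_activity_projects_to_zero(self, small_setup):
        model = ds.SystemModel(small_setup["phantom"].mu_81, small_setup["protocol"], 10.0)
        p = model.forward(np.zeros(model.shape))
        assert not p.any()

    def test_point_source_rotation_invariance_vs_oracle(self, tiny_setup):
        """mu = 0, psf = 0: each angle's projection sums to the same total,
        matching the closed-form point-source oracle."""
        protocol = tiny_setup["protocol"]
        model = ds.SystemModel(None, protocol, psf_fwhm_mm=0.0, sensitivity_cps_per_bq=1.0)
        x = np.zeros(model.shape)
        cx, cy, cz = [(n - 1) // 2 for n in model.shape]
        x[cx, cy, cz] = 7.5
        p = model.forward(x)
        totals = p.sum(axis=(1, 2))
        expected = brute_force_point_projection(7.5, model.count_scale)
        np.testing.assert_allclose(totals, expected, rtol=1e-6)

    def test_linearity_in_projection_time(self, tiny_setup):
        ph, prot = tiny_setup["phantom"], tiny_setup["protocol"]
        from dataclasses import replace

        prot2 = replace(prot, time_per_projection_s=2 * prot.time_per_projection_s)
        a = ds.SystemModel(ph.mu_81, prot, 10.0).forward(ph.ho_activity.data)
        b = ds.SystemModel(ph.mu_81, prot2, 10.0).forward(ph.ho_activity.data)
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_grid_mismatch_rejected(self, small_setup, tiny_setup):
        model = ds.SystemModel(small_setup["phantom"].mu_81, small_setup["protocol"], 10.0)
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros(tiny_setup["phantom"].mu_81.shape))


class TestAcquisition:
    def test_superposition_of_isotopes(self, small_setup):
        """Expected counts are separately linear in each isotope's activity."""
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        both = ds.simulate_acquisition(ph, prot, seed=0, noise=False)
        ho = ds.simulate_acquisition(with_activities(ph, tc_scale=0), prot, seed=0, noise=False)
        tc = ds.simulate_acquisition(with_activities(ph, ho_scale=0), prot, seed=0, noise=False)
        for w in both.counts:
            np.testing.assert_allclose(
                both.counts[w], ho.counts[w] + tc.counts[w], rtol=1e-9, atol=1e-9
            )

    def test_terms_sum_to_total_expectation(self, small_setup):
        proj = ds.simulate_acquisition(
            small_setup["phantom"], small_setup["protocol"], seed=0, noise=False
        )
        for w in proj.counts:
            np.testing.assert_array_equal(proj.counts[w], proj.expected(w))

    def test_window_layout_without_tc(self, small_setup):
        """With no 99mTc the 140 keV window holds only Ho downscatter and the
        81 keV window is identical to the Ho-only acquisition for that seed."""
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        ho_only = with_activities(ph, tc_scale=0)
        proj = ds.simulate_acquisition(ho_only, prot, seed=3)
        assert set(proj.terms["140"]) == {("ho", "downscatter")}
        proj_full_tc0 = ds.simulate_acquisition(ho_only, prot, seed=3)
        np.testing.assert_array_equal(proj.counts["81"], proj_full_tc0.counts["81"])

    def test_no_ho_means_empty_170_window(self, small_setup):
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        proj = ds.simulate_acquisition(with_activities(ph, ho_scale=0), prot, seed=0, noise=False)
        assert not proj.counts["170"].any()

    def test_counts_are_nonnegative_integers(self, small_setup):
        proj = ds.simulate_acquisition(small_setup["phantom"], small_setup["protocol"], seed=5)
        for c in proj.counts.values():
            assert np.issubdtype(c.dtype, np.integer)
            assert (c >= 0).all()

    def test_poisson_stage_mean_converges_to_expectation(self, tiny_setup):
        """Per-window total counts over replicates average to the expected
        totals within sampling error."""
        ph, prot = tiny_setup["phantom"], tiny_setup["protocol"]
        expected = ds.simulate_acquisition(ph, prot, seed=0, noise=False)
        n_rep = 40
        sums = {w: [] for w in expected.counts}
        for s in range(n_rep):
            proj = ds.simulate_acquisition(ph, prot, seed=1000 + s)
            for w in sums:
                sums[w].append(proj.counts[w].sum())
        for w, lam in ((w, c.sum()) for w, c in expected.counts.items()):
            mean = np.mean(sums[w])
            tol = 4 * np.sqrt(lam / n_rep)  # 4 sigma of the replicate mean
            assert abs(mean - lam) < tol, f"window {w}: {mean} vs {lam}"


class TestKFactor:
    def test_default_crosstalk_realizes_combined_k(self, small_setup):
        """Total downscatter inside the 81 keV window over total 118 keV
        counts equals the clinical combined factor 1.15."""
        ph, prot = small_setup["phantom"], small_setup["protocol"]
        terms = expected_window_terms(ph, prot)
        ds81 = sum(t.sum() for (iso, kind), t in terms["81"].items() if kind == "downscatter")
        est = sum(t.sum() for t in terms["118"].values())
        assert ds81 / est == pytest.approx(1.15, abs=1e-3)

    def test_calibrated_k_matches_target(self, small_setup):
        k = ds.calibrate_k_factor(small_setup["phantom"], small_setup["protocol"])
        assert k == pytest.approx(1.15, abs=0.01)

    def test_k_scale_invariance(self, small_setup):
        """Doubling every downscatter sensitivity leaves k unchanged."""
        xt = ds.default_crosstalk().scaled_downscatter(2.0)
        k = ds.calibrate_k_factor(small_setup["phantom"], small_setup["protocol"], xt)
        assert k == pytest.approx(1.15, abs=0.01)

    def test_symmetric_sensitivities_give_unit_k(self, small_setup):
        xt = ds.default_crosstalk()
        for iso in ("ho", "tc"):
            xt.downscatter[(iso, "81")] = xt.downscatter[(iso, "118")]
        k = ds.calibrate_k_factor(small_setup["phantom"], small_setup["protocol"], xt)
        assert k == pytest.approx(1.0, abs=1e-9)

    def test_zero_estimation_window_raises(self, small_setup):
        ph = with_activities(small_setup["phantom"], ho_scale=0, tc_scale=0)
        with pytest.raises(ValueError, match="estimation window"):
            ds.calibrate_k_factor(ph, small_setup["protocol"])


class TestCrosstalkValidation:
    def test_ho_primary_outside_81_rejected(self):
        xt = ds.default_crosstalk()
        xt.primary[("ho", "140")] = 1e-5
        with pytest.raises(ValueError, match="photopeak"):
            xt.validate()

    def test_negative_sensitivity_rejected(self):
        xt = ds.default_crosstalk()
        xt.downscatter[("tc", "81")] = -1.0
        with pytest.raises(ValueError):
            xt.validate()

    def test_projection_set_roundtrip(self, tiny_setup, tmp_path):
        proj = ds.simulate_acquisition(tiny_setup["phantom"], tiny_setup["protocol"], seed=0)
        proj.save(str(tmp_path / "acq"))
        back = ds.VoxelVolume.from_nifti(str(tmp_path / "acq_win81.nii.gz"))
        np.testing.assert_array_equal(np.moveaxis(back.data, -1, 0), proj.counts["81"])
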