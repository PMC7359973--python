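"""Reconstruct both isotopes with OSEM and report VOI absorbed doses.

Shows the effect of the window-based downscatter correction on the
healthy-liver dose: the corrected dual-isotope reconstruction tracks the
ground truth, the uncorrected one overestimates healthy-liver activity
(the Tc-colloid counts leak into the 81 keV window there).
"""

from dataclasses import replace

import duospect as ds

phantom = ds.build_phantom(ds.PhantomSpec())
protocol = ds.AcquisitionProtocol()
proj = ds.simulate_acquisition(phantom, protocol, seed=1)

cfg = ds.ReconConfig()  # 10 iterations x 8 subsets, k = 1.15
recon = ds.reconstruct_ho(proj, phantom.mu_81, protocol, cfg)
recon_unc = ds.reconstruct_ho(proj, phantom.mu_81, protocol, replace(cfg, k_factor=0.0))

administered = 5757.0  # MBq therapy activity
truth = ds.true_dose_map(phantom, administered)
voi = ds.place_healthy_voi(phantom.healthy_liver_mask, phantom.mask("tumor"), phantom.labels)
print(f"healthy-liver VOI: {voi.volume_ml:.1f} ml")

for name, rec in (("corrected", recon), ("uncorrected", recon_unc)):
    act = ds.rescale_to_administered(rec.values, administered)
    dose = ds.dose_map(act, phantom.density)
    d = ds.mean_voi_dose(dose, voi)
    t = ds.mean_voi_dose(truth, voi)
    print(f"{name:>12}: {d:6.1f} Gy (truth {t:6.1f} Gy, {100 * (d - t) / t:+.1f}%)")
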