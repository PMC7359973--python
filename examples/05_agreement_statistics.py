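"""The agreement battery on paired dose measurements and paired ratings.

Bland–Altman limits of agreement (mean difference +- 1.96 x SD), Pearson
correlation and a two-sided paired t test for dose pairs; Cohen's kappa
for two raters' preference calls.
"""

import numpy as np

import duospect as ds
from duospect.stats import PairedSample

rng = np.random.default_rng(0)
ho_only = rng.normal(27.0, 7.0, 20)  # healthy-liver doses, Gy
di = ho_only + rng.normal(-2.0, 2.8, 20)  # DI runs slightly low

s = PairedSample(ho_only, di)
ba = ds.bland_altman(s)
t, p = ds.paired_t_test(s)
print(f"mean difference : {ba.mean_diff:+.2f} Gy")
print(f"CRP (1.96 x SD) : {ba.crp:.2f} Gy")
print(f"LoA             : [{ba.loa_lower:+.2f}, {ba.loa_upper:+.2f}] Gy")
print(f"Pearson r       : {ds.pearson_r(s):.3f}")
print(f"paired t test   : t = {t:.2f}, p = {p:.2e}")

# two physicians expressing a preference per case ('ho', 'di'): near-chance
# agreement means neither reconstruction is systematically preferred
a = rng.choice(["ho", "di"], 65)
b = rng.choice(["ho", "di"], 65)
res = ds.cohens_kappa(a, b)
print(f"\nCohen's kappa   : {res.kappa:+.3f} "
      f"(observed {res.observed_agreement:.2f}, chance {res.expected_agreement:.2f})")
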