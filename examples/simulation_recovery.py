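"""Check Ka recovery on synthetic dilution data at the study's own scale.

Generates noisy dilution tables from the isodesmic forward model (study
concentration grid, 3 Hz shift noise, per-proton limiting shifts at the
study scale), refits each proton, and summarizes the relative error of the
recovered stacking constant.  A small version of the 200-replicate study
the test suite runs.
"""

import numpy as np

from nmrbind import SyntheticSpec, fit_isodesmic, generate_dilution_series

rng = np.random.default_rng(12345)
errors = []
for rep in range(25):
    truth = float(rng.uniform(2.0, 10.0))
    spec = SyntheticSpec(seed=rep, truth_ka=truth, shift_noise_sd=3.0)
    for series in generate_dilution_series(spec):
        fit = fit_isodesmic(series, offset_free=True)
        errors.append(abs(fit.ka - truth) / truth)

print(f"{len(errors)} per-proton fits over 25 replicate experiments")
print(f"median relative Ka error: {np.median(errors):.1%}")
print(f"80th percentile:          {np.quantile(errors, 0.8):.1%}")
print("Weakly responding protons (|ddmax| below ~100 Hz) dominate the upper "
      "tail: 3 Hz noise on a few-tens-of-Hz curve leaves Ka poorly "
      "determined, which is why deviant protons are averaged with care.")
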