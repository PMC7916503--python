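"""Calibrate the nonlinear estimators on reference stochastic processes.

The estimators have known values on canonical signals: a Brownian random
walk has generalized Hurst exponent H = 0.5 and Higuchi fractal dimension
1.5; i.i.d. noise has HFD ~ 2 and permutation entropy ln(4!) = ln 24; a
ramp has HFD ~ 1 and zero permutation entropy.  On fractional Brownian
motion the two scaling estimators satisfy HFD ~ 2 - H.
"""

import numpy as np

import drowseeg as dg

rng = np.random.default_rng(1)

h_brownian = np.mean(
    [dg.generalized_hurst(dg.brownian_series(15_360, np.random.default_rng(s)))
     for s in np.random.SeedSequence(1).spawn(200)]
)
print(f"mean H of 200 Brownian walks (target 0.5):  {h_brownian:.4f}")

hfd_ramp = dg.higuchi_fd(np.arange(4096.0))
hfd_noise = np.mean([dg.higuchi_fd(np.random.default_rng(s).standard_normal(4096))
                     for s in range(50)])
print(f"HFD of a ramp (target 1.0):                 {hfd_ramp:.4f}")
print(f"mean HFD of white noise (target 2.0):       {hfd_noise:.4f}")

pe = dg.permutation_entropy(rng.standard_normal(50_000))
print(f"PmEn of i.i.d. noise (target ln 24 = {np.log(24):.4f}): {pe:.4f}")

print("\nHFD vs 2 - H on fractional Brownian motion:")
for hurst in (0.3, 0.5, 0.7):
    hfd = np.mean([dg.higuchi_fd(dg.fractional_brownian_motion(4096, hurst, rng))
                   for _ in range(20)])
    print(f"  H = {hurst}: HFD = {hfd:.3f} (2 - H = {2 - hurst:.1f})")
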