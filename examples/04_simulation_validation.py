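"""Estimator validation on synthetic two-sample summary data.

Generates summary statistics with a known causal effect and directional
pleiotropy on 40% of SNPs, then shows how IVW is biased while MR-Egger and
the weighted median recover the truth; also demonstrates multivariable IVW
on a two-exposure design.
"""

import numpy as np

import cecmr

theta = -0.5
cfg = cecmr.SimulationConfig(
    m_snps=50, theta=theta, n_exposure=10**6,
    n_outcome_cases=10**6, n_outcome_controls=10**6,
    pleiotropy_mode="directional", pleiotropy_mean=0.05, pleiotropy_sd=0.01,
    prop_invalid=0.4, seed=42,
)
study = cecmr.simulate_two_sample_summary(cfg)
inst = study.harmonized()

print(f"True causal effect theta = {theta} "
      f"(log-odds per SD of exposure); 40% of the 50 SNPs carry a direct")
print("outcome effect of +0.05 (directional pleiotropy).\n")
print(f"IVW             {cecmr.ivw(inst).theta:+.3f}   <- biased upward")
print(f"MR-Egger slope  {cecmr.mr_egger(inst).slope.theta:+.3f}   "
      "<- pleiotropy-corrected")
print(f"Egger intercept {cecmr.mr_egger(inst).intercept.value:+.3f}   "
      "<- estimates the mean direct effect (~ 0.4 x 0.05 = 0.020)")
print(f"Weighted median {cecmr.weighted_median(inst, seed=0).theta:+.3f}   "
      "<- majority of weight is valid\n")

# Multivariable IVW: two exposures with known joint effects.
rng = np.random.default_rng(7)
k = 30
X = np.abs(rng.normal(0, 0.2, size=(k, 2)))
truth = np.array([0.5, -0.2])
sey = np.full(k, 0.01)
y = X @ truth + rng.normal(0, sey)
for est in cecmr.multivariable_ivw(X, y, sey, ["exposure_A", "exposure_B"]):
    print(f"multivariable IVW slope for {est.exposure}: {est.theta:+.3f} "
          f"(truth {truth[0] if est.exposure == 'exposure_A' else truth[1]:+.1f})")
print("\nJoint regression on both exposure effect columns separates each")
print("exposure's direct contribution to the outcome.")
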