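# Heritable-continuum clone preset calibrated to the OV90 single-clone
# fluctuation experiment: latent suspension growth rate per clone
# ~ Normal(-0.004, 0.012^2) per hour (cohort mean -0.004/hr, CV 300%),
# memoryless across passages (rho = 0, no inter-passage correlation),
# measurement noise CV 0.05 so total interclonal survival CV ~ 0.28-0.30.
kind: continuum
version: 1
description: OV90-like single-clone cohort, 24 h suspension survival
mu_g: -0.004
sigma_g: 0.012
rho: 0.0
meas_cv: 0.05
T: 24.0
N0: 250000
n_clones: 60
passages: [P1, P3, P6]
link: exp_growth
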