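# Parental (uncloned) population replicate preset: mean 24 h suspension
# survival 0.9 with replicate-to-replicate measurement CV 0.11 — the
# technical/biological baseline against which interclonal fluctuation
# is judged (n = 11 biological repeats in the study design).
kind: parental
version: 1
description: OV90 parental population replicate measurements
mean_survival: 0.9
noise_cv: 0.11
n_replicates: 11
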