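# Full configuration schema for shockbias (all values shown are the
# shipped defaults; marginal parameters are PLACEHOLDERS — replace them
# with estimated values when available and drop the placeholder flag).
schema_version: 1
seed: 1
n: 16305
truncation: clip          # clip | quantile
exact_half_split: false   # exact-half permutation split for GCS=15
welch: false              # Welch instead of pooled-variance t-test
correlation:
  base: 0.55              # equal-scenario magnitude, all pairs
  strong: 0.8             # unequal: hr/sbp/gcs block with transfusion
  weak: 0.3               # unequal: bd with transfusion
marginals:
  hr:
    family: truncated-normal
    location: 100.0
    scale: 28.0
    lower_bound: 30.0
    upper_bound: 220.0
    round_to_integer: false
    placeholder: true
  sbp:
    family: truncated-normal
    location: 120.0
    scale: 29.0
    lower_bound: 40.0
    upper_bound: 250.0
    round_to_integer: false
    placeholder: true
  gcs:
    family: discrete-trimodal
    lower_bound: 3
    upper_bound: 15
    round_to_integer: true
    # [weight, mode, spread]; modes must be exactly 3, 7, 15
    mixture:
      - [0.25, 3, 1.0]
      - [0.32, 7, 1.8]
      - [0.43, 15, 1.7]
    placeholder: true
  bd:
    family: truncated-normal
    location: 3.5
    scale: 4.0
    lower_bound: -10.0
    upper_bound: 30.0
    round_to_integer: false
    placeholder: true
  transfusion:
    family: truncated-normal
    location: 2.2
    scale: 4.2
    lower_bound: 0.0
    upper_bound: 60.0
    round_to_integer: false
    placeholder: true
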