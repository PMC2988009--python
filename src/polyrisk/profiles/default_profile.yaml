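# Default class profile for the synthetic ovarian-tumor generator.
#
# Per-class targets are descriptive statistics of the training cohort of a
# four-class ovarian tumor study (benign / borderline / primary invasive /
# metastatic invasive): medians for continuous variables (mm or years),
# means for the ordinal papillation count, and percentages for binaries.
# Dispersions and the structural-zero mass are generator choices, not
# observed quantities (see docs/methods.md).

prevalences:
  benign: 0.75
  borderline: 0.05
  primary_invasive: 0.16
  metastatic: 0.04

defaults:
  log_sd: 0.5        # log-scale SD of the log-normal continuous family
  ordinal_max: 4     # truncation point of the papillation count

variables:
  age:
    kind: continuous
    params:
      benign: {median: 42}
      borderline: {median: 52.5}
      primary_invasive: {median: 58}
      metastatic: {median: 59}
  lesion_diameter:
    kind: continuous
    params:
      benign: {median: 63}
      borderline: {median: 108}
      primary_invasive: {median: 98}
      metastatic: {median: 73}
  solid_diameter:
    kind: continuous
    params:
      benign: {median: 0, zero_mass: 0.55, nonzero_median: 15}
      borderline: {median: 22}
      primary_invasive: {median: 51}
      metastatic: {median: 54}
  papillation_count:
    kind: ordinal
    params:
      benign: {mean: 0.35}
      borderline: {mean: 1.70}
      primary_invasive: {mean: 1.43}
      metastatic: {mean: 0.93}
  ascites:
    kind: binary
    params:
      benign: {prop: 0.032}
      borderline: {prop: 0.125}
      primary_invasive: {prop: 0.504}
      metastatic: {prop: 0.400}
  solid_tumor:
    kind: binary
    params:
      benign: {prop: 0.066}
      borderline: {prop: 0.075}
      primary_invasive: {prop: 0.322}
      metastatic: {prop: 0.567}
  irregular_walls:
    kind: binary
    params:
      benign: {prop: 0.336}
      borderline: {prop: 0.675}
      primary_invasive: {prop: 0.884}
      metastatic: {prop: 0.833}
  personal_history:
    kind: binary
    params:
      benign: {prop: 0.009}
      borderline: {prop: 0.050}
      primary_invasive: {prop: 0.008}
      metastatic: {prop: 0.100}
  bilateral:
    kind: binary
    params:
      benign: {prop: 0.176}
      borderline: {prop: 0.125}
      primary_invasive: {prop: 0.413}
      metastatic: {prop: 0.333}
  papillary_flow:
    kind: binary
    params:
      benign: {prop: 0.068}
      borderline: {prop: 0.475}
      primary_invasive: {prop: 0.430}
      metastatic: {prop: 0.233}
  acoustic_shadows:
    kind: binary
    params:
      benign: {prop: 0.130}
      borderline: {prop: 0.025}
      primary_invasive: {prop: 0.000}
      metastatic: {prop: 0.033}
  unilocular:
    kind: binary
    params:
      benign: {prop: 0.403}
      borderline: {prop: 0.025}
      primary_invasive: {prop: 0.000}
      metastatic: {prop: 0.000}
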