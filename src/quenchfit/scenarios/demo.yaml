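# Demo plate: lindane-exposed pure and mixed populations of glycine-receptor
# phenotypes.  Homomeric alpha2 receptors are blocked by the drug (EC50
# shifted to ~190 uM) while alpha2-beta heteromers are not (~32 uM), so the
# two phenotypes separate cleanly in (EC50, slope) space.  Wells A1/A2 are
# pure populations used for training the phenotype tree; A3 is a 1:1 mixture
# to be classified.
name: lindane-demo
mode: traces
ladder: [0, 0.1, 0.3, 1, 3, 10, 30, 100, 300, 1000, 3000]
cv_folds: 10

populations:
  alpha2_lindane:
    ec50_median: 190.0
    ec50_log_sd: 0.15
    slope_range: [1.8, 4.0]
    dF_range: [30, 70]
    fraction_responders: 0.85
  alpha2beta_lindane:
    ec50_median: 32.0
    ec50_log_sd: 0.15
    slope_range: [0.8, 2.0]
    dF_range: [30, 70]
    fraction_responders: 0.85

wells:
  - well_id: A1
    role: train
    n_cells: 160
    debris_count: 40
    detach_probability: 0.05
    noise_sd_frac: 0.02
    mix: {alpha2_lindane: 1.0}
  - well_id: A2
    role: train
    n_cells: 160
    debris_count: 40
    detach_probability: 0.05
    noise_sd_frac: 0.02
    mix: {alpha2beta_lindane: 1.0}
  - well_id: A3
    role: classify
    n_cells: 200
    debris_count: 40
    detach_probability: 0.05
    noise_sd_frac: 0.02
    mix: {alpha2_lindane: 0.5, alpha2beta_lindane: 0.5}
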