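# End-to-end characterization of a synthetic 12-dose experiment.
mode: characterize
seed: 11

channels:
  volume_x: FSC-W
  volume_y: SSC-H
  reporter: FL1
  dna: DNA

population:
  n_events: 5000
  vol_meanlog: 3.6888794541139363   # ln(40 fL)
  vol_sdlog: 0.25
  scatter_gain_x: 25.0
  scatter_gain_y: 12.0
  scatter_noise_sd: 0.05
  auto_meanlog: 4.382026634673881   # ln(80 a.u.)
  auto_sdlog: 0.25
  expr_alpha: 1.0                   # expression proportional to volume
  expr_extrinsic_sd: 0.2
  viv_sd: 0.2
  dose_model:                       # ground-truth medians vs aTc dose
    b: -2.0
    c: 100.0
    d: 10000.0
    e: -0.1
    p1: 1.0
    p2: 2.0

doses: [0.0, 0.1, 0.4, 1.0, 2.5, 6.0, 16.0, 40.0, 100.0, 250.0, 600.0, 1500.0]

# bootstrap settings (percentile CIs)
n_boot: 1000
level: 0.95
viv_n_boot: 200     # robust fits are costlier; fewer resamples for VIV CIs

# dose-response fit settings (fixed powers + dynamic-range slope threshold)
p1: 1.0
p2: 2.0
epsilon_frac: 0.01
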