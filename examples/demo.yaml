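# Canonical demo configuration for `fluctlight run --config examples/demo.yaml`.
# Every key has a documented default (see fluctlight.io.RunConfig); this file
# overrides only what the demo needs.
seed: 42
outdir: results/demo
ll2_duration: 1800        # s; LL2 is prolonged until NPQ is steady

quenching:                # PAM simulator ground truth
  A_qE: 1.2
  A_qZ: 0.8
  qI: 0.1                 # persistent quenching added per HL exposure
  noise_sd: 0.01

ecs:
  gH_plus: 20.0           # s-1
  pmf: 1.0                # a.u.
  f_dpH: 0.6
  noise_sd: 0.01

drought:
  onsets: [8, 13, 18]     # transpiration / NPQ / photodamage onset days
  n_days: 24
  n_reps: 4

gasex: {}                 # defaults: slopes WW 0.10, DS 0.05

alpha: 0.05
persistence: 2            # consecutive significant days required for an onset
abs_frac: 0.86            # fixed leaf absorptivity
lef_max: 85.0             # umol e- m-2 s-1, inclusive comparison bound
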