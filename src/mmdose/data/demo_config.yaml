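# Demo configuration: covariate-linear piperacillin model with the
# published assay-error polynomial and median population parameters.
model_kind: linear_covariate
seed: 7
tol: 1.0e-4
error:
  c0: 1.04
  c1: 0.14
  c2: 0.0
  c3: 0.0
  gamma: 1.0
params:        # population medians (simulate subcommand)
  cl_i: 2.79
  cl_s: 0.10
  v_i: 1.83
  v_s: 0.06
  kcp: 0.85
  kpc: 1.65
bounds:        # fit-pop search bounds, [lo, hi] per parameter
  cl_i: [0.04, 38.3]
  cl_s: [0.0011, 1.1]
  v_i: [0.045, 45.4]
  v_s: [0.0012, 1.2]
  kcp: [0.067, 67.4]
  kpc: [0.091, 91.4]
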