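# Full pipeline demo: synthesise a reduced multi-school study, fit every
# school, pool, and emit selection tables.
#
#   netcoevolve run --config examples/config.yaml --seed 1 --out runs/demo
#
# The full 22-school x 5-wave design (the SynthConfig defaults) takes a
# few hours of single-core estimation; this reduced layout finishes in
# minutes.  Drop the `synth` block and add a `data` block
# (root + metadata CSV) to analyse panels from disk instead.

stages: [synth, estimate, gof, meta, tables]

synth:
  n_coed: 4
  n_girls: 3
  n_boys: 2
  size_range: [40, 60]
  waves: 3
  absence_prob: 0.10

model:
  # fix the weakly identified interactions at zero for small schools
  exclude: [con_ego_x_alc_sim, alc_con_x_totsim, alc_sec_x_totsim]

estimation:
  n1: 10
  newton_iters: 10
  refresh_every: 2
  n_dev: 20
  final_iters: 40
  n_avg: 3
  n3: 800
  max_restarts: 1

meta:
  require_converged: false      # reduced-scale fits; see docs/methods.md

gof:
  replicates: 200

tables:
  behaviors: [alcohol, control, secrecy]
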