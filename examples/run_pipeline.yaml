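# End-to-end pipeline configuration for `classed run --config run_pipeline.yaml`.
# Generate the inputs first:
#   classed fixtures --topology crosstalk_demo --seed 1 --out demo/

model: demo/model          # directory with species.csv + reactions.csv (or .xlsx)
data: demo/records.csv     # experiment table, one record per row
outdir: demo/run           # stage artifacts + manifest.json land here
seed: 7                    # fans out to deterministic per-stage seeds
# context: S1              # optional: restrict scoring to one agonist context

stages:                    # any subset, executed in order
  - estimate
  - validate
  - deletion
  - morris
  - sobol
  - calibrate_ec50
  - crosstalk

simulation:                # solver + steady-state settings (all optional)
  tol_ss: 1.0e-5
  rtol: 1.0e-5

estimate:
  n_starts: 8              # multi-start scatter size (production: 100)
  maxiter: 50              # objective evaluations per pattern search

morris:
  levels: 8
  trajectories: 4          # production: 16
  oversample: 50           # production: 300
  threshold: 1.0e-6        # mu* cut selecting the Sobol/calibration subset

sobol:
  n: 64                    # base sample size (production: up to 1e5)
  bootstrap: 200           # CI replicates (production: 1e5)
  pairs: false
  max_factors: 3

calibrate_ec50:
  n_starts: 4
  n_reactions: 2           # top-ranked reactions whose EC50 is calibrated

crosstalk:
  gate: and                # or | and | both
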