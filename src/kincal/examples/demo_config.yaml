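# Demonstration calibration protocol for the reduced Smad7/Ski models.
# Values reflect the published demo settings: estimation bounds 1e-7..1e4,
# genetic algorithm population 300 x 500 generations, 300 repeat runs,
# chaser refinement of the best 3 sets (Hooke & Jeeves, tol 1e-10,
# 1000 iterations), profiles over +/-3 orders of magnitude (Hooke &
# Jeeves, tol 1e-6, 50 iterations) at the 95% confidence level, and
# top-10% truncation for exploratory plots.
models:
  - smad_variant_1.mdl
  - smad_variant_2.mdl
  - smad_variant_3.mdl
data: smad_experiment.csv
observation_map:
  Smad7:
    species: Smad7
    scale_factor: 100
  Ski:
    species: Ski
    scale_factor: 100
free_parameters:
  - {name: Smad7Transcription_V, lower: 1.0e-7, upper: 1.0e4}
  - {name: Smad7Transcription_km, lower: 1.0e-7, upper: 1.0e4}
  - {name: Smad7Transcription_I50, lower: 1.0e-7, upper: 1.0e4}
  - {name: Smad7Deg_k, lower: 1.0e-7, upper: 1.0e4}
  - {name: SkiTranscription_k, lower: 1.0e-7, upper: 1.0e4}
  - {name: SkiDeg_k, lower: 1.0e-7, upper: 1.0e4}
  - {name: Feedback_k, lower: 1.0e-7, upper: 1.0e4}
weighting: sd
estimation:
  algorithm: genetic
  population_size: 300
  generations: 500
  n_runs: 300
chaser:
  top_k: 3
  tolerance: 1.0e-10
  iteration_limit: 1000
profile:
  tolerance: 1.0e-6
  iteration_limit: 50
  span_orders: 3
  n_points: 20
  alpha: 0.95
selection:
  criteria: [aicc, bic]
truncation:
  mode: fraction
  value: 0.1
generate:
  times: [0, 1, 2, 4, 8, 12]
  replicates: 6
  noise: gaussian_cv
  cv: 0.1
  protein_lag_h: 0.5
  protein_magnitude: 100
output_dir: kincal_runs
seed: 1
max_workers: 1
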