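# Desk-scale demonstration cohort: full analysis chain on synthetic data.
out_dir: results/demo
k: 7
n_init: 100
n_init_session: 20
min_peak_distance: 10
aggregate_n_iter: 50
seed: 7
preprocess: true
simulate:
  n_subjects: 24
  n_channels: 64
  fs: 250.0
  n_classes: 7
  session_plan:
    - [Training, Trial, 30.0]
    - [Training, Trial, 30.0]
    - [Training, Trial, 30.0]
    - [PracticeA, Trial, 30.0]
    - [PracticeA, Trial, 30.0]
    - [PracticeA, Trial, 30.0]
    - [PracticeB, Trial, 30.0]
    - [PracticeB, Trial, 30.0]
    - [PracticeB, Trial, 30.0]
  snr: 4.0
  planted_effects:
    - {class_index: 6, parameter: coverage, dimension: D4, rho: 0.6}
    - {class_index: 5, parameter: coverage, dimension: D1, rho: 0.6}
    - {class_index: 0, parameter: occurrence, dimension: D5, rho: -0.6}
  seed: 0
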