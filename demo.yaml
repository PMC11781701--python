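# Small demonstration experiment: two virtual subjects, the two flagship
# hybrid models plus both single-modality baselines, spectral features.
# `brakesense run --config demo.yaml --out reports/` finishes in ~2 minutes.
n_subjects: 2
seed: 7
test_n_trials: 12
simulation:
  n_trials: 24
  n_hard_trials: 12
evaluation:
  n_folds: 6
models:
  - {model: hbci_fl, strategy: tree, feature_kind: spectral}
  - {model: hbci_se1, strategy: ovr, feature_kind: spectral}
  - {model: eeg, strategy: tree, feature_kind: spectral}
  - {model: emg, strategy: tree, feature_kind: spectral}
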