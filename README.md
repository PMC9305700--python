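# erpmkl

Event-related-potential (ERP) classification pipeline for oddball paradigms:
synthetic two-group cohorts → preprocessing → a 726-column morphological /
spectral feature table → sigmoid scaling → shadow-feature (Boruta-style)
selection → a multiple-kernel SVM with grouped kernels → nested
cross-validated performance metrics.

Because the clinical dataset this kind of analysis targets is third-party
restricted, the package ships a first-class simulator: oddball stimulus
schedules (auditory/visual P300 with 400 stimuli, 10/10/80% target /
distractor / standard split, ISI uniform on 1–1.5 s; MMN with 1800 tones,
5/5/90% split, fixed 0.3 s ISI), Gaussian-bump evoked components with
group-level amplitude/latency effects, additive noise with SNR calibration,
and two-group cohort generation — so every downstream stage is testable
end to end.

## Layout

| module | role |
| --- | --- |
| `erpmkl.synthetic` | paradigm specs, schedules, evoked templates, cohorts |
| `erpmkl.preprocessing` | zero-phase 0.1–30 Hz bandpass, epoching, baseline, artifact rejection, averaging |
| `erpmkl.features` | peak, peak-to-peak and whole-signal features (282+282+162 = 726 columns) |
| `erpmkl.scaling` | per-column z-score + logistic squash into (0, 1) |
| `erpmkl.boruta` | all-relevant selection with shadow features around a random forest |
| `erpmkl.mkl` | linear/polynomial/gaussian kernels, ℓp-constrained kernel weights, alternating training |
| `erpmkl.evaluation` | stratified nested CV, kernel grouping modes, Acc/Sen/Spe/AUC |
| `erpmkl.io`, `erpmkl.pipeline`, `erpmkl.cli` | plain-text formats, config runner, CLI |

## CLI

```sh
erpmkl simulate --seed 1 --n-per-group 10 --out cohort/      # averaged-ERP cohort + manifest
erpmkl featurize --cohort cohort/ --out features.tsv          # 726-column table + schema sidecar
erpmkl select --features features.tsv --out boruta.tsv        # shadow-feature selection report
erpmkl train --features features.tsv --kind gaussian --width 5 --out model.json
erpmkl evaluate --features features.tsv --out eval.json       # nested CV report
erpmkl report --evaluation eval.json                          # metric + selection-frequency summary
erpmkl run --config pipeline.yaml                             # simulate → featurize → evaluate
```

`erpmkl preprocess` converts an external continuous recording (TSV) plus an
event list into per-class averaged responses. All artifacts are delimited
text or JSON and carry the seed and a config hash.

A minimal `pipeline.yaml`:

```yaml
seed: 1
out_dir: out
simulate:
  n_per_group: 10
  target_snr: 4.0
evaluate:
  outer_k: 5
  feature_selection: true
```

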