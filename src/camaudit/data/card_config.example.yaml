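# Example configuration for `camaudit scorecard --config card.yaml --out card.md`
#
# dataset:   directory containing manifest.csv + PNGs (see `camaudit generate`)
# model:     optional saved model archive (.npz); omitted => template detector
# explainer: eigen_cam | ablation_cam

dataset: ./phantoms
explainer: ablation_cam
lesion_radius: 8

framework:
  # Pass thresholds are deliberately not defaulted by the package; every
  # criterion without a threshold is reported as "not evaluated".
  thresholds:
    consistency: 0.5     # mean SSIM over perturbation levels
    plausibility: 0.5    # mean IoU vs ground-truth lesion box
    fidelity: 0.2        # randomization sensitivity (1 - mean pre/post SSIM)
  dose_levels: [1.0, 0.66, 0.5, 0.33]
  rotation_angles: [0.0, 10.0, 25.0, 50.0]
  presence_threshold: 0.5
  seed: 7

descriptive:
  overview:
    name: Ablation CAM
    abbreviation: A-CAM
    type: local, post-hoc heatmap
    software: camaudit 0.1.0
  context_of_use:
    audience: radiologists reading screening mammograms
    task: lesion detection on synthetic mammography phantoms
    model: matched-filter template detector
  limitations_and_recommendations:
    - channel ablation assumes the presence score is the relevant target
  validation_setting: >-
    synthetic phantoms with exact lesion ground truth; no human reader
    study performed
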