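# depthpop

Population analysis of depth coding from single-photon calcium imaging in
freely moving mice. The package turns behavior tracking tables and extracted
neural traces/events into:

- **behavior metrics** for the visual-cliff arena (deep-side distance
  ratios, center-zone exploration, accumulated median speed);
- **depth-sensitive cell selection** in the cliff test via occupancy-
  normalized rate maps and the area-score contrast
  `(A1 - A2) / (|A1| + |A2|)` with a mean ± SD threshold;
- **mutual-information machinery**: a k-nearest-neighbor estimator for
  continuous traces vs. binary head orientation (3 neighbors), discrete /
  conditional / three-way interaction information, rotation and permutation
  shuffle nulls, and MI-based cell selection against the null's 95%
  interval;
- **decoders**: an in-repo Gaussian naive Bayes (depth per X-bin, with
  calibration curves and a scikit-learn classifier roster for comparison),
  k-nearest-neighbor choice decoding over trial time (k = 5), and
  random-forest position decoding (100 trees, 10 iterations of random
  80/20 splits) on maze arms and a linear track, including
  actual-vs-relative (goal-distance) positions and the signed-error
  analysis of prospective coding;
- a **synthetic session generator** with planted cell classes
  (depth-tuned, choice-tuned, place/goal-distance, noise) and full ground
  truth, so every stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `depthpop.core` | domain types (`SimConfig`, `NeuralSession`, `BehaviorTrack`, `RateMap`, `CellScore`, …) |
| `depthpop.simulate` | cliff pair / maze / linear-track session generators, calcium trace rendering |
| `depthpop.preprocess` | sliding-window event rates, z-scoring, trial alignment, speed, zone metrics, cross-registration (≤ 10 px) |
| `depthpop.depth_tuning` | rate maps, area score, depth-cell selection, cross-session R² |
| `depthpop.information` | `mi_knn`, `mi_discrete`, `cmi_discrete`, `joint_mi`, shuffle nulls, MI-cell selection, ridge-line fits |
| `depthpop.decoding` | GNB (from the likelihood formula), choice/position decoders, calibration, error-sign ratios |
| `depthpop.pipeline` | `run_cliff`, `run_vslm`, `run_overlap_and_track`, YAML config, deterministic reports |
| `depthpop.io` | DLC-dialect CSV, HDF5 neural container, JSON ground truth |

## CLI

```bash
# write synthetic sessions (DLC CSV + HDF5 + ground-truth JSON)
depthpop simulate --out out/sim --seed 1

# run the analyses (optionally with a YAML config)
depthpop cliff --out out/cliff --seed 1
depthpop vslm  --out out/vslm  --seed 1
depthpop track --out out/track --seed 1
depthpop all --config config.yaml --out out/all
```

A config file mirrors `AnalysisConfig`; the `sim:` block maps to
`SimConfig`:

```yaml
seed: 1
n_shuffles: 1000
pos_bin_cm: 2.0
sim:
  duration_s: 900.0
  n_trials: 30
  depth_gain: 2.0
```

Every run writes tidy CSV tables plus a `*_report.json` whose bytes are a
pure function of (config, seed).

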