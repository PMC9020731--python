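# wormbox

Bounding-box based behavioral analysis for *C. elegans*.

Modern worm-tracking rigs increasingly rely on object detectors that output
axis-aligned bounding boxes with confidence scores rather than segmented
postures. A surprising amount of biology is recoverable from boxes alone:
where the animal is (the box centroid), how fast it moves, whether it is
roaming or dwelling, how many eggs it has laid and where, and how its
movement declines with age. `wormbox` is the analysis layer for exactly that
setting — it consumes per-frame box annotations/detections (labelImg-style
Pascal VOC XML, COCO-style JSON, or plain CSV) and provides:

- **Detector characterization** (`wormbox.detect_eval`): IoU, greedy
  Pascal-VOC matching, precision, recall/sensitivity
  (TP/(TP+FN)), and interpolated average precision
  AP = Σ Δr · max<sub>r'≥r</sub> p(r′) over the pooled, confidence-ranked
  detections.
- **Centroid kinematics** (`wormbox.kinematics`): single-animal track
  assembly with explicit gaps, displacement and linear velocity in mm/min,
  centered gap-aware smoothing, downsampling, bounding-box growth, and
  agreement statistics against a reference (hand-annotated) track.
- **Behavioral states** (`wormbox.behavior_states`): three-point angular
  velocity |Δheading|/Δt in deg/min and roaming/dwelling classification by
  the 90 deg/min split at 1-minute sampling, with accuracy/confusion
  scoring against ground-truth labels.
- **Egg-laying phenotypes** (`wormbox.egg_analysis`): egg counting at a low
  (0.01) confidence threshold, cross-tile duplicate removal for overlapping
  fields of view, two-window egg-laying rates, the lawn preference score
  (eggs_on − eggs_off)/(eggs_on + eggs_off), and two-sample
  Kolmogorov–Smirnov comparisons.
- **Aging decline** (`wormbox.aging_metrics`): the per-video movement score
  1 − IoU(first-frame box, last-frame box), the mask pixel-change metric
  Σ|m₁ − m₂| / ((Σm₁ + Σm₂)/2), cohort mean ± SEM decline curves, and
  food-level (dietary restriction) comparisons.
- **Synthetic scenarios** (`wormbox.synthetic_data`): a two-state Markov
  trajectory simulator with box growth and detector noise, a burst-like egg
  deposition model with tiled imaging, and an aging-cohort generator whose
  box pairs have exactly the prescribed IoU — each paired with the hidden
  truth needed for recovery testing.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

The `demo` subcommand simulates all three scenarios with one seed, runs
every analysis stage on the simulated observables, and writes
`summary.json` plus per-stage CSVs:

```bash
wormbox demo --seed 0 --out-dir demo_out
```

prints

```json
{
 "AP": 0.9148689529593694,
 "state_accuracy": 0.6574307304785895,
 "egg_rate1": 12.0,
 "preference": 0.4634146341463415
}
```

Reading these numbers: the emulated detector (5% misses, 5% false
positives/frame, 1 px jitter) scores AP 0.915 at confidence 0.5 / IoU 0.5
against the simulation's ground-truth boxes. The 90 deg/min angular-velocity
split labels 65.7% of timestamps with the true roaming/dwelling state on
this run — bracketing the 62.8% Bayes-optimal accuracy of the generative
model computed by quadrature (single-run accuracy fluctuates a few points
around it; the multi-seed average in the acceptance run lands within one
point). The simulated adult laid 24 eggs by the 2-hour snapshot (12.0
eggs/hr in the first window; the 5-hour window gives 5.7 eggs/hr against a
configured mean of 6), and its lawn preference score of +0.46 reflects the
configured 80% on-lawn probability (expected score 2·0.8 − 1 = 0.6).
`summary.json` additionally records the detection confusion counts, the
~5-fold bounding-box growth over development, per-age mean ± SEM movement
decline for both food levels, and the KS comparison between them.

Individual stages are available as `wormbox evaluate`, `wormbox track`,
`wormbox states`, and `wormbox simulate {trajectory,eggs,aging}`, or
directly as library calls:

```python
from wormbox.boxio import read_voc, read_detections
from wormbox.detect_eval import evaluate

frames = read_detections("detections.csv", "csv")
gt = {fr.frame_id: fr for fr in map(read_voc, voc_paths)}
for fr in frames:
    fr.ground_truth = gt[fr.frame_id].ground_truth
report = evaluate(frames, label="worm", confidence_threshold=0.5, iou_threshold=0.5)
print(report.precision, report.recall, report.average_precision)
```

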