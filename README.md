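# uemotion

A toolkit for the taxonomy of functional upper-extremity (UE) motion:
the decomposition of activities of daily living (ADLs) into their five
building-block **functional primitives** —

* **reach** — motion ending in contact with a target object,
* **reposition** — motion ending near (not on) a target,
* **transport** — conveying a grasped/touched target object,
* **stabilize** — holding a target object still under grasp,
* **idle** — minimal-motion "standing at the ready" without target contact,

each further characterized by temporal cyclicity (discrete vs. rhythmic
bouts), the upper-body effector segment chiefly translating the UE
(axial / proximal / distal or adjacent pairs), and grasp type
(prehensile vs. non-prehensile).

The package is aimed at rehabilitation researchers and movement
scientists who need to turn continuous joint-angle + contact recordings
into countable training units. It provides:

* a **rule-based segmentation engine**: endpoint speed in a
  pelvis-centered frame is thresholded (minimal-motion = speed <
  `speed_thresh` sustained ≥ 50 ms) and combined frame-wise with the
  target-contact channel; runs merge into primitives with the taxonomy's
  start/end rules (reach ends at contact completion, transport splits
  where motion direction turns > 90° under sustained grasp, ...);
* **boundary-tolerant inter-rater agreement**: expert/coder transitions
  matched within ±20 ms, the three error types tallied, and per-primitive
  Cohen's κ = (p_o − p_e)/(1 − p_e) averaged over coder-expert pairs;
* a **decision-tree validation harness** for the reach/transport
  phenotype split (whole-primitive 60/40 holdout × 100 repetitions,
  Gini tree, feature importances with per-class mean angles);
* **dose analytics**: primitive dose (count), density (count/s),
  composition percentages, and mixed-model group comparison
  (impairment fixed effect, subject random intercept);
* a **synthetic ADL-session simulator** that emits kinematics, a
  consistent contact channel, intent events, and exact ground-truth
  labels — plus simulated coders and two-group cohorts — so every module
  is testable without any recorded data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from uemotion import *

cfg = SimulationConfig(seed=42, duration_s=60.0)
rec = generate_session(cfg)                       # synthetic ADL session
seq = flag_incomplete(
    segment_primitives(rec.kinematics, rec.contact), rec.intent_events
)
seq = characterize(seq, rec.kinematics, rec.contact)

comp = compute_composition([seq], [rec.kinematics.span_ms / 1000.0])
print(f"dose: {comp.dose} primitives over {comp.duration_s:.1f} s "
      f"(density {comp.density:.2f}/s)")
for label, pct in comp.primitive_pct.items():
    print(f"  {label.value.lower():<10} {pct:5.1f} %")
print(f"motion {comp.motion_pct:.1f} % / minimal-motion {comp.minimal_pct:.1f} %")

coder = simulate_coder(
    rec.truth, CoderModel(boundary_jitter_sd_ms=12.0, label_swap_rate=0.05, seed=7)
)
report = agreement_report(rec.truth, [coder])
for label, kappa in report.kappa.items():
    print(f"  kappa[{label.value.lower():<10}] = {kappa:.3f}")
```

prints

```
dose: 70 primitives over 62.9 s (density 1.11/s)
  reach       21.4 %
  reposition  14.3 %
  transport   27.1 %
  stabilize   14.3 %
  idle        22.9 %
motion 46.1 % / minimal-motion 53.9 %
  kappa[reach     ] = 0.870
  kappa[reposition] = 0.873
  kappa[transport ] = 0.925
  kappa[stabilize ] = 0.883
  kappa[idle      ] = 0.881
```

The session was decomposed into 70 primitives at about one per second;
the composition percentages say what the activity was made of (here
transport-dominated, as tabletop ADLs are). The κ values score a
simulated coder — whose boundaries jitter by ~12 ms and whose labels are
5% corrupted — against the ground truth: boundary misses beyond ±20 ms
and label mismatches both count against agreement, so κ sits below 1
even though most labels match.

On a noise-free simulated session the engine reproduces the generator's
ground truth exactly — labels and boundaries to the frame — which is the
package's core self-consistency property.

## Command line

Every step is also a subcommand of `uemotion`:

```bash
uemotion simulate --out-dir sessions/ --n 10 --seed 1
uemotion segment --kinematics sessions/session_000.csv --out labels.tsv
uemotion characterize --kinematics sessions/session_000.csv \
    --labels labels.tsv --out labels_enriched.tsv
uemotion agree --expert sessions/session_000_truth.tsv \
    --coder labels.tsv --window-ms 20 --out report.json
uemotion analyze --labels labels_enriched.tsv --out summary.json
```

Exit code 2 signals a format/validation error.

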