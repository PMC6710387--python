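# Methods

This note documents the models and procedures implemented in `uemotion`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## The taxonomy as an executable rule cascade

Functional upper-extremity (UE) motion during activities of daily living
is classified frame-by-frame into five mutually exclusive primitives,
distinguished by two explicit phenotypic features:

| presence of motion | target contact | primitive |
|---|---|---|
| motion | grasp/touch of target | **transport** |
| motion | none | **reach** or **reposition** |
| minimal | grasp of target | **stabilize** |
| minimal | none | **idle** |

Reach vs. reposition is resolved at merge time by what terminates the
motion run: a run ending where stable target contact begins is a reach
(its offset is contact completion); a run ending in stillness or at the
recording end is a reposition. Two further layers annotate segments with
temporal cyclicity (discrete vs. rhythmic bouts) and the upper-body
effector segment chiefly translating the UE (axial / proximal / distal or
an adjacent pair).

### Presence of motion

Motion is operationalized as translation of the hand endpoint in a
pelvis-centered body frame. Endpoint speed is the central difference of
position (one-sided at the record edges), optionally smoothed by a moving
average (`smooth_ms`, default 0). A frame is *minimal-motion* iff it lies
in a maximal run of frames with speed below `speed_thresh_cm_s` whose
duration is at least `min_still_ms` (default 50 ms). Sub-threshold runs
shorter than the dwell are absorbed into motion, which is what lets the
rule tolerate subtle drift of a limb held aloft without fragmenting a
motion run.

The 50 ms dwell is part of the taxonomy itself; the speed magnitude is
not — no printed threshold for "largely unchanged" exists, so the 2 cm/s
default is a package convention, chosen to sit well above the drift the
taxonomy tolerates (< 1 cm/s in the simulator) and well below functional
movement speeds (tens of cm/s), and it must remain configurable.

### Contact

Contact/grasp is an *input channel*, never inferred from kinematics: the
taxonomy's contact judgments require knowing the target of engagement,
and grasp is unobservable without instrumenting the fingers. Non-target
contact (resting the hand on a table) is treated as no contact. "Contact
completed" is operationalized as the first frame of a stable (≥2
consecutive frames) grasp/touch state, since per-finger data are out of
scope. The modal target contact state over a grasp-bearing segment gives
its grasp type (target touch counts as non-prehensile — one generated
force opposed externally; ties break toward prehensile).

### Transport splitting

A transport ends when grasp is released **or** when a new direction of
motion begins with the object in hand. The splitter looks for frames
inside a conveyance run where the smoothed velocity direction before and
after (50 ms windows) differs by more than `direction_split_deg`
(default 90°); one turn produces a cluster of adjacent candidate frames,
and the split goes at the cluster's local speed minimum. The 90° default
separates out-and-back strokes without fragmenting curved paths.

### Incomplete variants

Failed primitives are identified by observer intent cues, not phenotype,
so they arrive as an event channel: an `OBJECT_DROPPED` event inside a
transport/stabilize marks it incomplete; a `TARGET_AIMED_MISSED` event
inside a reposition relabels it as an incomplete reach. Events that match
no segment are warnings, not errors.

### Cyclicity

A cycle unit is an adjacent transport+transport pair of alternating
direction (brushing strokes) or an adjacent reach+transport pair
(repeated regrasp-and-turn). Runs of ≥2 consecutive units whose
amplitudes agree within `amp_tol_frac` (default 25%, invented and
configurable — no printed tolerance exists), whose leading strokes share
a direction, and whose inter-unit pauses stay below `bout_gap_factor` ×
the median intra-bout pause form one rhythmic bout with a shared
`bout_id`. Transport-transport pairing takes priority over
reach-transport pairing at any position; otherwise a reach leading into
an alternating stroke run would steal the run's first transport and
misalign every subsequent pair. Cycle logic is deliberately
segment-pair-based, not spectral: the taxonomy describes cycles as
primitive pairs.

### Effector attribution

Per frame pair, the endpoint displacement attributable to each joint
group (axial: trunk flexion; proximal: shoulder flexion/abduction, elbow
flexion; distal: forearm supination, wrist extension) is the displacement
predicted by a fixed kinematic chain when only that group's angles
advance and the others stay frozen. The chain (trunk 40 cm, upper arm
30 cm, forearm+hand 35 cm, 10 cm wrist lever, 6 cm supination lever) is a
shared convention, not a per-subject calibration; what matters is the
ordering of lever arms. Displacements are summed over the segment's
interior frame pairs only, so posture changes at segment boundaries are
attributed to neither neighbor. If one group's share reaches
`dominance_frac` (default 0.66) it is returned alone — this also subsumes
small distal adjustments that orient the hand during a proximal motion —
otherwise the adjacent pair holding the two largest shares is returned.
When the top two shares belong to the non-adjacent axial/distal pair
(undefined in a strictly adjacent-pair scheme), the adjacent pair with
the larger combined share is returned.

## Agreement

Coder segmentations are scored against an expert within a ±20 ms window
around each expert transition (segment onset). Greedy nearest-first
pairing matches expert to coder transitions (each coder transition used
once, ties to the earlier one); no coder transition within twice the
window is a miss. An item is an error if (1) the boundary misses the
window even with a matching label, (2) the boundary is in-window but the
label mismatches, or (3) both.

The unit of analysis for kappa is a reconstruction (protocols of this
kind rarely state whether kappa was computed over frames, segments, or
transitions): items are expert segments; the coder-side category is the
coder's label when the matched onset lies inside the window, and a
distinct ERROR category when the boundary itself missed. Gating on the
boundary alone matters: if the coder's label were replaced by ERROR on
*any* disagreement, the ERROR category would be correlated with the
expert side and independent raters would score kappa ≈ +0.28 rather than
0; with boundary-only gating, an in-window label mismatch disagrees with
the expert naturally, all three error rules still enter the statistic,
and chance-level agreement scores ≈ 0. Per-primitive kappa is one-vs-rest
over the five labels plus ERROR, averaged across coder-expert pairs.
Kappa itself is the standard chance-corrected agreement
κ = (p_o − p_e)/(1 − p_e); the degenerate both-raters-constant case
returns 1 at perfect agreement. Only onsets gate items; offsets are not
scored as separate items.

## The reach/transport decision-tree harness

Frames of reach and transport segments form the dataset (six joint
angles per row, one label and one `primitive_id` per segment). In each of
`reps` (default 100) repetitions, *primitives* — never frames — are
split 60/40 into train/test; a Gini-impurity binary tree (depth 5 by
default; hyperparameters are unprinted anywhere, chosen here for
interpretability and configurable) is fit on training frames; a test
primitive is correct when the majority vote over its frames matches its
label. Whether published accuracies of this design were frame- or
primitive-level is ambiguous, so both are computed; primitive-level is
the headline because it respects whole-primitive splitting. Feature
importances are averaged over repetitions and reported with per-class
mean angles, so the direction of the phenotype difference (reaches:
greater wrist extension/supination, more extended elbow) is readable.
Single-class test partitions are redrawn (at most 10 times).

## Dose metrics and group comparison

Dose is the primitive count; density is dose divided by duration
(an exact identity, asserted everywhere); primitive-type and incomplete
percentages are count shares of the dose; motion vs. minimal-motion,
discrete vs. rhythmic, and effector shares are time shares by default
(segment-count weighting is exposed as an option, since the published
shares do not state their weighting); grasp shares are count shares over
transport+stabilize segments. Frames outside any labeled segment are
excluded from all denominators. Aggregation across trials is pooled
(count-preserving); per-trial summaries are also available.

Group comparisons fit, per outcome, a linear mixed model with impairment
group as a fixed effect and a subject random intercept, via statsmodels
`MixedLM` (REML). The model stage is standard estimation machinery; the
bespoke content of the module is the metric definitions. Designs with
fewer than two subjects in a group are refused. The reported df is the
residual n − 2 approximation; the test statistic is the Wald z of the
fixed effect.

## The synthetic-session generator

The generator emulates tabletop/sink ADL sessions at 100 Hz with exact
ground truth, and is the oracle for every other module.

**Sequence grammar.** Primitives are sampled with mixture-weighted
choices over the currently feasible labels. Default mixture
(transport 38.5%, stabilize 26%, idle 15.5%, reach 12.5%,
reposition 7.5%), default density 1/s, and the mild/moderate group
presets (density 1.2 vs 0.9 /s, more transports vs more reaches/idles,
99% vs 90% prehensile grasps, ~0% vs 10% axial-proximal motion) mirror
the regime reported for this class of activities. Grammar constraints —
a reposition is always followed by an idle, an idle never follows an
idle, a reach is never preceded by a reposition, consecutive transports
occur only inside alternating-direction rhythmic bouts — exist because
adjacent segments with identical frame-level signatures would merge into
a single run and be unrecoverable by *any* frame-rule segmenter; the
realized label frequencies therefore approximate but do not equal the
raw mixture. Durations are log-normal (medians: reach 0.5 s,
reposition 0.6 s, transport 1.0 s, stabilize/idle 1.5 s, log-sd 0.18 —
invented, configurable), scaled uniformly to hit the requested density;
a config needing a scale below 0.3 is infeasible.

**Endpoint trajectories.** Motion primitives travel straight toward a
workspace target with a raised-bell (minimum-jerk-like) speed profile
whose floor stays above the stillness threshold, with asymmetric onset
(5.4 cm/s) and offset (2.6 cm/s) floors chosen so that *central-
difference* speed crosses the 2 cm/s threshold exactly at the boundary
frame against sub-0.8 cm/s drift on the minimal side. A pure
minimum-jerk profile (zero boundary velocity) would make any thresholded
detector fire tens of milliseconds inside the true segment, which is a
property of threshold detection, not an engine defect; the floored
profile makes frame-exact recovery well-defined. Minimal-motion
primitives get mean-reverting sub-threshold drift. Within rhythmic
bouts, strokes alternate direction at equal amplitude, so the reversal
frame is a one-frame speed dip — exactly the signature the transport
splitter keys on.

**Angles.** Each segment's joint angles are a session baseline plus a
constant per-label phenotype offset (reach: +20° wrist extension, +12°
supination, −12° elbow flexion; transport: +15° shoulder flexion, +10°
abduction) plus a smooth sinusoidal excursion on the designated effector
group's joints only. Phenotype offsets step at segment boundaries rather
than ramping inside segments; this keeps effector attribution exact and
gives the decision tree clean per-frame class structure, at the cost of
realism (real angle traces have no boundary steps, and angles here are
deliberately decoupled from the endpoint trajectory rather than linked
through forward kinematics). Gaussian noise on angles and endpoint is
added last.

**Coders and cohorts.** A simulated coder jitters each distinct boundary
by Gaussian noise (clipped to neighboring-boundary midpoints to preserve
ordering, optionally hard-clipped by `max_abs_ms` so boundedly-jittered
coders can be constructed exactly) and swaps each label to a uniformly
random other primitive at `label_swap_rate`. Cohorts layer a per-subject
lognormal density perturbation (sd 5%) over the group presets — the
random-intercept structure the mixed model expects.

**What passing tests show.** Noise-free oracle equivalence shows the
engine implements the stated rules exactly on data that obeys them; it
does not show robustness to real sensor noise (white endpoint noise at
100 Hz is brutal in velocity — agreement degrades from 1.0 to ~0.4 as
per-frame position noise grows from 0 to 0.05 cm, and the tests only
assert that this degradation is monotone). Phenotype separability in the
simulator is by construction; the published ~92% accuracy of the
equivalent harness on real instrumented recordings is not reproducible
here and is not claimed. Likewise the simulated-coder kappas validate
the agreement machinery, not human reliability.

## Problem sizes

Default test/verification sizes: 50 noise-free 60 s sessions for oracle
equivalence; 100 seeds × 60 segments for the chance-kappa law; 20 seeds
per point on the swap/jitter grids; 10 sessions (~330 reach/transport
primitives) × 100 repetitions for the tree harness; 1,000 primitives for
mixture recovery; 50 replicates of a 5+5-subject × 5-trial × 20 s cohort
for density-effect sign recovery; 200 property-generated round-trip
cases.

## Known limitations

* The contact and intent channels must be supplied (by an annotator or
  the simulator); nothing is inferred from video or raw inertial data.
* Movement quality/abnormality is deliberately not graded, and
  peripersonal-space extent is not classified.
* The rhythmic-bout detector may mark accidental repeats of similar
  adjacent reach+transport pairs as rhythmic; such repeats genuinely
  satisfy the cycle definition, but the generator does not plan them, so
  cyclicity tests assert recovery of planned bouts rather than exact
  cyclicity equality.
* `NONCLASSIFIABLE` is reserved for contradictory channel states and is
  never produced by the nominal rules.
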