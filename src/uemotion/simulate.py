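"""Synthetic ADL-session generator with exact ground-truth labels.

Sessions are sampled from a small grammar over the five primitives that
keeps the contact channel consistent with the labels (a grasp begins where
a reach ends and is released where the last conveying/stabilizing segment
ends) and guarantees that adjacent segments always differ in their
frame-level signature, so a rule-based segmenter can in principle recover
the truth exactly.

Endpoint trajectories for motion primitives are straight paths with a
minimum-jerk-like raised bell speed profile whose floor sits above the
engine's stillness threshold (asymmetric at onset vs offset so that
central-difference speed crosses the threshold exactly at the boundary
frame); minimal-motion primitives get mean-reverting sub-threshold drift.
Joint angles carry the primitive phenotypes (reaches: greater wrist
extension, forearm supination, and elbow extension; transports: greater
shoulder flexion and abduction) as constant within-segment offsets, while
the designated effector group's joints move smoothly within the segment —
so effector attribution and the decision-tree phenotype check both have a
known ground truth. Gaussian noise, when configured, is added last.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .errors import FeasibilityError, UemotionError
from .types import (
    ANGLE_NAMES,
    ContactSeries,
    ContactState,
    Cyclicity,
    Effector,
    EngineParams,
    GraspType,
    ImpairmentGroup,
    IntentEvent,
    IntentKind,
    KinematicSeries,
    LabelSequence,
    PrimitiveLabel,
    PrimitiveSegment,
    SessionRecording,
)

FRAME_MS = 10  # 100 Hz

# speed profile floors (cm/s); both sit above the 2 cm/s stillness
# threshold, and their choice makes central-difference speed cross the
# threshold exactly at segment boundaries against sub-0.8 cm/s drift:
# the first frame of a motion segment averages the onset step with the
# preceding drift step ((5.4 - 0.7) / 2 > 2), while the first frame after
# it averages the offset step with drift ((2.6 + 0.7) / 2 < 2)
_V_FLOOR_START = 5.4
_V_FLOOR_END = 2.6
_DRIFT_MAX_CM_S = 0.8

#: default duration medians (seconds) per primitive; lognormal around these
DEFAULT_DURATION_MEDIANS = {
    PrimitiveLabel.REACH: 0.5,
    PrimitiveLabel.REPOSITION: 0.6,
    PrimitiveLabel.TRANSPORT: 1.0,
    PrimitiveLabel.STABILIZE: 1.5,
    PrimitiveLabel.IDLE: 1.5,
}
_DURATION_LOG_SD = 0.18
_MIN_SEG_S = 0.26

#: session-baseline posture (degrees), ordered as ANGLE_NAMES
BASE_POSTURE = np.array([5.0, 30.0, 15.0, 60.0, 10.0, 5.0])

#: designated-effector excursion amplitudes (degrees) per joint; the
#: amplitudes are sized so each class's joint-group displacement shares
#: land where the dominance rule expects them under the body geometry
EFFECTOR_EXCURSIONS: Dict[Effector, Dict[str, float]] = {
    Effector.AXIAL: {"trunk_flexion": 15.0},
    Effector.PROXIMAL: {
        "shoulder_flexion": 25.0,
        "shoulder_abduction": 12.0,
        "elbow_flexion": -15.0,
    },
    Effector.DISTAL: {"wrist_extension": 20.0, "forearm_supination": 15.0},
    Effector.AXIAL_PROXIMAL: {"trunk_flexion": 12.0, "shoulder_flexion": 12.0},
    Effector.PROXIMAL_DISTAL: {
        "shoulder_flexion": 6.0,
        "wrist_extension": 25.0,
        "forearm_supination": 18.0,
    },
}


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-primitive joint-angle offsets (degrees), constant per segment."""

    reach_wrist_extension_deg: float = 20.0
    reach_supination_deg: float = 12.0
    reach_elbow_extension_deg: float = 12.0  # subtracted from elbow flexion
    transport_shoulder_flexion_deg: float = 15.0
    transport_shoulder_abduction_deg: float = 10.0

    def offsets(self, label: PrimitiveLabel) -> np.ndarray:
        off = np.zeros(len(ANGLE_NAMES))
        if label is PrimitiveLabel.REACH:
            off[ANGLE_NAMES.index("wrist_extension")] = self.reach_wrist_extension_deg
            off[ANGLE_NAMES.index("forearm_supination")] = self.reach_supination_deg
            off[ANGLE_NAMES.index("elbow_flexion")] = -self.reach_elbow_extension_deg
        elif label is PrimitiveLabel.TRANSPORT:
            off[ANGLE_NAMES.index("shoulder_flexion")] = self.transport_shoulder_flexion_deg
            off[ANGLE_NAMES.index("shoulder_abduction")] = self.transport_shoulder_abduction_deg
        return off


def _default_mixture() -> Dict[PrimitiveLabel, float]:
    # observed ADL composition regime: transports and stabilizations
    # predominate, repositions are rare
    return {
        PrimitiveLabel.REACH: 0.125,
        PrimitiveLabel.REPOSITION: 0.075,
        PrimitiveLabel.TRANSPORT: 0.385,
        PrimitiveLabel.STABILIZE: 0.26,
        PrimitiveLabel.IDLE: 0.155,
    }


def _default_effector_profile() -> Dict[Effector, float]:
    return {
        Effector.PROXIMAL: 0.82,
        Effector.DISTAL: 0.07,
        Effector.PROXIMAL_DISTAL: 0.06,
        Effector.AXIAL_PROXIMAL: 0.05,
        Effector.AXIAL: 0.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic ADL session.

    Defaults emulate the mildly-structured tabletop/sink ADL regime:
    ~1 primitive per second, transport/stabilize-dominated composition,
    predominantly proximal effector use, mostly prehensile grasps, and an
    occasional rhythmic bout.
    """

    seed: int = 0
    duration_s: float = 60.0
    density_per_s: float = 1.0
    mixture: Dict[PrimitiveLabel, float] = field(default_factory=_default_mixture)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    effector_profile: Dict[Effector, float] = field(default_factory=_default_effector_profile)
    grasp_profile: float = 0.95  # prehensile probability per hold episode
    rhythmic_prob: float = 0.10
    noise_sd_deg: float = 0.0
    noise_sd_cm: float = 0.0
    incomplete_prob: float = 0.005
    duration_medians_s: Dict[PrimitiveLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_MEDIANS)
    )
    group: ImpairmentGroup = ImpairmentGroup.CONTROL

    def __post_init__(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise UemotionError("mixture probabilities must sum to 1")
        probs = [self.grasp_profile, self.rhythmic_prob, self.incomplete_prob]
        probs += list(self.effector_profile.values())
        if any(p < 0 or p > 1 for p in probs):
            raise UemotionError("probabilities must lie in [0, 1]")
        if abs(sum(self.effector_profile.values()) - 1.0) > 1e-9:
            raise UemotionError("effector profile must sum to 1")
        if self.duration_s <= 0 or self.density_per_s <= 0:
            raise UemotionError("duration and density must be positive")


def mild_config(seed: int = 0, **kw) -> SimulationConfig:
    """Preset echoing the mildly impaired group's regime (higher density,
    more transports, almost no combined axial-proximal motion)."""
    mixture = {
        PrimitiveLabel.REACH: 0.115,
        PrimitiveLabel.REPOSITION: 0.075,
        PrimitiveLabel.TRANSPORT: 0.42,
        PrimitiveLabel.STABILIZE: 0.25,
        PrimitiveLabel.IDLE: 0.14,
    }
    eff = {
        Effector.PROXIMAL: 0.84,
        Effector.DISTAL: 0.09,
        Effector.PROXIMAL_DISTAL: 0.065,
        Effector.AXIAL_PROXIMAL: 0.005,
        Effector.AXIAL: 0.0,
    }
    defaults = dict(
        seed=seed,
        density_per_s=1.2,
        mixture=mixture,
        effector_profile=eff,
        grasp_profile=0.99,
        incomplete_prob=0.0032,
        group=ImpairmentGroup.MILD,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def moderate_config(seed: int = 0, **kw) -> SimulationConfig:
    """Preset echoing the moderately impaired group's regime (lower
    density, more reaches/idles, more axial-proximal motion, more
    non-prehensile grasps)."""
    mixture = {
        PrimitiveLabel.REACH: 0.135,
        PrimitiveLabel.REPOSITION: 0.07,
        PrimitiveLabel.TRANSPORT: 0.36,
        PrimitiveLabel.STABILIZE: 0.27,
        PrimitiveLabel.IDLE: 0.165,
    }
    eff = {
        Effector.PROXIMAL: 0.775,
        Effector.DISTAL: 0.06,
        Effector.PROXIMAL_DISTAL: 0.065,
        Effector.AXIAL_PROXIMAL: 0.10,
        Effector.AXIAL: 0.0,
    }
    defaults = dict(
        seed=seed,
        density_per_s=0.9,
        mixture=mixture,
        effector_profile=eff,
        grasp_profile=0.905,
        incomplete_prob=0.0068,
        group=ImpairmentGroup.MODERATE,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@dataclass
class CoderModel:
    """Simulated human coder: boundary jitter plus random label swaps."""

    boundary_jitter_sd_ms: float = 10.0
    label_swap_rate: float = 0.0
    seed: int = 0
    max_abs_ms: Optional[float] = None  # optional hard clip on jitter

    def __post_init__(self) -> None:
        if self.boundary_jitter_sd_ms < 0:
            raise UemotionError("jitter sd must be >= 0")
        if not (0.0 <= self.label_swap_rate <= 1.0):
            raise UemotionError("swap rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# sequence grammar
# ---------------------------------------------------------------------------

@dataclass
class _PlannedSegment:
    label: PrimitiveLabel
    n_frames: int
    effector: Effector = Effector.NOT_APPLICABLE
    grasp: GraspType = GraspType.NONE
    cyclicity: Cyclicity = Cyclicity.DISCRETE
    bout_id: Optional[int] = None
    amplitude_cm: float = 0.0
    direction: Optional[np.ndarray] = None
    incomplete: bool = False
    event: Optional[IntentKind] = None


def _duration_scale(config: SimulationConfig) -> float:
    mean_factor = math.exp(0.5 * _DURATION_LOG_SD**2)
    base_mean = sum(
        p * config.duration_medians_s[l] * mean_factor for l, p in config.mixture.items()
    )
    scale = (1.0 / config.density_per_s) / base_mean
    if scale < 0.3:
        raise FeasibilityError(
            f"density {config.density_per_s}/s needs duration scale {scale:.2f} "
            "(< 0.3) given the configured duration medians"
        )
    return scale


def _sample_duration_frames(
    label: PrimitiveLabel, scale: float, config: SimulationConfig, rng: np.random.Generator
) -> int:
    median = config.duration_medians_s[label] * scale
    dur = float(np.exp(rng.normal(np.log(median), _DURATION_LOG_SD)))
    dur = max(dur, _MIN_SEG_S)
    return max(int(round(dur * 1000.0 / FRAME_MS)), int(_MIN_SEG_S * 100))


def _choose(rng: np.random.Generator, options: List, weights: List[float]):
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(options))
    w = w / w.sum()
    return options[int(rng.choice(len(options), p=w))]


def _plan_sequence(config: SimulationConfig, rng: np.random.Generator) -> List[_PlannedSegment]:
    """Sample the primitive sequence from the grammar.

    Ordering constraints (each exists because adjacent segments with the
    same frame-level signature would merge into one run): a reposition is
    always followed by an idle; an idle never follows an idle; a reach is
    never preceded by a reposition; consecutive transports occur only
    inside alternating-direction rhythmic bouts.
    """
    n_frames_target = int(round(config.duration_s * 1000.0 / FRAME_MS))
    scale = _duration_scale(config)
    mix = config.mixture
    plan: List[_PlannedSegment] = []
    total = 0
    holding = False
    hold_grasp = GraspType.NONE
    bout_id = 0
    prev: Optional[PrimitiveLabel] = None

    def dur(label: PrimitiveLabel) -> int:
        return _sample_duration_frames(label, scale, config, rng)

    R, P, T, S, I = (
        PrimitiveLabel.REACH,
        PrimitiveLabel.REPOSITION,
        PrimitiveLabel.TRANSPORT,
        PrimitiveLabel.STABILIZE,
        PrimitiveLabel.IDLE,
    )
    eff_classes = list(config.effector_profile.keys())
    eff_weights = list(config.effector_profile.values())

    while total < n_frames_target:
        if not holding:
            if prev is P:
                choice = I
            elif prev is I:
                choice = _choose(rng, [R, P], [mix[R], mix[P]])
            else:  # session start or just released
                choice = _choose(rng, [R, P, I], [mix[R], mix[P], mix[I]])
        else:
            if prev is R:
                choice = _choose(rng, [T, S], [mix[T], mix[S]])
            elif prev is T:
                # release options weighted by their mixture mass
                choice = _choose(
                    rng, [S, "REL_R", "REL_P", "REL_I"],
                    [mix[S], mix[R], mix[P], mix[I]],
                )
            else:  # prev is STABILIZE
                choice = _choose(
                    rng, [T, "REL_R", "REL_P", "REL_I"],
                    [mix[T], mix[R], mix[P], mix[I]],
                )
        if choice in ("REL_R", "REL_P", "REL_I"):  # release, then move on
            holding = False
            hold_grasp = GraspType.NONE
            choice = {"REL_R": R, "REL_P": P, "REL_I": I}[choice]

        if choice in (R, P):
            eff = _choose(rng, eff_classes, eff_weights)
            incomplete_reach = choice is P and rng.random() < config.incomplete_prob
            label = R if incomplete_reach else choice
            plan.append(
                _PlannedSegment(
                    label=label,
                    n_frames=dur(choice),
                    effector=eff,
                    incomplete=incomplete_reach,
                    event=IntentKind.TARGET_AIMED_MISSED if incomplete_reach else None,
                )
            )
            if incomplete_reach:
                # an incomplete reach behaves like a reposition kinematically
                # and is followed by an idle
                plan.append(_PlannedSegment(label=I, n_frames=dur(I)))
                total += plan[-1].n_frames
                prev = I
                total += plan[-2].n_frames
                continue
            if choice is R:
                holding = True
                hold_grasp = (
                    GraspType.PREHENSILE
                    if rng.random() < config.grasp_profile
                    else GraspType.NON_PREHENSILE
                )
            prev = choice
            total += plan[-1].n_frames
            continue

        if choice is T:
            eff = _choose(rng, eff_classes, eff_weights)
            if prev is not T and rng.random() < config.rhythmic_prob:
                bout_id += 1
                cycles = int(rng.integers(2, 5))
                n = dur(T)
                for c in range(2 * cycles):
                    plan.append(
                        _PlannedSegment(
                            label=T,
                            n_frames=n,
                            effector=eff,
                            grasp=hold_grasp,
                            cyclicity=Cyclicity.RHYTHMIC,
                            bout_id=bout_id,
                        )
                    )
                    total += n
                prev = T
                continue
            plan.append(
                _PlannedSegment(label=T, n_frames=dur(T), effector=eff, grasp=hold_grasp)
            )
        else:  # STABILIZE or IDLE
            grasp = hold_grasp if choice is S else GraspType.NONE
            plan.append(_PlannedSegment(label=choice, n_frames=dur(choice), grasp=grasp))
        total += plan[-1].n_frames
        prev = choice

    # a trailing reach whose grasp never begins is, by definition, a
    # motion ending near (not on) its target: a reposition
    if plan and plan[-1].label is R and not plan[-1].incomplete:
        plan[-1].label = P

    # drop events on the last holding segment of an episode
    for i, seg in enumerate(plan):
        nxt_holding = i + 1 < len(plan) and plan[i + 1].grasp is not GraspType.NONE
        if (
            seg.label in (T, S)
            and not nxt_holding
            and seg.cyclicity is Cyclicity.DISCRETE
            and rng.random() < config.incomplete_prob
        ):
            seg.incomplete = True
            seg.event = IntentKind.OBJECT_DROPPED
    return plan


# ---------------------------------------------------------------------------
# kinematic realization
# ---------------------------------------------------------------------------

_WORKSPACE_CENTER = np.array([32.0, -12.0, 8.0])
_WORKSPACE_HALF = np.array([14.0, 14.0, 10.0])


def _bell_speed(n: int, amplitude_cm: float) -> np.ndarray:
    """Per-step speeds (cm/s): raised bell with asymmetric floors.

    The step integral equals ``amplitude_cm`` exactly.
    """
    tau = (np.arange(n) + 0.5) / n
    floor = _V_FLOOR_START + (_V_FLOOR_END - _V_FLOOR_START) * tau
    bell = np.sin(np.pi * tau) ** 2
    dt_s = FRAME_MS / 1000.0
    residual = amplitude_cm - floor.sum() * dt_s
    if residual < 0:
        # amplitude too small for the floor: stretch the floor down uniformly
        return np.full(n, amplitude_cm / (n * dt_s))
    v = floor + bell * residual / (bell.sum() * dt_s)
    return v


def _min_amplitude(n_frames: int) -> float:
    # floor integral plus a margin so the bell has positive residual
    return (_V_FLOOR_END + _V_FLOOR_START) / 2.0 * n_frames * FRAME_MS / 1000.0 * 1.15


def _drift_steps(n: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting sub-threshold drift displacements per step (cm)."""
    dt_s = FRAME_MS / 1000.0
    max_step = _DRIFT_MAX_CM_S * dt_s * 0.85
    pos = np.zeros(3)
    steps = np.zeros((n, 3))
    for i in range(n):
        step = rng.normal(0.0, 0.002, 3) - 0.03 * pos
        norm = np.linalg.norm(step)
        if norm > max_step:
            step *= max_step / norm
        steps[i] = step
        pos += step
    return steps


def _pick_direction(
    pos: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit direction keeping the endpoint near the workspace."""
    for _ in range(20):
        target = _WORKSPACE_CENTER + rng.uniform(-1.0, 1.0, 3) * _WORKSPACE_HALF
        d = target - pos
        norm = np.linalg.norm(d)
        if norm > 0.5 * amplitude:
            return d / norm
    d = _WORKSPACE_CENTER - pos
    return d / max(np.linalg.norm(d), 1e-9)


def generate_session(
    config: SimulationConfig,
    subject_id: str = "S01",
    activity: str = "synthetic_adl",
    trial: int = 0,
) -> SessionRecording:
    """Generate one ground-truth-labeled synthetic session.

    Output is a pure function of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    plan = _plan_sequence(config, rng)
    n_total = sum(s.n_frames for s in plan)
    t = np.arange(n_total, dtype=np.int64) * FRAME_MS

    endpoint = np.zeros((n_total, 3))
    angles = np.tile(BASE_POSTURE, (n_total, 1))
    contact_state = np.full(n_total, ContactState.NONE.value, dtype="U14")
    is_target = np.zeros(n_total, dtype=bool)

    pos = _WORKSPACE_CENTER + rng.uniform(-4, 4, 3)
    idx = 0
    segments: List[PrimitiveSegment] = []
    events: List[IntentEvent] = []
    bout_amp, bout_dir = 0.0, np.zeros(3)

    motion_labels = (PrimitiveLabel.REACH, PrimitiveLabel.REPOSITION, PrimitiveLabel.TRANSPORT)
    for si, seg in enumerate(plan):
        a, b = idx, idx + seg.n_frames
        onset_ms, offset_ms = a * FRAME_MS, b * FRAME_MS
        if seg.label in motion_labels:
            if seg.cyclicity is Cyclicity.RHYTHMIC:
                same_bout = bool(segments) and segments[-1].bout_id == seg.bout_id
                if same_bout:
                    amp = bout_amp
                    direction = -bout_dir  # strokes alternate out-and-back
                else:
                    amp = max(rng.uniform(12.0, 22.0), _min_amplitude(seg.n_frames))
                    direction = _pick_direction(pos, amp, rng)
                bout_amp, bout_dir = amp, direction
            else:
                lo, hi = {
                    PrimitiveLabel.REACH: (15.0, 28.0),
                    PrimitiveLabel.REPOSITION: (12.0, 24.0),
                    PrimitiveLabel.TRANSPORT: (15.0, 32.0),
                }[seg.label]
                amp = max(rng.uniform(lo, hi), _min_amplitude(seg.n_frames))
                direction = _pick_direction(pos, amp, rng)
            speeds = _bell_speed(seg.n_frames, amp)
            steps = direction[None, :] * speeds[:, None] * (FRAME_MS / 1000.0)
        else:
            steps = _drift_steps(seg.n_frames, rng)
        traj = pos + np.cumsum(steps, axis=0)
        endpoint[a:b] = np.vstack([pos[None, :], traj[:-1]]) if seg.n_frames > 1 else pos
        pos = traj[-1]

        # angles: constant phenotype offset + designated effector excursion
        ang = BASE_POSTURE + config.phenotype.offsets(seg.label)
        frame_angles = np.tile(ang, (seg.n_frames, 1))
        if seg.label in motion_labels and seg.effector is not Effector.NOT_APPLICABLE:
            tau = (np.arange(seg.n_frames) + 0.5) / seg.n_frames
            bump = np.sin(np.pi * tau)
            for joint, amp_deg in EFFECTOR_EXCURSIONS[seg.effector].items():
                frame_angles[:, ANGLE_NAMES.index(joint)] += amp_deg * bump
        angles[a:b] = frame_angles

        if seg.grasp is not GraspType.NONE:
            contact_state[a:b] = (
                ContactState.PREHENSILE.value
                if seg.grasp is GraspType.PREHENSILE
                else ContactState.NON_PREHENSILE.value
            )
            is_target[a:b] = True
        elif seg.label is PrimitiveLabel.IDLE and rng.random() < 0.3:
            contact_state[a:b] = ContactState.TOUCH.value  # resting on the table
            is_target[a:b] = False

        if seg.event is not None:
            ev_t = int(rng.integers(onset_ms + FRAME_MS, offset_ms - FRAME_MS))
            events.append(IntentEvent(t_ms=ev_t, kind=seg.event))

        segments.append(
            PrimitiveSegment(
                label=seg.label,
                onset_ms=onset_ms,
                offset_ms=offset_ms,
                cyclicity=seg.cyclicity,
                bout_id=seg.bout_id,
                effector=seg.effector if seg.label in motion_labels else Effector.NOT_APPLICABLE,
                grasp=seg.grasp,
                incomplete=seg.incomplete,
            )
        )
        idx = b

    if config.noise_sd_cm > 0:
        endpoint = endpoint + rng.normal(0.0, config.noise_sd_cm, endpoint.shape)
    if config.noise_sd_deg > 0:
        angles = angles + rng.normal(0.0, config.noise_sd_deg, angles.shape)

    kin = KinematicSeries(t=t, angles=angles, endpoint=endpoint)
    contact = ContactSeries(t=t, state=contact_state, is_target=is_target)
    truth = LabelSequence(segments=segments, span_ms=kin.span_ms)
    events.sort(key=lambda e: e.t_ms)
    return SessionRecording(
        subject_id=subject_id,
        activity=activity,
        trial=trial,
        impairment_group=config.group,
        kinematics=kin,
        contact=contact,
        intent_events=events,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# simulated coders and cohorts
# ---------------------------------------------------------------------------

_SWAP_POOL = [
    PrimitiveLabel.REACH,
    PrimitiveLabel.REPOSITION,
    PrimitiveLabel.TRANSPORT,
    PrimitiveLabel.STABILIZE,
    PrimitiveLabel.IDLE,
]


def simulate_coder(truth: LabelSequence, model: CoderModel) -> LabelSequence:
    """Relabel a ground-truth sequence like an imperfect human coder.

    Each distinct boundary is shifted by Gaussian jitter (clipped to the
    midpoints of its neighboring boundaries so ordering and non-overlap
    are preserved, and optionally to ``max_abs_ms``); each label is
    independently swapped to a random other primitive at ``label_swap_rate``.
    """
    rng = np.random.default_rng(model.seed)
    bounds = sorted({s.onset_ms for s in truth.segments} | {s.offset_ms for s in truth.segments})
    new_bounds: Dict[int, int] = {}
    for i, bnd in enumerate(bounds):
        jit = rng.normal(0.0, model.boundary_jitter_sd_ms)
        if model.max_abs_ms is not None:
            jit = float(np.clip(jit, -model.max_abs_ms, model.max_abs_ms))
        lo = (bounds[i - 1] + bnd) / 2 + 1 if i > 0 else 0
        hi = (bnd + bounds[i + 1]) / 2 - 1 if i < len(bounds) - 1 else truth.span_ms
        new_bounds[bnd] = int(round(np.clip(bnd + jit, lo, hi)))
    out = []
    for seg in truth.segments:
        label = seg.label
        if rng.random() < model.label_swap_rate:
            label = _SWAP_POOL[int(rng.choice([i for i, l in enumerate(_SWAP_POOL) if l is not label]))]
        grasp = seg.grasp
        if label in (PrimitiveLabel.TRANSPORT, PrimitiveLabel.STABILIZE):
            if grasp is GraspType.NONE:
                grasp = GraspType.PREHENSILE
        else:
            grasp = GraspType.NONE
        out.append(
            seg.replace(
                label=label,
                onset_ms=new_bounds[seg.onset_ms],
                offset_ms=new_bounds[seg.offset_ms],
                grasp=grasp,
            )
        )
    return LabelSequence(segments=out, span_ms=truth.span_ms)


def sample_label_sequence(
    mixture: Dict[PrimitiveLabel, float],
    n_primitives: int,
    rng: np.random.Generator,
    duration_medians_s: Optional[Dict[PrimitiveLabel, float]] = None,
) -> LabelSequence:
    """Annotation-level sequence of i.i.d. mixture draws (no kinematics).

    Used to exercise composition metrics against a known generating
    mixture without the ordering constraints of the session grammar.
    """
    medians = duration_medians_s or DEFAULT_DURATION_MEDIANS
    labels = list(mixture.keys())
    probs = np.array([mixture[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    t = 0
    segs = []
    for _ in range(n_primitives):
        label = labels[int(rng.choice(len(labels), p=probs))]
        dur = float(np.exp(rng.normal(np.log(medians[label]), _DURATION_LOG_SD)))
        n_ms = max(int(round(dur * 1000)), 50)
        grasp = (
            GraspType.PREHENSILE
            if label in (PrimitiveLabel.TRANSPORT, PrimitiveLabel.STABILIZE)
            else GraspType.NONE
        )
        segs.append(
            PrimitiveSegment(label=label, onset_ms=t, offset_ms=t + n_ms, grasp=grasp)
        )
        t += n_ms
    return LabelSequence(segments=segs, span_ms=t)


def generate_cohort(
    n_subjects_per_group: int,
    trials_per_subject: int,
    mild: Optional[SimulationConfig] = None,
    moderate: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> List[SessionRecording]:
    """Two-group cohort with per-subject random density effects.

    Each subject's density is the group preset times a small lognormal
    perturbation (sd 5%), the random-intercept structure the group
    comparison model expects. Returns one session per subject x trial.
    """
    import warnings as _warnings

    if n_subjects_per_group < 2:
        _warnings.warn("fewer than 2 subjects per group: compare_groups will refuse")
    mild = mild or mild_config()
    moderate = moderate or moderate_config()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sessions: List[SessionRecording] = []
    for gi, (tag, cfg, group) in enumerate(
        [("M", mild, ImpairmentGroup.MILD), ("X", moderate, ImpairmentGroup.MODERATE)]
    ):
        fma_range = (53, 64) if group is ImpairmentGroup.MILD else (33, 49)
        for s in range(n_subjects_per_group):
            subject = f"{tag}{s + 1:02d}"
            subj_density = cfg.density_per_s * float(np.exp(rng.normal(0.0, 0.05)))
            fma = int(rng.integers(*fma_range))
            for tr in range(trials_per_subject):
                child_seed = int(rng.integers(2**31))
                scfg = replace(cfg, seed=child_seed, density_per_s=subj_density, group=group)
                rec = generate_session(
                    scfg, subject_id=subject, activity="synthetic_adl", trial=tr
                )
                rec.fma_score = fma
                sessions.append(rec)
    return sessions
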