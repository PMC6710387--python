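"""Domain types for the functional upper-extremity motion taxonomy.

Conventions
-----------
* Time is integer milliseconds; labeled intervals are half-open
  ``[onset_ms, offset_ms)`` so adjacent segments share a boundary without
  overlapping.
* Joint angles are degrees; the hand endpoint is centimeters in a
  pelvis-centered body frame (x forward, y left, z up).
* The default sampling rate is 100 Hz (10 ms frame period).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import AlignmentError, DataError, SamplingError, SequenceError

#: Canonical joint-angle column order shared by every module.
ANGLE_NAMES = (
    "trunk_flexion",
    "shoulder_flexion",
    "shoulder_abduction",
    "elbow_flexion",
    "forearm_supination",
    "wrist_extension",
)

#: Endpoint coordinate order.
ENDPOINT_NAMES = ("hand_x", "hand_y", "hand_z")

DEFAULT_RATE_HZ = 100.0


class PrimitiveLabel(str, Enum):
    """The five functional primitives, plus a reserved fallback.

    NONCLASSIFIABLE is reserved for frames failing every rule; the nominal
    taxonomy rules never emit it.
    """

    REACH = "REACH"
    REPOSITION = "REPOSITION"
    TRANSPORT = "TRANSPORT"
    STABILIZE = "STABILIZE"
    IDLE = "IDLE"
    NONCLASSIFIABLE = "NONCLASSIFIABLE"


#: Labels that entail UE translation.
MOTION_LABELS = frozenset(
    {PrimitiveLabel.REACH, PrimitiveLabel.REPOSITION, PrimitiveLabel.TRANSPORT}
)
#: Labels that entail minimal-motion.
MINIMAL_LABELS = frozenset({PrimitiveLabel.STABILIZE, PrimitiveLabel.IDLE})
#: Labels that carry a grasp on the target object.
GRASP_LABELS = frozenset({PrimitiveLabel.TRANSPORT, PrimitiveLabel.STABILIZE})
#: The five real primitives in canonical order.
PRIMITIVE_ORDER = (
    PrimitiveLabel.REACH,
    PrimitiveLabel.REPOSITION,
    PrimitiveLabel.TRANSPORT,
    PrimitiveLabel.STABILIZE,
    PrimitiveLabel.IDLE,
)


class Cyclicity(str, Enum):
    DISCRETE = "DISCRETE"
    RHYTHMIC = "RHYTHMIC"


class Effector(str, Enum):
    """Upper-body segment chiefly translating the UE."""

    DISTAL = "DISTAL"
    PROXIMAL = "PROXIMAL"
    AXIAL = "AXIAL"
    PROXIMAL_DISTAL = "PROXIMAL_DISTAL"
    AXIAL_PROXIMAL = "AXIAL_PROXIMAL"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class GraspType(str, Enum):
    PREHENSILE = "PREHENSILE"
    NON_PREHENSILE = "NON_PREHENSILE"
    NONE = "NONE"


class ContactState(str, Enum):
    """Per-frame contact channel state.

    PREHENSILE: >=2 self-generated opposing contact forces secure the object.
    NON_PREHENSILE: one generated force opposed by an external force
    (gravity, a surface, the other limb).
    TOUCH: surface contact without a securing grasp.
    """

    NONE = "NONE"
    TOUCH = "TOUCH"
    PREHENSILE = "PREHENSILE"
    NON_PREHENSILE = "NON_PREHENSILE"


class ImpairmentGroup(str, Enum):
    MILD = "MILD"
    MODERATE = "MODERATE"
    CONTROL = "CONTROL"


class IntentKind(str, Enum):
    OBJECT_DROPPED = "OBJECT_DROPPED"
    TARGET_AIMED_MISSED = "TARGET_AIMED_MISSED"


@dataclass(frozen=True)
class IntentEvent:
    t_ms: int
    kind: IntentKind


@dataclass
class KinematicSeries:
    """Uniformly sampled joint angles plus pelvis-frame hand position.

    Parameters
    ----------
    t : (n,) int64 array
        Frame timestamps in milliseconds, strictly increasing, uniform.
    angles : (n, 6) float array
        Joint angles in degrees, columns ordered as :data:`ANGLE_NAMES`.
    endpoint : (n, 3) float array
        Hand position in centimeters, pelvis frame.
    """

    t: np.ndarray
    angles: np.ndarray
    endpoint: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.angles = np.asarray(self.angles, dtype=float)
        self.endpoint = np.asarray(self.endpoint, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n = len(self.t)
        if self.angles.shape != (n, len(ANGLE_NAMES)):
            raise DataError(
                f"angles shape {self.angles.shape} does not match "
                f"({n}, {len(ANGLE_NAMES)})"
            )
        if self.endpoint.shape != (n, 3):
            raise DataError(f"endpoint shape {self.endpoint.shape} != ({n}, 3)")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise SamplingError(f"timestamps not strictly increasing at frame {bad}")
            if np.any(dt != dt[0]):
                bad = int(np.argmax(dt != dt[0])) + 1
                raise SamplingError(
                    f"non-uniform sampling at frame {bad}: interval "
                    f"{int(dt[bad - 1])} ms != {int(dt[0])} ms"
                )
        if not np.all(np.isfinite(self.angles)):
            frame = int(np.argwhere(~np.isfinite(self.angles))[0, 0])
            raise DataError(f"non-finite angle value at frame {frame}")
        if not np.all(np.isfinite(self.endpoint)):
            frame = int(np.argwhere(~np.isfinite(self.endpoint))[0, 0])
            raise DataError(f"non-finite endpoint value at frame {frame}")

    # -- conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.t)

    @property
    def frame_ms(self) -> int:
        """Frame period in milliseconds (10 at 100 Hz)."""
        if len(self.t) < 2:
            return int(round(1000.0 / DEFAULT_RATE_HZ))
        return int(self.t[1] - self.t[0])

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.frame_ms

    @property
    def span_ms(self) -> int:
        """Recording extent: last timestamp plus one frame period."""
        if len(self.t) == 0:
            return 0
        return int(self.t[-1]) + self.frame_ms

    def angle(self, name: str) -> np.ndarray:
        return self.angles[:, ANGLE_NAMES.index(name)]

    def index_of(self, t_ms: int) -> int:
        """Frame index containing time ``t_ms`` (half-open frames)."""
        return int((t_ms - int(self.t[0])) // self.frame_ms)


@dataclass
class ContactSeries:
    """Per-frame contact state aligned to a :class:`KinematicSeries`."""

    t: np.ndarray
    state: np.ndarray  # array of ContactState values (unicode)
    is_target: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.state = np.asarray(self.state, dtype="U14")
        self.is_target = np.asarray(self.is_target, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if not (len(self.t) == len(self.state) == len(self.is_target)):
            raise DataError("contact arrays have mismatched lengths")
        valid = {s.value for s in ContactState}
        bad = set(np.unique(self.state)) - valid
        if bad:
            raise DataError(f"unknown contact state(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def target_contact(self) -> np.ndarray:
        """Frames with any contact on the target of engagement."""
        return (self.state != ContactState.NONE.value) & self.is_target

    def check_aligned(self, kin: KinematicSeries) -> None:
        if len(self.t) != len(kin.t) or not np.array_equal(self.t, kin.t):
            raise AlignmentError("contact series not aligned with kinematics")


@dataclass
class PrimitiveSegment:
    """A labeled half-open interval ``[onset_ms, offset_ms)``."""

    label: PrimitiveLabel
    onset_ms: int
    offset_ms: int
    cyclicity: Cyclicity = Cyclicity.DISCRETE
    bout_id: Optional[int] = None
    effector: Effector = Effector.NOT_APPLICABLE
    grasp: GraspType = GraspType.NONE
    incomplete: bool = False

    def __post_init__(self) -> None:
        self.onset_ms = int(self.onset_ms)
        self.offset_ms = int(self.offset_ms)
        if self.offset_ms <= self.onset_ms:
            raise SequenceError(
                f"segment {self.label.value} [{self.onset_ms}, {self.offset_ms}) "
                "has offset <= onset"
            )
        if self.label in GRASP_LABELS and self.grasp is GraspType.NONE:
            raise SequenceError(
                f"{self.label.value} segment requires a grasp type, got NONE"
            )
        if self.label in {PrimitiveLabel.REPOSITION, PrimitiveLabel.IDLE} and (
            self.grasp is not GraspType.NONE
        ):
            raise SequenceError(f"{self.label.value} segment must carry grasp NONE")

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms

    def replace(self, **kw) -> "PrimitiveSegment":
        return replace(self, **kw)


@dataclass
class LabelSequence:
    """Ordered, non-overlapping primitive segments over ``[0, span_ms)``.

    Gaps between segments are legal and mean "not functional motion"
    (rest, gestures, out-of-taxonomy stretches).
    """

    segments: list = field(default_factory=list)
    span_ms: int = 0

    def __post_init__(self) -> None:
        self.span_ms = int(self.span_ms)
        self.validate()

    def validate(self) -> None:
        prev = None
        for seg in self.segments:
            if not isinstance(seg, PrimitiveSegment):
                raise SequenceError("segments must be PrimitiveSegment instances")
            if seg.onset_ms < 0 or seg.offset_ms > self.span_ms:
                raise SequenceError(
                    f"segment [{seg.onset_ms}, {seg.offset_ms}) outside "
                    f"recording span [0, {self.span_ms})"
                )
            if prev is not None:
                if seg.onset_ms < prev.onset_ms:
                    raise SequenceError("segments not sorted by onset")
                if seg.onset_ms < prev.offset_ms:
                    raise SequenceError(
                        f"segments overlap: [{prev.onset_ms}, {prev.offset_ms}) "
                        f"and [{seg.onset_ms}, {seg.offset_ms})"
                    )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelSequence):
            return NotImplemented
        return self.span_ms == other.span_ms and self.segments == other.segments

    def onsets(self) -> np.ndarray:
        return np.array([s.onset_ms for s in self.segments], dtype=np.int64)

    def segment_at(self, t_ms: int) -> Optional[PrimitiveSegment]:
        """Segment containing ``t_ms``, or None if in a gap."""
        for seg in self.segments:
            if seg.onset_ms <= t_ms < seg.offset_ms:
                return seg
        return None

    def labeled_ms(self) -> int:
        return sum(s.duration_ms for s in self.segments)


@dataclass
class SessionRecording:
    """A recorded (or simulated) ADL session with metadata."""

    subject_id: str
    activity: str
    trial: int
    impairment_group: ImpairmentGroup
    kinematics: KinematicSeries
    contact: ContactSeries
    fma_score: Optional[int] = None
    intent_events: list = field(default_factory=list)
    truth: Optional[LabelSequence] = None

    def __post_init__(self) -> None:
        self.contact.check_aligned(self.kinematics)
        if self.fma_score is not None and not (0 <= self.fma_score <= 66):
            raise DataError(f"FMA score {self.fma_score} outside 0-66")
        span = self.kinematics.span_ms
        for ev in self.intent_events:
            if not (0 <= ev.t_ms < span):
                raise DataError(f"intent event at {ev.t_ms} ms outside recording span")


@dataclass
class EngineParams:
    """Tunable thresholds of the taxonomy engine.

    min_still_ms : dwell required for minimal-motion (default 50 ms).
    speed_thresh_cm_s : endpoint speed below which the UE counts as
        "largely unchanged" (default 2.0 cm/s; the dwell is prescribed by
        the taxonomy, the speed magnitude is a package convention and must
        stay configurable).
    transition_window_ms : agreement tolerance around expert transitions.
    direction_split_deg : velocity-direction change splitting a transport.
    bout_gap_factor : pause multiplier terminating a rhythmic bout.
    amp_tol_frac : cycle-amplitude similarity tolerance within a bout.
    dominance_frac : single-effector dominance threshold.
    smooth_ms : moving-average width for velocity smoothing (0 = raw).
    """

    min_still_ms: float = 50.0
    speed_thresh_cm_s: float = 2.0
    transition_window_ms: float = 20.0
    direction_split_deg: float = 90.0
    bout_gap_factor: float = 2.0
    amp_tol_frac: float = 0.25
    dominance_frac: float = 0.66
    smooth_ms: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "min_still_ms",
            "speed_thresh_cm_s",
            "transition_window_ms",
            "direction_split_deg",
            "bout_gap_factor",
            "amp_tol_frac",
            "dominance_frac",
        ):
            if getattr(self, name) <= 0:
                raise DataError(f"EngineParams.{name} must be positive")
        if self.smooth_ms < 0:
            raise DataError("EngineParams.smooth_ms must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "EngineParams":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
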