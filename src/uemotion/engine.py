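"""The mechanized taxonomy: from kinematics + contact to primitive segments.

The classification cascade mirrors the taxonomy hierarchy:

1. *Presence of motion* — endpoint speed in the pelvis frame is thresholded
   (``speed_thresh_cm_s``) and sub-threshold runs shorter than
   ``min_still_ms`` are absorbed into motion, so subtle drift of a limb
   held aloft never fragments a motion run, while any dwell of at least
   the minimum stillness duration becomes minimal-motion.
2. *Contact type* — per-frame target contact (grasp or touch of the target
   of engagement) splits motion into conveyance vs. free motion and
   minimal-motion into stabilization vs. idling. Contact with non-target
   objects is ignored.
3. *Merge* — contiguous runs of identical frame labels become segments.
   A free-motion run that terminates where stable target contact begins is
   a reach (ending at contact completion); one ending in stillness or at
   the recording end is a reposition. A conveyance run is split into
   consecutive transports wherever the smoothed velocity direction turns
   by more than ``direction_split_deg`` across a local speed minimum
   (a new direction of motion with the object in hand).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .characteristics import classify_grasp_type
from .errors import AlignmentError, InsufficientDataError
from .types import (
    ContactSeries,
    EngineParams,
    GraspType,
    IntentEvent,
    IntentKind,
    KinematicSeries,
    LabelSequence,
    PrimitiveLabel,
    PrimitiveSegment,
)

# internal frame codes
_MOVE, _TRANSPORT, _STABILIZE, _IDLE = 0, 1, 2, 3


@dataclass
class DisplacementSeries:
    """Per-frame endpoint speed and (smoothed) velocity direction."""

    speed: np.ndarray  # (n,) cm/s, >= 0
    direction: np.ndarray  # (n, 3) unit vectors where defined
    has_direction: np.ndarray  # (n,) bool, False where speed == 0
    frame_ms: int


class MotionState:
    """Per-frame motion presence flags."""

    MOTION = "MOTION"
    MINIMAL = "MINIMAL"


def compute_displacement(kin: KinematicSeries, smooth_ms: float = 0.0) -> DisplacementSeries:
    """Central-difference endpoint speed, optionally smoothed.

    The first and last frames use one-sided differences. Direction is the
    unit velocity vector, flagged undefined where the speed is zero.
    """
    if len(kin) < 2:
        raise InsufficientDataError("need at least 2 frames to compute displacement")
    dt_s = kin.frame_ms / 1000.0
    vel = np.gradient(kin.endpoint, dt_s, axis=0)  # cm/s
    if smooth_ms > 0:
        width = max(int(round(smooth_ms / kin.frame_ms)), 1)
        if width > 1:
            vel = uniform_filter1d(vel, size=width, axis=0, mode="nearest")
    speed = np.linalg.norm(vel, axis=1)
    has_dir = speed > 0
    direction = np.zeros_like(vel)
    direction[has_dir] = vel[has_dir] / speed[has_dir, None]
    return DisplacementSeries(
        speed=speed, direction=direction, has_direction=has_dir, frame_ms=kin.frame_ms
    )


def detect_motion_state(disp: DisplacementSeries, params: EngineParams) -> np.ndarray:
    """Per-frame MOTION/MINIMAL boolean array (True = MINIMAL).

    A frame is MINIMAL iff it lies in a maximal run of sub-threshold
    frames lasting at least ``min_still_ms``; shorter sub-threshold runs
    are absorbed into MOTION (drift tolerance).
    """
    if params.min_still_ms < disp.frame_ms:
        raise InsufficientDataError(
            f"min_still_ms ({params.min_still_ms}) below one frame period "
            f"({disp.frame_ms} ms)"
        )
    below = disp.speed < params.speed_thresh_cm_s
    minimal = np.zeros_like(below)
    min_frames = int(np.ceil(params.min_still_ms / disp.frame_ms))
    for start, stop in _runs(below):
        if stop - start >= min_frames:
            minimal[start:stop] = True
    return minimal


def classify_frame(minimal: bool, target_contact: bool) -> PrimitiveLabel:
    """Frame-wise taxonomy rule.

    Motion with target contact is conveyance (transport); motion without
    is a reach-or-reposition candidate disambiguated at merge time and
    reported here as REPOSITION. Minimal-motion splits into stabilize
    (target contact) vs idle. Non-target contact counts as no contact.
    """
    if minimal:
        return PrimitiveLabel.STABILIZE if target_contact else PrimitiveLabel.IDLE
    return PrimitiveLabel.TRANSPORT if target_contact else PrimitiveLabel.REPOSITION


def _runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i in range(0, len(edges), 2):
        yield int(edges[i]), int(edges[i + 1])


def _code_runs(codes: np.ndarray):
    """Yield (start, stop, code) of maximal equal-code runs."""
    change = np.flatnonzero(np.diff(codes)) + 1
    bounds = np.concatenate(([0], change, [len(codes)]))
    for i in range(len(bounds) - 1):
        yield int(bounds[i]), int(bounds[i + 1]), int(codes[bounds[i]])


def _stable_contact(target: np.ndarray, min_frames: int = 2) -> np.ndarray:
    """Debounced target contact: runs shorter than ``min_frames`` dropped.

    Realizes "contact completed" as the first frame of a stable
    (>= 2 consecutive frames) grasp/touch state.
    """
    out = target.copy()
    for start, stop in _runs(target):
        if stop - start < min_frames:
            out[start:stop] = False
    return out


def _split_transport_run(
    start: int, stop: int, disp: DisplacementSeries, params: EngineParams
) -> List[int]:
    """Interior split indices where a transport changes direction.

    A split is placed at a local speed minimum across which the smoothed
    velocity direction turns by more than ``direction_split_deg``.
    """
    n = stop - start
    if n < 5:
        return []
    window = max(int(round(50.0 / disp.frame_ms)), 2)
    vel = disp.direction * disp.speed[:, None]
    speed = disp.speed
    cos_thresh = np.cos(np.deg2rad(params.direction_split_deg))
    candidates: List[int] = []
    for j in range(start + 2, stop - 2):
        pre = vel[max(start, j - window) : j].sum(axis=0)
        post = vel[j + 1 : min(stop, j + 1 + window)].sum(axis=0)
        npre, npost = np.linalg.norm(pre), np.linalg.norm(post)
        if npre > 0 and npost > 0 and float(pre @ post) / (npre * npost) < cos_thresh:
            candidates.append(j)
    # one turn produces a cluster of adjacent candidate frames; the split
    # goes at the local speed minimum of each cluster
    splits: List[int] = []
    cluster: List[int] = []
    for j in candidates + [stop + window + 1]:
        if cluster and j - cluster[-1] > 2:
            splits.append(int(cluster[int(np.argmin(speed[cluster]))]))
            cluster = []
        if j <= stop:
            cluster.append(j)
    return splits


def segment_primitives(
    kin: KinematicSeries, contact: ContactSeries, params: Optional[EngineParams] = None
) -> LabelSequence:
    """Segment a recording into labeled functional primitives.

    Returns a sorted, non-overlapping :class:`LabelSequence` covering every
    frame. Grasp fields summarize the modal target contact state per
    grasp-bearing segment; cyclicity/effector annotation is done separately
    by :mod:`uemotion.characteristics`.
    """
    params = params or EngineParams()
    contact.check_aligned(kin)
    disp = compute_displacement(kin, smooth_ms=params.smooth_ms)
    minimal = detect_motion_state(disp, params)
    target = _stable_contact(contact.target_contact)

    codes = np.where(
        minimal,
        np.where(target, _STABILIZE, _IDLE),
        np.where(target, _TRANSPORT, _MOVE),
    )
    dt = kin.frame_ms
    t0 = int(kin.t[0]) if len(kin) else 0
    runs = list(_code_runs(codes))
    segments: List[PrimitiveSegment] = []
    for ri, (start, stop, code) in enumerate(runs):
        onset, offset = t0 + start * dt, t0 + stop * dt
        if code == _MOVE:
            nxt = runs[ri + 1][2] if ri + 1 < len(runs) else None
            if nxt in (_TRANSPORT, _STABILIZE):
                label = PrimitiveLabel.REACH
            else:
                label = PrimitiveLabel.REPOSITION
            segments.append(PrimitiveSegment(label=label, onset_ms=onset, offset_ms=offset))
        elif code == _TRANSPORT:
            cuts = [start] + _split_transport_run(start, stop, disp, params) + [stop]
            for a, b in zip(cuts[:-1], cuts[1:]):
                seg = PrimitiveSegment(
                    label=PrimitiveLabel.TRANSPORT,
                    onset_ms=t0 + a * dt,
                    offset_ms=t0 + b * dt,
                    grasp=GraspType.PREHENSILE,  # placeholder, refined below
                )
                seg.grasp = classify_grasp_type(contact, seg)
                segments.append(seg)
        else:
            label = PrimitiveLabel.STABILIZE if code == _STABILIZE else PrimitiveLabel.IDLE
            if code == _STABILIZE:
                seg = PrimitiveSegment(
                    label=label, onset_ms=onset, offset_ms=offset,
                    grasp=GraspType.PREHENSILE,
                )
                seg.grasp = classify_grasp_type(contact, seg)
            else:
                seg = PrimitiveSegment(label=label, onset_ms=onset, offset_ms=offset)
            segments.append(seg)
    return LabelSequence(segments=segments, span_ms=kin.span_ms)


def flag_incomplete(
    seq: LabelSequence, intent_events: Sequence[IntentEvent]
) -> LabelSequence:
    """Apply observer intent cues to mark incomplete primitive variants.

    * OBJECT_DROPPED inside a transport/stabilize marks it incomplete.
    * TARGET_AIMED_MISSED inside a reposition relabels it as an incomplete
      reach (the motion aimed at a target it never contacted).

    Events falling outside any segment, or inside a segment of another
    type, are ignored with a warning.
    """
    new_segments = list(seq.segments)
    for ev in intent_events:
        idx = next(
            (
                i
                for i, s in enumerate(new_segments)
                if s.onset_ms <= ev.t_ms < s.offset_ms
            ),
            None,
        )
        if idx is None:
            warnings.warn(f"intent event at {ev.t_ms} ms falls outside any segment; ignored")
            continue
        seg = new_segments[idx]
        if ev.kind is IntentKind.OBJECT_DROPPED and seg.label in (
            PrimitiveLabel.TRANSPORT,
            PrimitiveLabel.STABILIZE,
        ):
            new_segments[idx] = seg.replace(incomplete=True)
        elif (
            ev.kind is IntentKind.TARGET_AIMED_MISSED
            and seg.label is PrimitiveLabel.REPOSITION
        ):
            new_segments[idx] = seg.replace(label=PrimitiveLabel.REACH, incomplete=True)
        else:
            warnings.warn(
                f"intent event {ev.kind.value} at {ev.t_ms} ms does not apply to a "
                f"{seg.label.value} segment; ignored"
            )
    return LabelSequence(segments=new_segments, span_ms=seq.span_ms)
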