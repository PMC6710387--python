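"""Segment-level motion characteristics: cyclicity, effector segment, grasp.

These annotations sit one level above primitive identity in the taxonomy:
every motion segment is discrete or belongs to a rhythmic bout, is chiefly
translated by one upper-body segment (or two adjacent ones), and — if it
bears a grasp — holds the object prehensilely or non-prehensilely.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import body
from .errors import ContractError
from .types import (
    ContactSeries,
    ContactState,
    Cyclicity,
    Effector,
    EngineParams,
    GraspType,
    KinematicSeries,
    LabelSequence,
    MOTION_LABELS,
    PrimitiveLabel,
    PrimitiveSegment,
)


@dataclass
class EffectorContribution:
    """Endpoint displacement (cm) attributable to each joint group."""

    axial: float
    proximal: float
    distal: float

    @property
    def total(self) -> float:
        return self.axial + self.proximal + self.distal

    def shares(self) -> dict:
        t = self.total
        if t == 0:
            return {"axial": 0.0, "proximal": 0.0, "distal": 0.0}
        return {"axial": self.axial / t, "proximal": self.proximal / t, "distal": self.distal / t}


def _frame_slice(kin: KinematicSeries, segment: PrimitiveSegment) -> Tuple[int, int]:
    a = kin.index_of(segment.onset_ms)
    b = kin.index_of(segment.offset_ms - 1) + 1
    return max(a, 0), min(b, len(kin))


def effector_contributions(
    kin: KinematicSeries, segment: PrimitiveSegment
) -> EffectorContribution:
    """Sum per-frame group displacements over the segment's frames.

    Only frame pairs fully inside the segment contribute, so posture steps
    at segment boundaries are never attributed to either neighbor.
    """
    a, b = _frame_slice(kin, segment)
    disp = body.group_frame_displacements(kin.angles[a:b])
    return EffectorContribution(
        axial=float(disp["axial"].sum()),
        proximal=float(disp["proximal"].sum()),
        distal=float(disp["distal"].sum()),
    )


def attribute_effector_segment(
    kin: KinematicSeries,
    segment: PrimitiveSegment,
    params: Optional[EngineParams] = None,
) -> Effector:
    """Dominant upper-body segment translating the UE during a motion segment.

    If one group's displacement share reaches ``dominance_frac`` it is
    returned alone (this also subsumes small distal adjustments that orient
    the hand during a proximal motion); otherwise the adjacent pair holding
    the two largest shares is returned. Minimal-motion segments are
    NOT_APPLICABLE by definition.
    """
    params = params or EngineParams()
    if segment.label not in MOTION_LABELS:
        return Effector.NOT_APPLICABLE
    contrib = effector_contributions(kin, segment)
    if contrib.total == 0:
        return Effector.NOT_APPLICABLE
    shares = contrib.shares()
    top = max(shares, key=shares.get)
    if shares[top] >= params.dominance_frac:
        return {"axial": Effector.AXIAL, "proximal": Effector.PROXIMAL, "distal": Effector.DISTAL}[top]
    ranked = sorted(shares, key=shares.get, reverse=True)
    pair = frozenset(ranked[:2])
    if pair == frozenset(("axial", "proximal")):
        return Effector.AXIAL_PROXIMAL
    if pair == frozenset(("proximal", "distal")):
        return Effector.PROXIMAL_DISTAL
    # top two are the non-adjacent axial/distal pair: fall back to the
    # adjacent pair with the larger combined share
    if shares["axial"] + shares["proximal"] >= shares["proximal"] + shares["distal"]:
        return Effector.AXIAL_PROXIMAL
    return Effector.PROXIMAL_DISTAL


def classify_grasp_type(contact: ContactSeries, segment: PrimitiveSegment) -> GraspType:
    """Modal target contact state of a grasp-bearing segment.

    Target TOUCH counts as non-prehensile (one generated force opposed by
    the surface, as when sweeping or supporting). Ties break toward
    PREHENSILE.
    """
    if segment.label not in (PrimitiveLabel.TRANSPORT, PrimitiveLabel.STABILIZE):
        raise ContractError(
            f"grasp type applies to TRANSPORT/STABILIZE, not {segment.label.value}"
        )
    dt = int(contact.t[1] - contact.t[0]) if len(contact) > 1 else 10
    t0 = int(contact.t[0]) if len(contact) else 0
    a = max((segment.onset_ms - t0) // dt, 0)
    b = min((segment.offset_ms - 1 - t0) // dt + 1, len(contact))
    states = contact.state[a:b]
    tgt = contact.is_target[a:b]
    n_preh = int(np.sum(tgt & (states == ContactState.PREHENSILE.value)))
    n_non = int(
        np.sum(
            tgt
            & (
                (states == ContactState.NON_PREHENSILE.value)
                | (states == ContactState.TOUCH.value)
            )
        )
    )
    return GraspType.PREHENSILE if n_preh >= n_non else GraspType.NON_PREHENSILE


def _net_displacement(kin: KinematicSeries, segment: PrimitiveSegment) -> np.ndarray:
    a, b = _frame_slice(kin, segment)
    b = min(b, len(kin) - 1)
    return kin.endpoint[b] - kin.endpoint[a]


def _is_alternating(v1: np.ndarray, v2: np.ndarray, params: EngineParams) -> bool:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return False
    cosang = float(v1 @ v2) / (n1 * n2)
    return cosang < np.cos(np.deg2rad(params.direction_split_deg))


def _amp_similar(a1: float, a2: float, params: EngineParams) -> bool:
    ref = max(a1, 1e-9)
    return abs(a2 - a1) <= params.amp_tol_frac * ref


def detect_rhythmic_bouts(
    seq: LabelSequence, kin: KinematicSeries, params: Optional[EngineParams] = None
) -> LabelSequence:
    """Mark rhythmic bouts: runs of >=2 repeated motion cycles on one target.

    A cycle unit is an adjacent transport+transport pair of alternating
    direction (e.g. brushing strokes) or an adjacent reach+transport pair
    (e.g. repeatedly regrasping and turning a cap). Transport-transport
    pairing takes priority so a reach leading into an alternating stroke
    run cannot steal the run's first transport. Consecutive units chain
    into one bout while their amplitudes agree within ``amp_tol_frac`` and
    inter-unit pauses stay below ``bout_gap_factor`` times the median
    intra-bout pause. All remaining motion segments are discrete;
    minimal-motion segments are untouched.
    """
    params = params or EngineParams()
    segs = [s.replace() for s in seq.segments]
    n = len(segs)
    amp = [
        float(np.linalg.norm(_net_displacement(kin, s))) if s.label in MOTION_LABELS else 0.0
        for s in segs
    ]
    vec = [
        _net_displacement(kin, s) if s.label in MOTION_LABELS else np.zeros(3)
        for s in segs
    ]

    def _adjacent(i: int) -> bool:
        return segs[i + 1].onset_ms == segs[i].offset_ms

    # enumerate candidate cycle units greedily, transport-transport first
    units: List[Tuple[int, int, float]] = []  # (first_idx, last_idx, amplitude)
    i = 0
    while i < n - 1:
        a, b = segs[i], segs[i + 1]
        tt = (
            a.label is PrimitiveLabel.TRANSPORT
            and b.label is PrimitiveLabel.TRANSPORT
            and _adjacent(i)
            and _is_alternating(vec[i], vec[i + 1], params)
            and _amp_similar(amp[i], amp[i + 1], params)
        )
        rt = (
            a.label is PrimitiveLabel.REACH
            and b.label is PrimitiveLabel.TRANSPORT
            and _adjacent(i)
            and not (
                i + 2 < n
                and segs[i + 2].label is PrimitiveLabel.TRANSPORT
                and _adjacent(i + 1)
                and _is_alternating(vec[i + 1], vec[i + 2], params)
            )
        )
        if tt or rt:
            units.append((i, i + 1, 0.5 * (amp[i] + amp[i + 1])))
            i += 2
        else:
            i += 1

    # chain consecutive, similar-amplitude units into bouts
    bout_id = 0
    mark: dict = {}
    k = 0
    while k < len(units):
        chain = [units[k]]
        gaps: List[int] = []
        while k + len(chain) < len(units):
            prev, nxt = chain[-1], units[k + len(chain)]
            if nxt[0] != prev[1] + 1:
                break
            gap = segs[nxt[0]].onset_ms - segs[prev[1]].offset_ms
            if not _amp_similar(prev[2], nxt[2], params):
                break
            # cycles repeat on a fixed target: the leading strokes of
            # consecutive units must share a direction
            if _is_alternating(vec[prev[0]], vec[nxt[0]], params):
                break
            if gaps and np.median(gaps) > 0 and gap >= params.bout_gap_factor * np.median(gaps):
                break
            chain.append(nxt)
            gaps.append(gap)
        if len(chain) >= 2:
            bout_id += 1
            for u in chain:
                for idx in range(u[0], u[1] + 1):
                    mark[idx] = bout_id
        k += len(chain)

    out = []
    for idx, seg in enumerate(segs):
        if idx in mark:
            out.append(seg.replace(cyclicity=Cyclicity.RHYTHMIC, bout_id=mark[idx]))
        elif seg.label in MOTION_LABELS:
            out.append(seg.replace(cyclicity=Cyclicity.DISCRETE, bout_id=None))
        else:
            out.append(seg)
    return LabelSequence(segments=out, span_ms=seq.span_ms)


def characterize(
    seq: LabelSequence,
    kin: KinematicSeries,
    contact: ContactSeries,
    params: Optional[EngineParams] = None,
) -> LabelSequence:
    """Annotate a segmented sequence with cyclicity, effector, and grasp."""
    params = params or EngineParams()
    seq = detect_rhythmic_bouts(seq, kin, params)
    out = []
    for seg in seq.segments:
        eff = attribute_effector_segment(kin, seg, params)
        grasp = seg.grasp
        if seg.label in (PrimitiveLabel.TRANSPORT, PrimitiveLabel.STABILIZE):
            grasp = classify_grasp_type(contact, seg)
        out.append(seg.replace(effector=eff, grasp=grasp))
    return LabelSequence(segments=out, span_ms=seq.span_ms)
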