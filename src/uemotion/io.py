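"""Readers and writers for the kinematics CSV and annotation TSV formats.

Kinematics CSV columns (exact order)::

    t_ms, trunk_flexion_deg, shoulder_flexion_deg, shoulder_abduction_deg,
    elbow_flexion_deg, forearm_supination_deg, wrist_extension_deg,
    hand_x_cm, hand_y_cm, hand_z_cm, contact_state, contact_is_target

Annotation TSV columns::

    subject, activity, trial, label, onset_ms, offset_ms, cyclicity,
    bout_id, effector, grasp, incomplete

Both dialects are fixed (UTF-8, '.' decimal separator, mandatory header;
comma vs tab separation) so round-trips are bit-exact.

This tab-separated annotation layout is a convention of this package, not
the format used by any particular annotation study.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError, SequenceError
from .types import (
    ANGLE_NAMES,
    ContactSeries,
    ContactState,
    Cyclicity,
    Effector,
    GraspType,
    KinematicSeries,
    LabelSequence,
    PrimitiveLabel,
    PrimitiveSegment,
)

KINEMATICS_COLUMNS = (
    "t_ms",
    *(f"{name}_deg" for name in ANGLE_NAMES),
    "hand_x_cm",
    "hand_y_cm",
    "hand_z_cm",
    "contact_state",
    "contact_is_target",
)

ANNOTATION_COLUMNS = (
    "subject",
    "activity",
    "trial",
    "label",
    "onset_ms",
    "offset_ms",
    "cyclicity",
    "bout_id",
    "effector",
    "grasp",
    "incomplete",
)


def read_kinematics(
    path, expected_rate_hz: float = 100.0
) -> Tuple[KinematicSeries, ContactSeries]:
    """Read a kinematics CSV into aligned kinematic and contact series.

    Raises
    ------
    FormatError
        If a required column is missing.
    SamplingError
        If timestamps are not uniform at ``expected_rate_hz``.
    DataError
        If any value is non-finite (raised by series validation).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in KINEMATICS_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"kinematics file missing required column '{col}'")
    t = df["t_ms"].to_numpy(dtype=np.int64)
    expected_dt = int(round(1000.0 / expected_rate_hz))
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.nonzero(dt != expected_dt)[0]
        if bad.size:
            i = int(bad[0])
            raise SamplingError(
                f"expected {expected_dt} ms frames at {expected_rate_hz} Hz but "
                f"interval t[{i}]->t[{i + 1}] is {int(dt[i])} ms (frame {i + 1})"
            )
    angles = df[[f"{n}_deg" for n in ANGLE_NAMES]].to_numpy(dtype=float)
    endpoint = df[["hand_x_cm", "hand_y_cm", "hand_z_cm"]].to_numpy(dtype=float)
    kin = KinematicSeries(t=t, angles=angles, endpoint=endpoint)
    contact = ContactSeries(
        t=t,
        state=df["contact_state"].astype(str).to_numpy(),
        is_target=df["contact_is_target"].to_numpy(dtype=int).astype(bool),
    )
    return kin, contact


def write_kinematics(kin: KinematicSeries, contact: ContactSeries, path) -> None:
    """Write aligned kinematic and contact series to the CSV format."""
    kin.validate()
    contact.check_aligned(kin)
    df = pd.DataFrame({"t_ms": kin.t})
    for j, name in enumerate(ANGLE_NAMES):
        df[f"{name}_deg"] = kin.angles[:, j]
    for j, name in enumerate(("hand_x_cm", "hand_y_cm", "hand_z_cm")):
        df[name] = kin.endpoint[:, j]
    df["contact_state"] = contact.state
    df["contact_is_target"] = contact.is_target.astype(int)
    # repr-based float formatting keeps the round-trip bit-exact
    df.to_csv(path, index=False, float_format=None)


def _parse_enum(enum_cls, raw: str, what: str):
    try:
        return enum_cls(raw)
    except ValueError:
        raise FormatError(f"unknown {what} '{raw}'") from None


def read_annotations(path) -> LabelSequence:
    """Read an annotation TSV into a validated :class:`LabelSequence`.

    The recording span is taken as the largest offset (0 for an empty file).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"annotation file missing required column '{col}'")
    segments = []
    for _, row in df.iterrows():
        onset, offset = int(row["onset_ms"]), int(row["offset_ms"])
        if offset <= onset:
            raise SequenceError(
                f"segment {row['label']} [{onset}, {offset}) has offset <= onset"
            )
        bout = row["bout_id"]
        segments.append(
            PrimitiveSegment(
                label=_parse_enum(PrimitiveLabel, row["label"], "primitive label"),
                onset_ms=onset,
                offset_ms=offset,
                cyclicity=_parse_enum(Cyclicity, row["cyclicity"], "cyclicity"),
                bout_id=int(bout) if bout != "" else None,
                effector=_parse_enum(Effector, row["effector"], "effector"),
                grasp=_parse_enum(GraspType, row["grasp"], "grasp type"),
                incomplete=bool(int(row["incomplete"])),
            )
        )
    segments.sort(key=lambda s: s.onset_ms)
    span = max((s.offset_ms for s in segments), default=0)
    return LabelSequence(segments=segments, span_ms=span)


def write_annotations(
    seq: LabelSequence,
    path,
    subject: str = "NA",
    activity: str = "NA",
    trial: int = 0,
) -> None:
    """Write a label sequence to the TSV format.

    Refuses to write a sequence that violates ordering/overlap invariants.
    """
    seq.validate()
    rows = []
    for seg in seq.segments:
        rows.append(
            {
                "subject": subject,
                "activity": activity,
                "trial": trial,
                "label": seg.label.value,
                "onset_ms": seg.onset_ms,
                "offset_ms": seg.offset_ms,
                "cyclicity": seg.cyclicity.value,
                "bout_id": "" if seg.bout_id is None else seg.bout_id,
                "effector": seg.effector.value,
                "grasp": seg.grasp.value,
                "incomplete": int(seg.incomplete),
            }
        )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
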