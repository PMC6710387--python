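"""Shared fixtures: tiny hand-built series and seeded synthetic sessions."""
import numpy as np
import pytest

from uemotion import (
    ANGLE_NAMES,
    ContactSeries,
    ContactState,
    EngineParams,
    GraspType,
    KinematicSeries,
    LabelSequence,
    PrimitiveLabel,
    PrimitiveSegment,
    SimulationConfig,
    generate_session,
)

FRAME_MS = 10


def make_kinematics(endpoint, angles=None):
    """KinematicSeries from an (n, 3) endpoint array at 100 Hz."""
    endpoint = np.asarray(endpoint, dtype=float)
    n = len(endpoint)
    t = np.arange(n, dtype=np.int64) * FRAME_MS
    if angles is None:
        angles = np.zeros((n, len(ANGLE_NAMES)))
    return KinematicSeries(t=t, angles=angles, endpoint=endpoint)


def make_contact(n, state=ContactState.NONE, is_target=False, spans=None):
    """ContactSeries of length n; ``spans`` overrides per-range state.

    spans: list of (start_frame, stop_frame, ContactState, is_target).
    """
    t = np.arange(n, dtype=np.int64) * FRAME_MS
    states = np.full(n, state.value, dtype="U14")
    target = np.full(n, bool(is_target))
    for a, b, st, tg in spans or []:
        states[a:b] = st.value
        target[a:b] = tg
    return ContactSeries(t=t, state=states, is_target=target)


def seg(label, onset, offset, **kw):
    if label in (PrimitiveLabel.TRANSPORT, PrimitiveLabel.STABILIZE):
        kw.setdefault("grasp", GraspType.PREHENSILE)
    return PrimitiveSegment(label=label, onset_ms=onset, offset_ms=offset, **kw)


def random_sequence(rng, n_segments, seg_ms=500):
    """Contiguous sequence with uniformly random primitive labels."""
    labels = list(PrimitiveLabel)[:5]
    segs = []
    for i in range(n_segments):
        label = labels[int(rng.integers(5))]
        segs.append(seg(label, i * seg_ms, (i + 1) * seg_ms))
    return LabelSequence(segments=segs, span_ms=n_segments * seg_ms)


@pytest.fixture(scope="session")
def default_params():
    return EngineParams()


@pytest.fixture(scope="session")
def session_noise_free():
    """One deterministic noise-free synthetic session (60 s)."""
    return generate_session(SimulationConfig(seed=11))
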