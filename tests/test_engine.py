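"""Taxonomy engine: displacement, stillness detection, segmentation rules."""
import numpy as np
import pytest

from uemotion import (
    ContactState,
    EngineParams,
    GraspType,
    IntentEvent,
    IntentKind,
    LabelSequence,
    PrimitiveLabel,
    SimulationConfig,
    flag_incomplete,
    generate_session,
    segment_primitives,
)
from uemotion.engine import (
    classify_frame,
    compute_displacement,
    detect_motion_state,
)
from uemotion.errors import AlignmentError, InsufficientDataError

from conftest import make_contact, make_kinematics, seg


def assert_sorted_nonoverlapping(seq: LabelSequence):
    prev = None
    for s in seq.segments:
        if prev is not None:
            assert s.onset_ms >= prev.offset_ms
        prev = s


# ------------------------------------------------------------- displacement

def test_constant_endpoint_zero_speed():
    kin = make_kinematics(np.tile([10.0, 0.0, 5.0], (20, 1)))
    disp = compute_displacement(kin)
    assert np.all(disp.speed == 0)
    assert not disp.has_direction.any()


def test_uniform_advance_matches_finite_difference_oracle():
    # 1 cm per 10 ms frame along +x: an independent hand finite-difference
    # gives 100 cm/s everywhere, direction (1, 0, 0)
    endpoint = np.column_stack([np.arange(10, dtype=float), np.zeros(10), np.zeros(10)])
    disp = compute_displacement(make_kinematics(endpoint))
    np.testing.assert_allclose(disp.speed, 100.0)
    np.testing.assert_allclose(disp.direction, np.tile([1.0, 0, 0], (10, 1)))


def test_reversal_flips_direction_per_central_difference_oracle():
    # 5-frame out-and-back toy; oracle: central differences computed by hand
    x = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
    endpoint = np.column_stack([x, np.zeros(5), np.zeros(5)])
    disp = compute_displacement(make_kinematics(endpoint))
    dt = 0.01
    oracle_v = np.array(
        [
            (x[1] - x[0]) / dt,
            (x[2] - x[0]) / (2 * dt),
            (x[3] - x[1]) / (2 * dt),
            (x[4] - x[2]) / (2 * dt),
            (x[4] - x[3]) / dt,
        ]
    )
    np.testing.assert_allclose(disp.speed, np.abs(oracle_v))
    assert disp.direction[1, 0] == 1.0 and disp.direction[3, 0] == -1.0
    assert not disp.has_direction[2]  # apex frame: zero central difference


def test_too_short_series_rejected():
    with pytest.raises(InsufficientDataError):
        compute_displacement(make_kinematics(np.zeros((1, 3))))


# ------------------------------------------------------------- motion state

def _speed_profile_kinematics(speeds_cm_s):
    """Endpoint whose per-step displacement realizes the given speeds."""
    steps = np.asarray(speeds_cm_s) * 0.01
    x = np.concatenate([[0.0], np.cumsum(steps)])[:-1]
    return make_kinematics(np.column_stack([x, np.zeros_like(x), np.zeros_like(x)]))


def test_dwell_of_100ms_is_minimal(default_params):
    # 10 still frames (100 ms) bracketed by fast motion
    speeds = [50.0] * 10 + [0.0] * 10 + [50.0] * 10
    kin = _speed_profile_kinematics(speeds)
    disp = compute_displacement(kin)
    minimal = detect_motion_state(disp, default_params)
    assert minimal[12:17].all()  # interior of the still run
    assert not minimal[:9].any() and not minimal[-9:].any()


def test_40ms_dwell_absorbed_into_motion(default_params):
    # sub-threshold run of 4 frames (40 ms < 50 ms) stays MOTION throughout
    speeds = [50.0] * 10 + [0.0] * 4 + [50.0] * 10
    kin = _speed_profile_kinematics(speeds)
    disp = compute_displacement(kin)
    minimal = detect_motion_state(disp, default_params)
    assert not minimal.any()


def test_uniform_fast_motion_never_minimal(default_params):
    disp = compute_displacement(_speed_profile_kinematics([30.0] * 30))
    assert not detect_motion_state(disp, default_params).any()


# -------------------------------------------------------------- frame rule

@pytest.mark.parametrize(
    "minimal,target_contact,expected",
    [
        (True, True, PrimitiveLabel.STABILIZE),
        (True, False, PrimitiveLabel.IDLE),
        (False, True, PrimitiveLabel.TRANSPORT),
        (False, False, PrimitiveLabel.REPOSITION),
    ],
)
def test_frame_rule(minimal, target_contact, expected):
    assert classify_frame(minimal, target_contact) is expected


# ------------------------------------------------------------- segmentation

def test_reach_ends_at_contact_completion(default_params):
    # 50 motion frames, no contact, then grasp begins with motion continuing
    speeds = [30.0] * 100
    kin = _speed_profile_kinematics(speeds)
    contact = make_contact(
        100, spans=[(50, 100, ContactState.PREHENSILE, True)]
    )
    seq = segment_primitives(kin, contact, default_params)
    assert [s.label for s in seq.segments] == [
        PrimitiveLabel.REACH,
        PrimitiveLabel.TRANSPORT,
    ]
    assert seq[0].offset_ms == 500 and seq[1].onset_ms == 500
    assert seq[1].grasp is GraspType.PREHENSILE


def test_reposition_ends_at_stillness_onset(default_params):
    speeds = [30.0] * 50 + [0.0] * 20  # never contacts, 200 ms still tail
    kin = _speed_profile_kinematics(speeds)
    contact = make_contact(70)
    seq = segment_primitives(kin, contact, default_params)
    labels = [s.label for s in seq.segments]
    assert labels == [PrimitiveLabel.REPOSITION, PrimitiveLabel.IDLE]
    # central differencing blurs the boundary by at most one frame
    assert abs(seq[0].offset_ms - 500) <= 10


def test_nontarget_touch_is_idle(default_params):
    kin = _speed_profile_kinematics([0.0] * 30)
    contact = make_contact(30, state=ContactState.TOUCH, is_target=False)
    seq = segment_primitives(kin, contact, default_params)
    assert [s.label for s in seq.segments] == [PrimitiveLabel.IDLE]


def test_transport_split_on_direction_reversal(default_params):
    # out-and-back conveyance under sustained grasp: one motion run, two
    # transports split at the turn
    fwd = [30.0] * 40
    x = np.concatenate([np.cumsum(np.array(fwd) * 0.01), np.cumsum(np.array(fwd) * 0.01)[-1] - np.cumsum(np.array(fwd) * 0.01)])
    endpoint = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    kin = make_kinematics(endpoint)
    contact = make_contact(len(x), state=ContactState.PREHENSILE, is_target=True)
    seq = segment_primitives(kin, contact, default_params)
    transports = [s for s in seq.segments if s.label is PrimitiveLabel.TRANSPORT]
    assert len(transports) == 2
    assert abs(transports[0].offset_ms - 400) <= 20


def test_misaligned_series_rejected(default_params):
    kin = _speed_profile_kinematics([30.0] * 20)
    contact = make_contact(15)
    with pytest.raises(AlignmentError):
        segment_primitives(kin, contact, default_params)


def test_minimal_segments_never_shorter_than_dwell(session_noise_free, default_params):
    seq = segment_primitives(
        session_noise_free.kinematics, session_noise_free.contact, default_params
    )
    for s in seq.segments:
        if s.label in (PrimitiveLabel.STABILIZE, PrimitiveLabel.IDLE):
            assert s.duration_ms >= default_params.min_still_ms
    assert_sorted_nonoverlapping(seq)


def test_label_contact_consistency(session_noise_free, default_params):
    kin, contact = session_noise_free.kinematics, session_noise_free.contact
    seq = segment_primitives(kin, contact, default_params)
    tgt = contact.target_contact
    for s in seq.segments:
        a, b = s.onset_ms // 10, s.offset_ms // 10
        frac = tgt[a:b].mean()
        if s.label in (PrimitiveLabel.TRANSPORT, PrimitiveLabel.STABILIZE):
            assert frac >= 0.5
        elif s.label in (PrimitiveLabel.REPOSITION, PrimitiveLabel.IDLE):
            assert frac == 0.0


def test_determinism(session_noise_free, default_params):
    kin, contact = session_noise_free.kinematics, session_noise_free.contact
    a = segment_primitives(kin, contact, default_params)
    b = segment_primitives(kin, contact, default_params)
    assert a == b


# ---------------------------------------------------------------- oracle

def test_noise_free_sessions_recovered_exactly():
    """Engine output equals generator ground truth on noise-free sessions."""
    for s in range(6):
        rec = generate_session(SimulationConfig(seed=100 + s, duration_s=30.0))
        got = flag_incomplete(
            segment_primitives(rec.kinematics, rec.contact), rec.intent_events
        )
        truth = [(x.label, x.onset_ms, x.offset_ms, x.incomplete) for x in rec.truth]
        found = [(x.label, x.onset_ms, x.offset_ms, x.incomplete) for x in got]
        assert found == truth


def test_noise_degrades_agreement_monotonically():
    """Frame-wise agreement with truth is non-increasing in endpoint noise."""

    def frame_agreement(rec, seq):
        n = len(rec.kinematics)
        ft = np.empty(n, dtype=object)
        fg = np.empty(n, dtype=object)
        for s in rec.truth:
            ft[s.onset_ms // 10 : s.offset_ms // 10] = s.label.value
        for s in seq:
            fg[s.onset_ms // 10 : s.offset_ms // 10] = s.label.value
        return float(np.mean(ft == fg))

    grid = (0.0, 0.005, 0.01, 0.02, 0.05)
    means = []
    for noise in grid:
        vals = [
            frame_agreement(
                rec := generate_session(
                    SimulationConfig(seed=s, noise_sd_cm=noise, duration_s=15.0)
                ),
                segment_primitives(rec.kinematics, rec.contact),
            )
            for s in range(20)
        ]
        means.append(np.mean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(means[:-1], means[1:]))


# ------------------------------------------------------------- incomplete

def test_drop_event_marks_transport_incomplete():
    segs = [
        seg(PrimitiveLabel.REACH, 0, 500),
        seg(PrimitiveLabel.TRANSPORT, 500, 1200),
    ]
    seq = LabelSequence(segments=segs, span_ms=1200)
    out = flag_incomplete(seq, [IntentEvent(800, IntentKind.OBJECT_DROPPED)])
    assert out[1].incomplete is True and out[0].incomplete is False


def test_aimed_missed_relabels_reposition_as_incomplete_reach():
    seq = LabelSequence(
        segments=[seg(PrimitiveLabel.REPOSITION, 0, 600)], span_ms=600
    )
    out = flag_incomplete(seq, [IntentEvent(300, IntentKind.TARGET_AIMED_MISSED)])
    assert out[0].label is PrimitiveLabel.REACH and out[0].incomplete is True


def test_empty_event_list_is_identity(session_noise_free):
    truth = session_noise_free.truth
    assert flag_incomplete(truth, []) == truth


def test_event_outside_segments_warns_and_is_ignored():
    seq = LabelSequence(segments=[seg(PrimitiveLabel.IDLE, 0, 500)], span_ms=1000)
    with pytest.warns(UserWarning):
        out = flag_incomplete(seq, [IntentEvent(700, IntentKind.OBJECT_DROPPED)])
    assert out == seq
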