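"""Cyclicity bouts, effector attribution, and grasp classification."""
import numpy as np
import pytest

from uemotion import (
    ANGLE_NAMES,
    ContactState,
    Cyclicity,
    Effector,
    EngineParams,
    GraspType,
    KinematicSeries,
    LabelSequence,
    PrimitiveLabel,
    SimulationConfig,
    attribute_effector_segment,
    characterize,
    classify_grasp_type,
    detect_rhythmic_bouts,
    effector_contributions,
    flag_incomplete,
    generate_session,
    segment_primitives,
)
from uemotion.errors import ContractError

from conftest import make_contact, make_kinematics, seg


# ----------------------------------------------------------------- effector

def _angles_with_motion(n, moving: dict):
    """Angle array with sinusoidal excursions on the named joints."""
    angles = np.tile([5.0, 30.0, 15.0, 60.0, 10.0, 5.0], (n, 1))
    tau = np.sin(np.pi * (np.arange(n) + 0.5) / n)
    for joint, amp in moving.items():
        angles[:, ANGLE_NAMES.index(joint)] += amp * tau
    return angles


def _motion_segment(n):
    return seg(PrimitiveLabel.REACH, 0, n * 10)


@pytest.mark.parametrize(
    "moving,expected",
    [
        ({"shoulder_flexion": 25.0, "elbow_flexion": -15.0}, Effector.PROXIMAL),
        ({"wrist_extension": 25.0, "forearm_supination": 15.0}, Effector.DISTAL),
        ({"trunk_flexion": 15.0}, Effector.AXIAL),
        ({"trunk_flexion": 12.0, "shoulder_flexion": 12.0}, Effector.AXIAL_PROXIMAL),
        (
            {"shoulder_flexion": 6.0, "wrist_extension": 25.0, "forearm_supination": 18.0},
            Effector.PROXIMAL_DISTAL,
        ),
    ],
)
def test_effector_attribution(moving, expected):
    n = 60
    kin = make_kinematics(np.zeros((n, 3)), angles=_angles_with_motion(n, moving))
    assert attribute_effector_segment(kin, _motion_segment(n)) is expected


def test_minimal_segment_is_not_applicable(session_noise_free):
    s = seg(PrimitiveLabel.IDLE, 0, 500)
    assert (
        attribute_effector_segment(session_noise_free.kinematics, s)
        is Effector.NOT_APPLICABLE
    )


def test_contribution_shares_sum_to_total():
    n = 50
    kin = make_kinematics(
        np.zeros((n, 3)),
        angles=_angles_with_motion(n, {"shoulder_flexion": 20.0, "wrist_extension": 10.0}),
    )
    c = effector_contributions(kin, _motion_segment(n))
    shares = c.shares()
    assert c.total > 0
    assert abs(sum(shares.values()) - 1.0) < 1e-12
    assert all(v >= 0 for v in shares.values())


def test_designated_effector_recovered_on_synthetic_sessions():
    """>=95% of motion segments recover the generator's designated effector."""
    ok = tot = 0
    for s in range(8):
        rec = generate_session(SimulationConfig(seed=400 + s, duration_s=30.0))
        got = characterize(
            segment_primitives(rec.kinematics, rec.contact),
            rec.kinematics,
            rec.contact,
        )
        for ts, gs in zip(rec.truth.segments, got.segments):
            if ts.label in (
                PrimitiveLabel.REACH,
                PrimitiveLabel.REPOSITION,
                PrimitiveLabel.TRANSPORT,
            ):
                tot += 1
                ok += ts.effector == gs.effector
    assert tot > 50
    assert ok / tot >= 0.95


# -------------------------------------------------------------------- grasp

def test_all_prehensile_segment():
    contact = make_contact(50, state=ContactState.PREHENSILE, is_target=True)
    s = seg(PrimitiveLabel.TRANSPORT, 0, 500)
    assert classify_grasp_type(contact, s) is GraspType.PREHENSILE


def test_tray_support_is_non_prehensile():
    contact = make_contact(50, state=ContactState.NON_PREHENSILE, is_target=True)
    s = seg(PrimitiveLabel.STABILIZE, 0, 500)
    assert classify_grasp_type(contact, s) is GraspType.NON_PREHENSILE


def test_majority_state_wins_60_40():
    # counting oracle: 30 prehensile vs 20 non-prehensile frames
    contact = make_contact(
        50,
        spans=[
            (0, 30, ContactState.PREHENSILE, True),
            (30, 50, ContactState.NON_PREHENSILE, True),
        ],
    )
    s = seg(PrimitiveLabel.TRANSPORT, 0, 500)
    assert classify_grasp_type(contact, s) is GraspType.PREHENSILE
    flipped = make_contact(
        50,
        spans=[
            (0, 20, ContactState.PREHENSILE, True),
            (20, 50, ContactState.NON_PREHENSILE, True),
        ],
    )
    assert classify_grasp_type(flipped, s) is GraspType.NON_PREHENSILE


def test_tie_breaks_prehensile():
    contact = make_contact(
        50,
        spans=[
            (0, 25, ContactState.PREHENSILE, True),
            (25, 50, ContactState.NON_PREHENSILE, True),
        ],
    )
    s = seg(PrimitiveLabel.TRANSPORT, 0, 500)
    assert classify_grasp_type(contact, s) is GraspType.PREHENSILE


def test_grasp_on_reposition_is_contract_error():
    contact = make_contact(10)
    with pytest.raises(ContractError):
        classify_grasp_type(contact, seg(PrimitiveLabel.REPOSITION, 0, 100))


# ---------------------------------------------------------------- cyclicity

def _alternating_transports(n_transports, amp_cm=12.0, seg_frames=50, amps=None):
    """Contiguous alternating-direction transports with full kinematics."""
    frames = n_transports * seg_frames
    x = np.zeros(frames)
    pos = 0.0
    segs = []
    for i in range(n_transports):
        a = i * seg_frames
        amp = amps[i] if amps else amp_cm
        sign = 1.0 if i % 2 == 0 else -1.0
        step = sign * amp / seg_frames
        for f in range(seg_frames):
            x[a + f] = pos + step * f
        pos += sign * amp
        segs.append(seg(PrimitiveLabel.TRANSPORT, a * 10, (a + seg_frames) * 10))
    kin = make_kinematics(np.column_stack([x, np.zeros(frames), np.zeros(frames)]))
    return kin, LabelSequence(segments=segs, span_ms=frames * 10)


def test_five_alternating_pairs_form_one_bout():
    kin, seq = _alternating_transports(10)
    out = detect_rhythmic_bouts(seq, kin)
    assert all(s.cyclicity is Cyclicity.RHYTHMIC for s in out.segments)
    assert len({s.bout_id for s in out.segments}) == 1


def test_single_transport_is_discrete(session_noise_free):
    kin, seq = _alternating_transports(1)
    out = detect_rhythmic_bouts(seq, kin)
    assert out[0].cyclicity is Cyclicity.DISCRETE and out[0].bout_id is None


def test_single_pair_is_discrete():
    # one out-and-back (a single cycle) does not make a bout
    kin, seq = _alternating_transports(2)
    out = detect_rhythmic_bouts(seq, kin)
    assert all(s.cyclicity is Cyclicity.DISCRETE for s in out.segments)


def test_amplitude_change_splits_bouts():
    # 3 cycles at amplitude A then 3 at 2A: two bouts with distinct ids
    amps = [12.0] * 6 + [24.0] * 6
    kin, seq = _alternating_transports(12, amps=amps)
    out = detect_rhythmic_bouts(seq, kin)
    ids = [s.bout_id for s in out.segments]
    assert all(i is not None for i in ids)
    assert ids[:6] == [1] * 6 and ids[6:] == [2] * 6


def test_generator_bouts_are_recovered():
    """Every truth-rhythmic segment is detected rhythmic, bouts intact."""
    for s in range(6):
        rec = generate_session(
            SimulationConfig(seed=500 + s, duration_s=40.0, rhythmic_prob=0.25)
        )
        got = characterize(
            segment_primitives(rec.kinematics, rec.contact),
            rec.kinematics,
            rec.contact,
        )
        truth_bouts = {}
        for ts, gs in zip(rec.truth.segments, got.segments):
            if ts.cyclicity is Cyclicity.RHYTHMIC:
                assert gs.cyclicity is Cyclicity.RHYTHMIC
                truth_bouts.setdefault(ts.bout_id, set()).add(gs.bout_id)
        for members in truth_bouts.values():
            assert len(members) == 1  # a truth bout maps to one detected bout
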