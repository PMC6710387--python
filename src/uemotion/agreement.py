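"""Boundary-tolerant inter-rater reliability for primitive segmentation.

A coder's labeling of an expert-segmented recording is scored per expert
transition (segment onset) inside a tolerance window (default ±20 ms).
An item is an error if (1) the transition mismatches by more than the
window even with a matching label, (2) the transition is inside the window
but the label mismatches, or (3) both mismatch. Per-primitive chance-
corrected agreement is Cohen's kappa, one-vs-rest, averaged over
coder-expert pairs.

The unit of analysis (per-expert-segment items, with the onset verdict
gating the coder category) is a reconstruction: published reliability
protocols of this kind rarely state whether kappa was computed over
frames, segments, or transitions, and this is the construction under
which the three error rules enter the kappa computation directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import AlignmentError, UemotionError
from .types import EngineParams, LabelSequence, PRIMITIVE_ORDER, PrimitiveLabel

#: Category used for items whose onset verdict is not CORRECT.
ERROR_CATEGORY = "ERROR"


class Verdict(str, Enum):
    CORRECT = "CORRECT"
    ERR_BOUNDARY = "ERR_BOUNDARY"  # matching label, transition off by > window
    ERR_LABEL = "ERR_LABEL"  # transition within window, label mismatched
    ERR_BOTH = "ERR_BOTH"
    MISSING = "MISSING"  # no coder transition within 2x window


@dataclass
class TransitionMatch:
    expert_t_ms: int
    coder_t_ms: Optional[int]
    delta_ms: Optional[int]
    expert_label: PrimitiveLabel
    coder_label: Optional[PrimitiveLabel]
    verdict: Verdict


@dataclass
class AgreementReport:
    """Per-primitive kappa and transition-error tallies."""

    kappa: Dict[PrimitiveLabel, float]
    verdict_counts: Dict[PrimitiveLabel, Dict[Verdict, int]]
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "kappa": {k.value: v for k, v in self.kappa.items()},
            "verdict_counts": {
                k.value: {v.value: c for v, c in counts.items()}
                for k, counts in self.verdict_counts.items()
            },
        }


def match_transitions(
    expert: LabelSequence, coder: LabelSequence, window_ms: float = 20.0
) -> List[TransitionMatch]:
    """Pair each expert transition with the nearest coder transition.

    Greedy nearest-first pairing over all (expert, coder) onset pairs; a
    coder transition is used at most once; distance ties go to the earlier
    coder transition. Expert transitions with no coder transition within
    twice the window are MISSING.
    """
    if expert.span_ms != coder.span_ms:
        raise AlignmentError(
            f"sequences cover different spans ({expert.span_ms} vs {coder.span_ms} ms)"
        )
    e_on = [(s.onset_ms, s.label) for s in expert.segments]
    c_on = [(s.onset_ms, s.label) for s in coder.segments]
    # all candidate pairs sorted by |delta|, then by coder onset (tie-break)
    pairs = sorted(
        (
            (abs(c[0] - e[0]), ci, ei)
            for ei, e in enumerate(e_on)
            for ci, c in enumerate(c_on)
            if abs(c[0] - e[0]) <= 2 * window_ms
        ),
        key=lambda p: (p[0], c_on[p[1]][0]),
    )
    assigned_e: Dict[int, int] = {}
    used_c: set = set()
    for _, ci, ei in pairs:
        if ei in assigned_e or ci in used_c:
            continue
        assigned_e[ei] = ci
        used_c.add(ci)
    matches = []
    for ei, (et, elabel) in enumerate(e_on):
        ci = assigned_e.get(ei)
        if ci is None:
            matches.append(
                TransitionMatch(et, None, None, elabel, None, Verdict.MISSING)
            )
            continue
        ct, clabel = c_on[ci]
        delta = ct - et
        in_window = abs(delta) <= window_ms
        same = clabel == elabel
        if in_window and same:
            verdict = Verdict.CORRECT
        elif in_window:
            verdict = Verdict.ERR_LABEL
        elif same:
            verdict = Verdict.ERR_BOUNDARY
        else:
            verdict = Verdict.ERR_BOTH
        matches.append(TransitionMatch(et, ct, delta, elabel, clabel, verdict))
    return matches


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement fraction and p_e the chance agreement
    implied by the two raters' marginal category distributions. The
    degenerate case p_e = 1 (both raters constant on one category) returns
    1.0 when agreement is perfect.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise UemotionError(f"rating lists differ in length ({len(a)} vs {len(b)})")
    if not a:
        raise UemotionError("rating lists are empty")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = set(a) | set(b)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _pair_categories(expert: LabelSequence, coder: LabelSequence, window_ms: float):
    """Per-expert-segment (expert label, coder category) item pairs.

    The coder category is the coder's label when the segment's onset lies
    inside the tolerance window (a label mismatch then disagrees with the
    expert naturally — rules (2) and (3)), and the distinct error category
    when the boundary itself missed the window, so a boundary miss makes
    the item incorrect even when the labels agree — rule (1). Gating on
    the boundary alone (rather than on the full verdict) keeps the coder
    category independent of the expert's label for independent raters,
    which is what makes chance-level agreement score kappa ~ 0.
    """
    matches = match_transitions(expert, coder, window_ms)
    expert_side = [m.expert_label.value for m in matches]
    coder_side = [
        m.coder_label.value
        if m.verdict in (Verdict.CORRECT, Verdict.ERR_LABEL)
        else ERROR_CATEGORY
        for m in matches
    ]
    return expert_side, coder_side, matches


def agreement_report(
    expert: LabelSequence,
    coders: Sequence[LabelSequence],
    params: Optional[EngineParams] = None,
) -> AgreementReport:
    """Score one or more coders against an expert segmentation.

    Per-primitive kappa is one-vs-rest over the five primitive labels plus
    the error category, averaged across coder-expert pairs; verdict tallies
    are pooled.
    """
    params = params or EngineParams()
    if not coders:
        raise UemotionError("need at least one coder sequence")
    window = params.transition_window_ms
    kappas: Dict[PrimitiveLabel, List[float]] = {p: [] for p in PRIMITIVE_ORDER}
    counts: Dict[PrimitiveLabel, Dict[Verdict, int]] = {
        p: {v: 0 for v in Verdict} for p in PRIMITIVE_ORDER
    }
    for coder in coders:
        e_side, c_side, matches = _pair_categories(expert, coder, window)
        for m in matches:
            if m.expert_label in counts:
                counts[m.expert_label][m.verdict] += 1
        for prim in PRIMITIVE_ORDER:
            a = [x == prim.value for x in e_side]
            b = [x == prim.value for x in c_side]
            kappas[prim].append(cohens_kappa(a, b))
    return AgreementReport(
        kappa={p: float(np.mean(v)) for p, v in kappas.items()},
        verdict_counts=counts,
        n_pairs=len(coders),
    )
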