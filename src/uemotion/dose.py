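"""Rehabilitation dose metrics and impairment-group comparison.

Dose is the total primitive repetition count; density is repetitions per
second; composition percentages describe what the repetitions were — per
primitive type (count shares), motion vs minimal-motion (time shares of
labeled data), discrete vs rhythmic and effector shares within functional
motion, prehensile vs non-prehensile shares within grasp-bearing
primitives, and the incomplete-variant share.

Group comparisons fit, per outcome, a linear mixed model with impairment
group as a fixed effect and a subject random intercept (the estimation
stage delegates to statsmodels MixedLM; the bespoke content here is the
metric definitions).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, UemotionError
from .types import (
    Cyclicity,
    Effector,
    GRASP_LABELS,
    GraspType,
    LabelSequence,
    MINIMAL_LABELS,
    MOTION_LABELS,
    PRIMITIVE_ORDER,
    PrimitiveLabel,
)


@dataclass
class CompositionSummary:
    """Dose, density, and composition percentages for one or more trials.

    Percentage families are NaN-flagged when their denominator is empty
    (e.g. grasp shares in a recording without transports/stabilizations).
    """

    dose: int
    duration_s: float
    density: float
    primitive_pct: Dict[PrimitiveLabel, float]
    motion_pct: float
    minimal_pct: float
    discrete_pct: float
    rhythmic_pct: float
    effector_pct: Dict[Effector, float]
    grasp_pct: Dict[GraspType, float]
    incomplete_pct: float
    n_trials: int = 1

    def as_outcomes(self) -> Dict[str, float]:
        """Flat outcome name -> value mapping used by group comparison."""
        out = {"density": self.density, "motion_pct": self.motion_pct,
               "minimal_pct": self.minimal_pct, "incomplete_pct": self.incomplete_pct,
               "discrete_pct": self.discrete_pct, "rhythmic_pct": self.rhythmic_pct}
        for p in PRIMITIVE_ORDER:
            out[f"{p.value.lower()}_pct"] = self.primitive_pct[p]
        for e in (Effector.PROXIMAL, Effector.DISTAL, Effector.AXIAL,
                  Effector.PROXIMAL_DISTAL, Effector.AXIAL_PROXIMAL):
            out[f"effector_{e.value.lower()}_pct"] = self.effector_pct[e]
        out["prehensile_pct"] = self.grasp_pct[GraspType.PREHENSILE]
        out["non_prehensile_pct"] = self.grasp_pct[GraspType.NON_PREHENSILE]
        return out


@dataclass
class GroupComparison:
    """Mixed-model fixed effect of impairment group on one outcome."""

    outcome: str
    estimate: float  # moderate - mild fixed effect
    stat: float  # z statistic of the fixed effect
    df: int  # residual degrees of freedom (n_obs - 2), approximate
    p_value: float
    ci_low: float
    ci_high: float


def _pct(count: float, total: float) -> float:
    return 100.0 * count / total if total > 0 else float("nan")


def compute_composition(
    seqs: Sequence[LabelSequence],
    durations_s: Sequence[float],
    weighting: str = "time",
) -> CompositionSummary:
    """Pooled dose/density/composition over one or more trials.

    ``weighting`` selects how motion-characteristic shares (motion/minimal,
    cyclicity, effector) are weighted: ``"time"`` (default) weights by
    labeled milliseconds, ``"count"`` by segment counts. Primitive-type and
    incomplete percentages are always count shares of the dose; grasp
    shares are count shares over grasp-bearing segments.
    """
    if len(seqs) != len(durations_s):
        raise UemotionError("seqs and durations differ in length")
    if any(d <= 0 for d in durations_s):
        raise UemotionError("trial durations must be positive")
    if weighting not in ("time", "count"):
        raise UemotionError(f"unknown weighting '{weighting}'")

    segs = [s for seq in seqs for s in seq.segments]
    dose = len(segs)
    duration_s = float(sum(durations_s))
    density = dose / duration_s if dose else 0.0

    def w(seg) -> float:
        return seg.duration_ms if weighting == "time" else 1.0

    label_counts = {p: sum(1 for s in segs if s.label is p) for p in PRIMITIVE_ORDER}
    labeled = sum(w(s) for s in segs)
    motion_w = sum(w(s) for s in segs if s.label in MOTION_LABELS)
    minimal_w = sum(w(s) for s in segs if s.label in MINIMAL_LABELS)

    motion_segs = [s for s in segs if s.label in MOTION_LABELS]
    motion_total = sum(w(s) for s in motion_segs)
    rhythmic_w = sum(w(s) for s in motion_segs if s.cyclicity is Cyclicity.RHYTHMIC)

    eff_classes = (Effector.PROXIMAL, Effector.DISTAL, Effector.AXIAL,
                   Effector.PROXIMAL_DISTAL, Effector.AXIAL_PROXIMAL)
    eff_w = {e: sum(w(s) for s in motion_segs if s.effector is e) for e in eff_classes}
    eff_total = sum(eff_w.values())

    grasp_segs = [s for s in segs if s.label in GRASP_LABELS]
    n_preh = sum(1 for s in grasp_segs if s.grasp is GraspType.PREHENSILE)
    n_nonp = sum(1 for s in grasp_segs if s.grasp is GraspType.NON_PREHENSILE)

    return CompositionSummary(
        dose=dose,
        duration_s=duration_s,
        density=density,
        primitive_pct={p: _pct(label_counts[p], dose) for p in PRIMITIVE_ORDER},
        motion_pct=_pct(motion_w, labeled),
        minimal_pct=_pct(minimal_w, labeled),
        discrete_pct=_pct(motion_total - rhythmic_w, motion_total),
        rhythmic_pct=_pct(rhythmic_w, motion_total),
        effector_pct={e: _pct(eff_w[e], eff_total) for e in eff_classes},
        grasp_pct={
            GraspType.PREHENSILE: _pct(n_preh, n_preh + n_nonp),
            GraspType.NON_PREHENSILE: _pct(n_nonp, n_preh + n_nonp),
        },
        incomplete_pct=_pct(sum(1 for s in segs if s.incomplete), dose),
        n_trials=len(seqs),
    )


def per_trial_compositions(
    seqs: Sequence[LabelSequence], durations_s: Sequence[float], weighting: str = "time"
) -> List[CompositionSummary]:
    """One :class:`CompositionSummary` per trial (non-pooled view)."""
    return [compute_composition([s], [d], weighting) for s, d in zip(seqs, durations_s)]


def compare_groups(
    per_trial: Sequence[CompositionSummary],
    subject_ids: Sequence[str],
    groups: Sequence[str],
    outcomes: Optional[Sequence[str]] = None,
) -> List[GroupComparison]:
    """Mixed-model group comparison per outcome.

    Fits ``outcome ~ group`` with a subject random intercept. Requires at
    least two subjects per group. The reported estimate is the second
    group's level relative to the first (alphabetical coding).
    """
    import statsmodels.formula.api as smf

    if not (len(per_trial) == len(subject_ids) == len(groups)):
        raise UemotionError("per_trial, subject_ids and groups differ in length")
    df = pd.DataFrame({"subject": list(subject_ids), "group": list(groups)})
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise DesignError(f"need exactly two groups, got {levels}")
    for g in levels:
        n_subj = df.loc[df["group"] == g, "subject"].nunique()
        if n_subj < 2:
            raise DesignError(f"group '{g}' has {n_subj} subject(s); need >= 2")

    values = pd.DataFrame([c.as_outcomes() for c in per_trial])
    if outcomes is None:
        outcomes = [c for c in values.columns if values[c].notna().any()]
    results: List[GroupComparison] = []
    for outcome in outcomes:
        data = df.copy()
        data["value"] = values[outcome].to_numpy()
        data = data.dropna(subset=["value"])
        if data["value"].nunique() <= 1:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-sample convergence chatter
            model = smf.mixedlm("value ~ C(group)", data, groups=data["subject"])
            fit = model.fit(reml=True)
        term = f"C(group)[T.{levels[1]}]"
        ci = fit.conf_int().loc[term]
        results.append(
            GroupComparison(
                outcome=outcome,
                estimate=float(fit.params[term]),
                stat=float(fit.tvalues[term]),
                df=len(data) - 2,
                p_value=float(fit.pvalues[term]),
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
            )
        )
    return results
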