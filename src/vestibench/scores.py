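"""HINTS and ABCD² clinical index-test scorers with ROC analysis.

HINTS (Head Impulse, gaze-evoked Nystagmus, Test of Skew) indicates a central
pattern if the horizontal head-impulse test is normal, and/or a
direction-changing nystagmus in eccentric gaze, and/or a skew deviation is
present: one point per central item, cutoff ≥ 1 for stroke.

ABCD² sums age ≥ 60 years (1), blood pressure ≥ 140/90 mmHg (1), unilateral
weakness (2) or speech impairment without weakness (1), symptom duration
≥ 60 min (2) or 10–59 min (1), and diabetes (1); cutoff ≥ 3 for stroke.
The blood-pressure item counts if systolic ≥ 140 OR diastolic ≥ 90 (the usual
convention in the TIA-score literature).

An AUC for either score is obtained by sweeping the integer cutoff over the
cohort (equivalently, treating the score itself as the ranking statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .metrics import roc_auc, roc_points

HINTS_CUTOFF = 1
ABCD2_CUTOFF = 3


class MissingInputError(ValueError):
    """A required index-test item is missing and no imputation policy applies."""


@dataclass(frozen=True)
class IndexTestResult:
    score: int
    decision_stroke: bool
    cutoff_used: int


def hints_score(hit_normal, direction_changing_gen, skew,
                missing_policy: str = "raise") -> IndexTestResult:
    """Score the three HINTS items; 1 point per central item, stroke at >= 1.

    ``missing_policy='raise'`` (default) refuses missing items;
    ``'conservative'`` treats a missing item as peripheral (0 points), for
    cohort-level screening.
    """
    items = (hit_normal, direction_changing_gen, skew)
    if any(i is None for i in items):
        if missing_policy == "raise":
            raise MissingInputError("missing HINTS item; pass missing_policy='conservative' "
                                    "to treat missing items as peripheral")
        if missing_policy != "conservative":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    score = sum(int(bool(i)) for i in items if i is not None)
    return IndexTestResult(score, score >= HINTS_CUTOFF, HINTS_CUTOFF)


def abcd2_score(age, sbp, dbp, unilateral_weakness, speech_impairment_wo_weakness,
                duration_minutes, diabetes,
                missing_policy: str = "raise") -> IndexTestResult:
    """ABCD² score with the printed point scheme; stroke at >= 3.

    Clinical-features points: 2 for unilateral weakness, else 1 for speech
    impairment without weakness, else 0.  Duration: 2 points for >= 60 min,
    1 point for [10, 60) min, 0 below.
    """
    inputs = dict(age=age, sbp=sbp, dbp=dbp, unilateral_weakness=unilateral_weakness,
                  speech=speech_impairment_wo_weakness,
                  duration_minutes=duration_minutes, diabetes=diabetes)
    missing = [k for k, v in inputs.items() if v is None]
    if missing:
        if missing_policy == "raise":
            raise MissingInputError(f"missing ABCD² inputs: {missing}")
        if missing_policy != "conservative":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if duration_minutes is not None and duration_minutes < 0:
        raise ValueError("duration must be >= 0 minutes")

    score = 0
    if age is not None and age >= 60:
        score += 1
    if (sbp is not None and sbp >= 140) or (dbp is not None and dbp >= 90):
        score += 1
    if unilateral_weakness:
        score += 2
    elif speech_impairment_wo_weakness:
        score += 1
    if duration_minutes is not None:
        if duration_minutes >= 60:
            score += 2
        elif duration_minutes >= 10:
            score += 1
    if diabetes:
        score += 1
    return IndexTestResult(score, score >= ABCD2_CUTOFF, ABCD2_CUTOFF)


def score_roc(scores, labels):
    """ROC over all integer score cutoffs plus the trapezoidal AUC.

    Returns ``(fpr, tpr, thresholds, auc)``.  With ties contributing ½, the
    AUC equals the exhaustive pair-counting (Mann–Whitney) statistic.
    """
    auc = roc_auc(scores, labels)
    fpr, tpr, thr = roc_points(scores, labels)
    return fpr, tpr, thr, auc


def score_cohort(cohort: Cohort, missing_policy: str = "conservative") -> pd.DataFrame:
    """Score HINTS and ABCD² for every patient of a cohort.

    Returns a table with per-patient scores and binary decisions; patients
    with missing items are handled per ``missing_policy`` and flagged in the
    ``hints_complete`` / ``abcd2_complete`` columns.
    """
    rows = []
    for rec in cohort.iter_records():
        h = rec.hints_components()
        a = rec.abcd2_components()
        hres = hints_score(h["hit_normal"], h["direction_changing_gen"], h["skew"],
                           missing_policy=missing_policy)
        ares = abcd2_score(a["age"], a["sbp"], a["dbp"], a["unilateral_weakness"],
                           a["speech_impairment_wo_weakness"], a["duration_minutes"],
                           a["diabetes"], missing_policy=missing_policy)
        rows.append({
            "patient_id": rec.patient_id,
            "hints": hres.score,
            "hints_stroke": int(hres.decision_stroke),
            "hints_complete": int(not any(v is None for v in h.values())),
            "abcd2": ares.score,
            "abcd2_stroke": int(ares.decision_stroke),
            "abcd2_complete": int(not any(v is None for v in a.values())),
        })
    return pd.DataFrame(rows).set_index("patient_id")
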