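"""Label-informed severe-side selection.

For each patient one kidney is chosen as the training input: the side with
the higher VUR grade; if the grades are equal and positive, the side with
the lower mean tracer uptake (lower mean intensity on the DMSA image); for
negative patients, a pseudo-random side keyed on (seed, patient_id) so the
choice is reproducible and independent of dataset ordering.

This rule uses the reference-standard grading, so it is a lesion-focused
research setting, not a deployable reader; image-driven side selection is
deliberately out of scope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["SideDecision", "select_severe_side", "select_cohort"]


@dataclass(frozen=True)
class SideDecision:
    patient_id: str
    chosen_side: str  # "left" | "right"
    rule_fired: str  # "higher_grade" | "lower_mean_intensity" | "random_negative"


def _stable_patient_hash(patient_id: str) -> int:
    digest = hashlib.sha256(patient_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def select_severe_side(
    grade_left: int,
    grade_right: int,
    mean_left: float,
    mean_right: float,
    patient_id: str,
    seed: int,
) -> SideDecision:
    """Apply the severe-side rule to one patient.

    Exact intensity ties under equal positive grades resolve to the left
    side (fixed deterministic tie-break).
    """
    for name, g in (("grade_left", grade_left), ("grade_right", grade_right)):
        if not (0 <= int(g) <= 5):
            raise ValueError(f"{name} must be in 0..5, got {g}")
    for name, v in (("mean_left", mean_left), ("mean_right", mean_right)):
        if not (0.0 <= v <= 255.0):
            raise ValueError(f"{name} must be in [0, 255], got {v}")
    if grade_left != grade_right:
        side = "left" if grade_left > grade_right else "right"
        rule = "higher_grade"
    elif grade_left >= 1:
        side = "left" if mean_left <= mean_right else "right"
        rule = "lower_mean_intensity"
    else:
        rng = np.random.default_rng([int(seed), _stable_patient_hash(patient_id)])
        side = "left" if rng.random() < 0.5 else "right"
        rule = "random_negative"
    return SideDecision(patient_id=patient_id, chosen_side=side, rule_fired=rule)


def select_cohort(rows: Iterable[dict], seed: int) -> pd.DataFrame:
    """Vectorised convenience: apply the rule to dict-like patient rows.

    Each row needs patient_id, vur_grade_left/right and mean_left/right;
    returns the side-decision table (patient_id, chosen_side, rule_fired).
    """
    decisions = [
        select_severe_side(
            r["vur_grade_left"],
            r["vur_grade_right"],
            r["mean_left"],
            r["mean_right"],
            r["patient_id"],
            seed,
        )
        for r in rows
    ]
    return pd.DataFrame([d.__dict__ for d in decisions])
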