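"""Per-patient counts and manual-vs-automated concordance accounting.

A patient's sample is one cartridge; the patient's CTC and CHC counts are
the numbers of events the classifier called in each class.  Two enumeration
methods are compared at a positivity cutoff: a patient is *status
concordant* when both methods fall on the same side of the cutoff, and
*numerically discordant* when the statuses agree but the raw counts differ
(all both-zero pairs are numerically equal by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .detection import DetectionConfig, EventFeatures, detect_stack
from .gating import CHC, CTC, CellCall, GateSet, classify_event


@dataclass
class PatientCounts:
    patient_id: str
    ctc: int
    chc: int
    other: int

    @property
    def total(self) -> int:
        return self.ctc + self.chc + self.other


@dataclass
class ConcordanceResult:
    """Two-method agreement at a positivity cutoff.

    ``crosstab`` is the 2x2 status table, rows = method A (negative,
    positive), columns = method B; its four cells sum to the cohort size.
    """

    analyte: str
    cutoff: int
    n: int
    n_both_negative: int
    n_both_positive: int
    n_discordant_status: int
    detection_concordance_rate: float
    n_numerical_discordant: int
    crosstab: list[list[int]]

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "cutoff": self.cutoff,
            "n": self.n,
            "n_both_negative": self.n_both_negative,
            "n_both_positive": self.n_both_positive,
            "n_discordant_status": self.n_discordant_status,
            "detection_concordance_rate": self.detection_concordance_rate,
            "n_numerical_discordant": self.n_numerical_discordant,
            "crosstab": self.crosstab,
        }


def count_patient(calls: Iterable[CellCall], patient_id: str = "") -> PatientCounts:
    """Tally one patient's calls; CTC + CHC + OTHER equals the event total."""
    calls = list(calls)
    ids = [c.event_id for c in calls]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate event ids in calls: {dupes}")
    ctc = sum(1 for c in calls if c.label == CTC)
    chc = sum(1 for c in calls if c.label == CHC)
    return PatientCounts(
        patient_id=patient_id, ctc=ctc, chc=chc, other=len(calls) - ctc - chc
    )


def enumerate_cartridge(
    stack,
    config: DetectionConfig | None = None,
    ctc_gates: GateSet | None = None,
    chc_gates: GateSet | None = None,
) -> tuple[list[EventFeatures], list[CellCall], PatientCounts]:
    """Detect, gate and count one cartridge (the automated path end to end)."""
    features = detect_stack(stack, config)
    calls = [classify_event(f, ctc_gates, chc_gates) for f in features]
    return features, calls, count_patient(calls, patient_id=stack.sample_id)


def detection_concordance(
    counts: pd.DataFrame, analyte: str = "ctc", cutoff: int = 1
) -> ConcordanceResult:
    """Status-level agreement between the manual and automated counts.

    The result is symmetric in the two methods; the crosstab orients rows by
    the manual method only for display.
    """
    if len(counts) == 0:
        raise ValueError("empty counts table")
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    a = counts[f"{analyte}_manual"].to_numpy()
    b = counts[f"{analyte}_auto"].to_numpy()
    pos_a = a >= cutoff
    pos_b = b >= cutoff
    both_neg = int(np.sum(~pos_a & ~pos_b))
    both_pos = int(np.sum(pos_a & pos_b))
    discord = int(np.sum(pos_a != pos_b))
    n = len(counts)
    numerical = int(np.sum((pos_a == pos_b) & (a != b)))
    crosstab = [
        [both_neg, int(np.sum(~pos_a & pos_b))],
        [int(np.sum(pos_a & ~pos_b)), both_pos],
    ]
    return ConcordanceResult(
        analyte=analyte,
        cutoff=cutoff,
        n=n,
        n_both_negative=both_neg,
        n_both_positive=both_pos,
        n_discordant_status=discord,
        detection_concordance_rate=(both_neg + both_pos) / n,
        n_numerical_discordant=numerical,
        crosstab=crosstab,
    )


def totals(counts: pd.DataFrame, cutoff: int = 1) -> dict:
    """Per-method column totals and positivity fractions (integer-exact)."""
    out: dict[str, dict] = {}
    n = len(counts)
    for col in ("ctc_manual", "ctc_auto", "chc_manual", "chc_auto"):
        if col not in counts.columns:
            continue
        vals = counts[col].to_numpy()
        n_pos = int(np.sum(vals >= cutoff))
        out[col] = {
            "total": int(vals.sum()),
            "n_positive": n_pos,
            "positivity_pct": 100.0 * n_pos / n if n else 0.0,
        }
    out["n"] = n
    out["cutoff"] = cutoff
    return out
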