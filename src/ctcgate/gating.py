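"""Event classification by declarative threshold gates.

Two classification paths are provided:

* the **automated** path — conjunctions of threshold predicates ("gates")
  over the measured event features, with shipped defaults for circulating
  tumor cells (CTC: nucleated, CK-positive, CD45-negative) and circulating
  hybrid cells (CHC: nucleated, CK-positive *and* CD45-positive);
* an **emulation of manual gallery review** — the qualitative reviewer
  criteria (diameter > 4 um, visible nucleus, CK status, CD45 status)
  operationalized on the same features, with an optional seeded
  operator-noise model that flips calls to OTHER to mimic inter-operator
  variability.

Default gate thresholds (all absolute, in AU / um^2):

========================  ==========  ==========
feature                   CTC         CHC
========================  ==========  ==========
cd45_mean                 <= 5        > 30
cd45_max                  —           > 50
dapi_mean                 > 45        > 45
ck_mean                   > 60        > 60
ck_size                   > 16        > 16
ck_size                   <= 400      <= 400
ck_dapi_overlay           > 0.2       > 0.2
marker1_mean              <= 5        <= 5
marker2_mean              <= 5        <= 5
cd45_dapi_overlay         —           > 0.2
cd45_size                 —           > 16
cd45_size                 —           <= 400
========================  ==========  ==========

Comparator strictness is exact: an event with ``cd45_mean == 5`` passes the
CTC CD45 gate, one with ``ck_size == 16`` fails both sets.  The marker
gates pass when the auxiliary channels are absent (feature 0 <= 5), so a
three-channel kit never blocks classification.  The two default sets are
mutually exclusive by construction (``cd45_mean <= 5`` vs ``> 30``);
custom gate configs are checked for exclusivity at load time.
"""

from __future__ import annotations

import json
import math
import operator
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .detection import FEATURE_NAMES, EventFeatures

_OPS = {"<=": operator.le, "<": operator.lt, ">=": operator.ge, ">": operator.gt}

CTC = "CTC"
CHC = "CHC"
OTHER = "OTHER"
AUTOMATED = "AUTOMATED"
MANUAL_EMULATED = "MANUAL_EMULATED"


class GateConfigError(ValueError):
    """A gate configuration is malformed or the class sets overlap."""


@dataclass(frozen=True)
class Gate:
    """A single threshold predicate over one event feature."""

    feature: str
    comparator: str  # one of <=, <, >=, >
    threshold: float

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise GateConfigError(f"unknown feature {self.feature!r}")
        if self.comparator not in _OPS:
            raise GateConfigError(f"unknown comparator {self.comparator!r}")
        if not math.isfinite(self.threshold):
            raise GateConfigError(f"non-finite threshold for {self.feature}")

    def passes(self, features: EventFeatures) -> bool:
        return _OPS[self.comparator](getattr(features, self.feature), self.threshold)


@dataclass(frozen=True)
class GateSet:
    """All-of (conjunctive) list of gates defining one cell class."""

    label: str
    gates: tuple[Gate, ...]

    def __post_init__(self) -> None:
        if not self.gates:
            raise GateConfigError(f"gate set {self.label!r} is empty")

    def passes(self, features: EventFeatures) -> bool:
        return all(g.passes(features) for g in self.gates)

    def with_override(self, feature: str, comparator: str, threshold: float) -> "GateSet":
        """Return a copy with the matching gate's threshold replaced."""
        new = []
        hit = False
        for g in self.gates:
            if g.feature == feature and g.comparator == comparator:
                new.append(Gate(feature, comparator, threshold))
                hit = True
            else:
                new.append(g)
        if not hit:
            raise GateConfigError(f"no gate {feature} {comparator} in set {self.label}")
        return replace(self, gates=tuple(new))


@dataclass(frozen=True)
class CellCall:
    event_id: int
    label: str   # CTC | CHC | OTHER
    method: str  # AUTOMATED | MANUAL_EMULATED


def default_gates() -> tuple[GateSet, GateSet]:
    """The shipped CTC (8 gates) and CHC (12 gates) sets; see module docs."""
    ctc = GateSet(
        CTC,
        (
            Gate("cd45_mean", "<=", 5.0),
            Gate("dapi_mean", ">", 45.0),
            Gate("ck_mean", ">", 60.0),
            Gate("ck_size", ">", 16.0),
            Gate("ck_size", "<=", 400.0),
            Gate("ck_dapi_overlay", ">", 0.2),
            Gate("marker1_mean", "<=", 5.0),
            Gate("marker2_mean", "<=", 5.0),
        ),
    )
    chc = GateSet(
        CHC,
        (
            Gate("cd45_mean", ">", 30.0),
            Gate("cd45_max", ">", 50.0),
            Gate("dapi_mean", ">", 45.0),
            Gate("ck_mean", ">", 60.0),
            Gate("ck_size", ">", 16.0),
            Gate("ck_size", "<=", 400.0),
            Gate("ck_dapi_overlay", ">", 0.2),
            Gate("marker1_mean", "<=", 5.0),
            Gate("marker2_mean", "<=", 5.0),
            Gate("cd45_dapi_overlay", ">", 0.2),
            Gate("cd45_size", ">", 16.0),
            Gate("cd45_size", "<=", 400.0),
        ),
    )
    return ctc, chc


def _feasible_interval(gates: Iterable[Gate]) -> tuple[float, bool, float, bool]:
    """(low, low_open, high, high_open) interval satisfying all gates."""
    low, low_open = -math.inf, False
    high, high_open = math.inf, False
    for g in gates:
        t = g.threshold
        if g.comparator in (">", ">="):
            if t > low or (t == low and g.comparator == ">" and not low_open):
                low, low_open = t, g.comparator == ">"
        else:
            if t < high or (t == high and g.comparator == "<" and not high_open):
                high, high_open = t, g.comparator == "<"
    return low, low_open, high, high_open


def _interval_empty(iv: tuple[float, bool, float, bool]) -> bool:
    low, low_open, high, high_open = iv
    if low > high:
        return True
    if low == high and (low_open or high_open):
        return True
    return False


def validate_mutually_exclusive(ctc: GateSet, chc: GateSet) -> None:
    """Raise :class:`GateConfigError` unless no event can satisfy both sets.

    Gates constrain features independently, so joint infeasibility holds iff
    some feature's combined interval (CTC gates AND CHC gates) is empty.
    """
    features = {g.feature for g in ctc.gates} | {g.feature for g in chc.gates}
    for feat in features:
        combined = [g for g in ctc.gates + chc.gates if g.feature == feat]
        if _interval_empty(_feasible_interval(combined)):
            return
    raise GateConfigError(
        "CTC and CHC gate sets are not mutually exclusive: some feature vector "
        "could satisfy both"
    )


def classify_event(
    features: EventFeatures,
    ctc_gates: GateSet | None = None,
    chc_gates: GateSet | None = None,
) -> CellCall:
    """Label one event CTC, CHC or OTHER under conjunctive gate sets."""
    if ctc_gates is None or chc_gates is None:
        d_ctc, d_chc = default_gates()
        ctc_gates = ctc_gates or d_ctc
        chc_gates = chc_gates or d_chc
    if ctc_gates.passes(features):
        label = CTC
    elif chc_gates.passes(features):
        label = CHC
    else:
        label = OTHER
    return CellCall(event_id=features.event_id, label=label, method=AUTOMATED)


@dataclass(frozen=True)
class ManualReviewConfig:
    """Operationalized gallery-review criteria (all thresholds in AU / um)."""

    min_diameter_um: float = 4.0
    dapi_visible_au: float = 45.0   #: "visible nucleus"
    ck_positive_au: float = 60.0    #: CK-positive
    cd45_positive_au: float = 30.0  #: CD45-positive (hybrid criterion)
    cd45_negative_au: float = 5.0   #: CD45-negative ceiling (tumor criterion)
    flip_to_other_prob: float = 0.0  #: operator-noise model


def classify_manual_emulated(
    features: EventFeatures,
    config: ManualReviewConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CellCall:
    """Emulate a trained reviewer's call on one gallery event.

    The qualitative criteria map to: equivalent-circle diameter of the CK
    object > 4 um; nucleus visible when ``dapi_mean`` exceeds the visibility
    threshold; CK/CD45 positivity as channel means above their thresholds;
    CD45 negativity as mean at or below the ceiling.  With
    ``flip_to_other_prob > 0`` each call is flipped to OTHER with that
    probability (seeded through ``rng``) to emulate operator variability.
    """
    config = config or ManualReviewConfig()
    diameter = 2.0 * math.sqrt(max(features.ck_size, 0.0) / math.pi)
    big_enough = diameter > config.min_diameter_um
    nucleus = features.dapi_mean > config.dapi_visible_au
    ck_pos = features.ck_mean > config.ck_positive_au
    cd45_pos = features.cd45_mean > config.cd45_positive_au
    cd45_neg = features.cd45_mean <= config.cd45_negative_au

    if big_enough and nucleus and ck_pos and cd45_neg:
        label = CTC
    elif big_enough and nucleus and ck_pos and cd45_pos:
        label = CHC
    else:
        label = OTHER

    if config.flip_to_other_prob > 0 and label != OTHER:
        if rng is None:
            raise ValueError("operator-noise model requires a seeded rng")
        if rng.random() < config.flip_to_other_prob:
            label = OTHER
    return CellCall(event_id=features.event_id, label=label, method=MANUAL_EMULATED)


# ---------------------------------------------------------------------------
# Gate config (de)serialization


def gates_to_dict(ctc: GateSet, chc: GateSet) -> dict:
    return {
        s.label: [
            {"feature": g.feature, "comparator": g.comparator, "threshold": g.threshold}
            for g in s.gates
        ]
        for s in (ctc, chc)
    }


def gates_from_dict(data: dict) -> tuple[GateSet, GateSet]:
    sets = {}
    for label in (CTC, CHC):
        if label not in data:
            raise GateConfigError(f"gate config missing {label!r} section")
        gates = tuple(
            Gate(g["feature"], g["comparator"], float(g["threshold"]))
            for g in data[label]
        )
        sets[label] = GateSet(label, gates)
    validate_mutually_exclusive(sets[CTC], sets[CHC])
    return sets[CTC], sets[CHC]


def save_gates(ctc: GateSet, chc: GateSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(gates_to_dict(ctc, chc), fh, indent=2)
    return path


def load_gates(path: str | Path) -> tuple[GateSet, GateSet]:
    """Load a JSON/YAML gate config; exclusivity is checked here, at load."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    return gates_from_dict(data)
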