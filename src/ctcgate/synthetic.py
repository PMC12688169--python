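"""Synthetic cartridges and cohorts with known ground truth.

Two generators make every downstream stage testable without patient data:

* :func:`simulate_cartridge` renders multi-channel fields of view with
  planted, labeled cells.  Each cell class carries the immunophenotype the
  stain chemistry implies — CTC: DAPI+/CK+/CD45-; CHC (hybrid):
  DAPI+/CK+/CD45+; WBC (leukocyte): DAPI+/CD45+/CK-; DEBRIS: anucleate CK
  fragments.  Cells are hard disks convolved with a Gaussian point spread,
  added to a background with a linear gradient, then Poisson shot noise and
  Gaussian read noise are applied.  The same seed reproduces the stack
  bit for bit.

* :func:`simulate_cohort` draws per-patient manual/automated CTC and CHC
  counts from a zero-inflated negative binomial (rare-cell counts are
  strongly zero-inflated and overdispersed: cohort medians of 0-1 coexist
  with four-digit totals concentrated in a few patients), couples the two
  methods through a shared latent true count observed via independent
  binomial thinning plus additive false positives, and attaches survival:
  exponential baseline hazard with a proportional-hazards effect on the
  indicator (true count >= cutoff), with independent uniform censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import draw

from .cartridge_io import CartridgeStack, ChannelFrame
from .detection import EventFeatures
from .gating import CHC, CTC, OTHER, CellCall

CELL_CLASSES = ("CTC", "CHC", "WBC", "DEBRIS")

#: Channels each cell class stains in.
CLASS_CHANNELS = {
    "CTC": ("DAPI", "CK"),
    "CHC": ("DAPI", "CK", "CD45"),
    "WBC": ("DAPI", "CD45"),
    "DEBRIS": ("CK",),
}


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic cartridge.

    Defaults emulate bright, well-stained galleries: stained events sit far
    above a few-AU background, cell radii span the 2.5-4.5 um of small
    epithelial cells (leukocytes slightly larger, debris smaller), and the
    optics blur with a 0.8 um Gaussian point spread at 0.64 um/pixel.
    """

    n_ctc: int = 10
    n_chc: int = 5
    n_wbc: int = 200
    n_debris: int = 20
    frame_shape: tuple[int, int] = (600, 600)
    n_frames: int = 2
    pixel_size_um: float = 0.64
    #: per-class (min, max) radius in um
    radius_um: dict = field(
        default_factory=lambda: {
            "CTC": (2.5, 4.5),
            "CHC": (2.5, 4.5),
            "WBC": (3.0, 5.0),
            "DEBRIS": (1.0, 2.2),
        }
    )
    #: per-class, per-channel (mean, sd) peak amplitude in AU
    peak_au: dict = field(
        default_factory=lambda: {
            "CTC": {"DAPI": (140.0, 20.0), "CK": (160.0, 25.0)},
            "CHC": {"DAPI": (140.0, 20.0), "CK": (160.0, 25.0), "CD45": (140.0, 20.0)},
            "WBC": {"DAPI": (140.0, 20.0), "CD45": (140.0, 20.0)},
            "DEBRIS": {"CK": (90.0, 20.0)},
        }
    )
    blur_sigma_um: float = 0.8
    background_au: float = 3.0
    gradient_au: float = 2.0       #: linear ramp amplitude across the frame
    shot_noise: bool = True        #: Poisson noise on the expected image
    read_noise_sd: float = 2.0     #: Gaussian read noise, AU
    min_separation_um: float = 6.0  #: edge-to-edge clearance between cells
    density_cap: float = 0.30      #: max packing fraction of exclusion disks
    include_markers: bool = False  #: also emit (blank) MARKER1/MARKER2 pages
    seed: int = 0

    def n_cells(self) -> dict[str, int]:
        return {
            "CTC": self.n_ctc,
            "CHC": self.n_chc,
            "WBC": self.n_wbc,
            "DEBRIS": self.n_debris,
        }


@dataclass
class PlantedCell:
    cell_class: str
    frame_index: int
    center: tuple[float, float]  # (row, col), pixels
    radius_um: float
    peaks_au: dict[str, float]

    def radius_px(self, pixel_size_um: float) -> float:
        return self.radius_um / pixel_size_um


@dataclass
class CartridgeGroundTruth:
    cells: list[PlantedCell] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CELL_CLASSES}
        for cell in self.cells:
            out[cell.cell_class] += 1
        return out


class DensityError(ValueError):
    """Requested cells cannot be placed without exceeding the density cap."""


def true_mask(cell: PlantedCell, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(cell.center, cell.radius_px(pixel_size_um), shape=shape)
    mask[rr, cc] = True
    return mask


def _place_cells(spec: SimulationSpec, rng: np.random.Generator) -> list[PlantedCell]:
    h, w = spec.frame_shape
    px = spec.pixel_size_um
    sep_px = spec.min_separation_um / px

    specs: list[tuple[str, float]] = []
    for cls, n in spec.n_cells().items():
        lo, hi = spec.radius_um[cls]
        for _ in range(n):
            specs.append((cls, float(rng.uniform(lo, hi))))
    rng.shuffle(specs)

    # density check: exclusion disks of radius r + sep/2 over all frames
    area = sum(math.pi * (r / px + sep_px / 2) ** 2 for _, r in specs)
    if area > spec.density_cap * h * w * spec.n_frames:
        raise DensityError(
            f"{len(specs)} cells need packing fraction "
            f"{area / (h * w * spec.n_frames):.2f} > cap {spec.density_cap}"
        )

    margin_px = 3 * spec.blur_sigma_um / px + 2
    placed: dict[int, list[tuple[float, float, float]]] = {
        i: [] for i in range(spec.n_frames)
    }
    cells: list[PlantedCell] = []
    for cls, r_um in specs:
        r_px = r_um / px
        lo = r_px + margin_px
        for attempt in range(10_000):
            fi = int(rng.integers(spec.n_frames))
            cy = float(rng.uniform(lo, h - lo))
            cx = float(rng.uniform(lo, w - lo))
            ok = all(
                math.hypot(cy - py, cx - px_) >= r_px + pr + sep_px
                for py, px_, pr in placed[fi]
            )
            if ok:
                placed[fi].append((cy, cx, r_px))
                peaks = {
                    ch: float(max(rng.normal(mu, sd), 1.0))
                    for ch, (mu, sd) in spec.peak_au[cls].items()
                }
                cells.append(
                    PlantedCell(
                        cell_class=cls,
                        frame_index=fi,
                        center=(cy, cx),
                        radius_um=r_um,
                        peaks_au=peaks,
                    )
                )
                break
        else:
            raise DensityError(
                f"could not place a {cls} cell after 10000 attempts; lower the "
                f"counts or raise the frame size"
            )
    return cells


def simulate_cartridge(
    spec: SimulationSpec, sample_id: str = "synthetic"
) -> tuple[CartridgeStack, CartridgeGroundTruth]:
    """Render one cartridge; returns the stack and its planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)
    h, w = spec.frame_shape
    px = spec.pixel_size_um
    sigma_px = spec.blur_sigma_um / px

    ramp = spec.gradient_au * (np.arange(w, dtype=float) / max(w - 1, 1))
    background = spec.background_au + np.tile(ramp, (h, 1))

    channels = ["DAPI", "CK", "CD45"] + (
        ["MARKER1", "MARKER2"] if spec.include_markers else []
    )
    frames: list[ChannelFrame] = []
    for fi in range(spec.n_frames):
        canvases = {ch: np.zeros((h, w), dtype=float) for ch in channels}
        for cell in cells:
            if cell.frame_index != fi:
                continue
            rr, cc = draw.disk(cell.center, cell.radius_px(px), shape=(h, w))
            for ch, peak in cell.peaks_au.items():
                canvases[ch][rr, cc] += peak
        for ch in channels:
            img = canvases[ch]
            if sigma_px > 0:
                img = ndimage.gaussian_filter(img, sigma_px)
            img = img + background
            if spec.shot_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if spec.read_noise_sd > 0:
                img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
            np.clip(img, 0, None, out=img)
            frames.append(ChannelFrame(channel_name=ch, pixels=img, frame_index=fi))

    stack = CartridgeStack(sample_id=sample_id, frames=frames, pixel_size_um=px)
    return stack, CartridgeGroundTruth(cells=cells)


def noise_free_spec(spec: SimulationSpec) -> SimulationSpec:
    """Copy of ``spec`` with blur, background and noise switched off.

    On the resulting image, the mean intensity inside each planted cell's
    true mask equals that cell's sampled peak exactly — the oracle the
    feature-extraction tests rely on.
    """
    from dataclasses import replace

    return replace(
        spec,
        blur_sigma_um=0.0,
        background_au=0.0,
        gradient_au=0.0,
        shot_noise=False,
        read_noise_sd=0.0,
    )


# ---------------------------------------------------------------------------
# Pipeline-vs-truth scoring


@dataclass
class RecoveryScore:
    """Pooled per-class detection+classification tallies and F1."""

    tp: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ("CTC", "CHC", "WBC")})
    fp: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ("CTC", "CHC", "WBC")})
    fn: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ("CTC", "CHC", "WBC")})

    def add(self, other: "RecoveryScore") -> None:
        for c in self.tp:
            self.tp[c] += other.tp[c]
            self.fp[c] += other.fp[c]
            self.fn[c] += other.fn[c]

    def f1(self, cls: str) -> float:
        tp, fp, fn = self.tp[cls], self.fp[cls], self.fn[cls]
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom else float("nan")


def predicted_class(features: EventFeatures, call: CellCall) -> str:
    """Evaluation label for one event: the gate call, else WBC for a
    nucleated CD45 object that is neither CTC nor CHC, else OTHER."""
    if call.label in (CTC, CHC):
        return call.label
    if features.cd45_size > 0 and features.dapi_size > 0:
        return "WBC"
    return OTHER


def score_recovery(
    features: Iterable[EventFeatures],
    calls: Iterable[CellCall],
    truth: CartridgeGroundTruth,
    pixel_size_um: float,
    match_slack_um: float = 2.0,
) -> RecoveryScore:
    """Match events to planted cells (optimal assignment, centroid distance
    capped at one cell radius + slack) and tally per-class TP/FP/FN."""
    features = list(features)
    calls = list(calls)
    preds = [predicted_class(f, c) for f, c in zip(features, calls)]
    score = RecoveryScore()

    matched_truth: dict[int, str | None] = {}
    matched_event: dict[int, int | None] = {i: None for i in range(len(features))}
    cells = truth.cells
    if cells and features:
        big = 1e9
        cost = np.full((len(cells), len(features)), big)
        for i, cell in enumerate(cells):
            limit = cell.radius_px(pixel_size_um) + match_slack_um / pixel_size_um
            for j, f in enumerate(features):
                if f.frame_index != cell.frame_index:
                    continue
                d = math.hypot(
                    f.centroid_y - cell.center[0], f.centroid_x - cell.center[1]
                )
                if d <= limit:
                    cost[i, j] = d
        rows, cols = optimize.linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < big:
                matched_truth[i] = preds[j]
                matched_event[j] = i

    for i, cell in enumerate(cells):
        cls = cell.cell_class
        if cls not in score.tp:
            continue  # DEBRIS has no positive prediction class
        pred = matched_truth.get(i)
        if pred == cls:
            score.tp[cls] += 1
        else:
            score.fn[cls] += 1
    for j, pred in enumerate(preds):
        if pred not in score.fp:
            continue
        i = matched_event[j]
        if i is None or cells[i].cell_class != pred:
            score.fp[pred] += 1
    return score


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CountModel:
    """Zero-inflated negative binomial for a latent per-patient count."""

    zero_inflation: float = 0.5   #: extra point mass at zero, in [0, 1]
    mean: float = 33.0            #: NB mean of the non-inflated component
    dispersion: float = 0.15      #: NB shape k; smaller = heavier tail

    def validate(self) -> None:
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.mean < 0 or self.dispersion <= 0:
            raise ValueError("mean must be >= 0 and dispersion > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self.validate()
        if self.mean == 0:
            return np.zeros(n, dtype=int)
        k = self.dispersion
        nb = rng.negative_binomial(k, k / (k + self.mean), size=n)
        zero = rng.random(n) < self.zero_inflation
        return np.where(zero, 0, nb).astype(int)

    def moments(self) -> tuple[float, float]:
        """Marginal (mean, variance) of the zero-inflated mixture."""
        pi, mu, k = self.zero_inflation, self.mean, self.dispersion
        m = (1 - pi) * mu
        var_nb = mu + mu**2 / k
        var = (1 - pi) * (var_nb + mu**2) - m**2
        return m, var


@dataclass
class CohortSimSpec:
    """Study conditions for a synthetic per-patient cohort table.

    Defaults mirror a 67-patient metastatic colorectal cohort with long
    retrospective follow-up: strongly zero-inflated CTC counts whose total
    is dominated by a few patients, low CHC counts with median ~1,
    exponential overall survival calibrated so the observed cohort median
    lands near 32 months, a hazard ratio of e^log_hr for patients whose
    true CTC count reaches the cutoff, and uniform independent censoring
    (~40% censored).
    """

    n_patients: int = 67
    ctc: CountModel = field(default_factory=CountModel)
    chc: CountModel = field(
        default_factory=lambda: CountModel(zero_inflation=0.35, mean=2.2, dispersion=0.8)
    )
    detection_p_manual: float = 0.85  #: binomial thinning, manual read
    detection_p_auto: float = 0.85    #: binomial thinning, automated read
    fp_rate_manual: float = 0.2       #: Poisson mean of additive false positives
    fp_rate_auto: float = 0.3
    os_scale_months: float = 95.0     #: exponential mean for the baseline group
    log_hr: float = math.log(2.9)     #: log hazard ratio for true count >= cutoff
    cutoff: int = 1
    censor_window_months: float | None = 170.0  #: uniform(0, w); None = none
    pfs_fraction: tuple[float, float] = (0.3, 0.8)  #: PFS = OS x U(a, b)
    seed: int = 0


@dataclass
class CohortGroundTruth:
    true_ctc: np.ndarray
    true_chc: np.ndarray
    true_status: np.ndarray  #: indicator true_ctc >= cutoff
    log_hr: float
    cutoff: int
    warnings: list[str] = field(default_factory=list)


_COVARIATE_LEVELS = {
    "sex": (("F", "M"), (0.343, 0.657)),
    "ras_status": (("wild-type", "mutated"), (0.418, 0.582)),
    "sidedness": (("left", "right", "rectum"), (0.388, 0.358, 0.254)),
    "grade": (("G1", "G2", "G3"), (0.015, 0.731, 0.254)),
    "nodes": (("N0", "N1", "N2"), (0.418, 0.313, 0.269)),
    "therapy_line": ((1, 2, 3, 4), (0.672, 0.179, 0.090, 0.059)),
    "ecog": ((0, 1, 2), (0.687, 0.224, 0.089)),
}
_SITE_PROBS = {"liver": 0.701, "lung": 0.493, "peritoneum": 0.179, "bone": 0.06}


def _observed_counts(
    true: np.ndarray, p: float, fp_rate: float, rng: np.random.Generator
) -> np.ndarray:
    detected = rng.binomial(true, p)
    false_pos = rng.poisson(fp_rate, size=true.shape)
    return (detected + false_pos).astype(int)


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Draw a cohort table with known count/survival structure."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    true_ctc = spec.ctc.sample(n, rng)
    true_chc = spec.chc.sample(n, rng)
    status = (true_ctc >= spec.cutoff).astype(int)

    ctc_manual = _observed_counts(true_ctc, spec.detection_p_manual, spec.fp_rate_manual, rng)
    ctc_auto = _observed_counts(true_ctc, spec.detection_p_auto, spec.fp_rate_auto, rng)
    chc_manual = _observed_counts(true_chc, spec.detection_p_manual, spec.fp_rate_manual, rng)
    chc_auto = _observed_counts(true_chc, spec.detection_p_auto, spec.fp_rate_auto, rng)

    scale = spec.os_scale_months * np.exp(-spec.log_hr * status)
    t = rng.exponential(scale)
    t = np.maximum(t, 0.05)
    if spec.censor_window_months is not None:
        c = rng.uniform(0.05, spec.censor_window_months, size=n)
        os_event = (t <= c).astype(int)
        os_months = np.minimum(t, c)
    else:
        os_event = np.ones(n, dtype=int)
        os_months = t
    frac = rng.uniform(*spec.pfs_fraction, size=n)
    pfs_months = np.maximum(os_months * frac, 0.05)
    pfs_event = os_event.copy()

    warnings: list[str] = []
    if os_event.sum() == 0:
        warnings.append("no events observed: survival effects are non-identifiable")
    if status.sum() in (0, n):
        warnings.append("one stratum is empty: the hazard ratio is non-identifiable")

    cols: dict[str, object] = {
        "patient_id": [f"P{i + 1:03d}" for i in range(n)],
    }
    for name, (levels, probs) in _COVARIATE_LEVELS.items():
        cols[name] = rng.choice(levels, size=n, p=np.asarray(probs) / sum(probs))
    sites = []
    for _ in range(n):
        chosen = [s for s, p in _SITE_PROBS.items() if rng.random() < p]
        sites.append(";".join(chosen) if chosen else "liver")
    cols["metastatic_sites"] = sites
    cols.update(
        ctc_manual=ctc_manual,
        ctc_auto=ctc_auto,
        chc_manual=chc_manual,
        chc_auto=chc_auto,
        os_months=np.round(os_months, 2),
        os_event=os_event,
        pfs_months=np.round(pfs_months, 2),
        pfs_event=pfs_event,
    )
    df = pd.DataFrame(cols)
    truth = CohortGroundTruth(
        true_ctc=true_ctc,
        true_chc=true_chc,
        true_status=status,
        log_hr=spec.log_hr,
        cutoff=spec.cutoff,
        warnings=warnings,
    )
    return df, truth
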