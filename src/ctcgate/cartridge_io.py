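"""Reading and writing cartridge image stacks, cohort tables and result reports.

A *cartridge* is one patient's scanned sample: a short stack of fields of
view (frames), each imaged in the nuclear (DAPI), epithelial (CK) and
leukocyte (CD45) fluorescence channels, optionally with two auxiliary marker
channels.  Cartridges are stored as multi-page TIFF files with a JSON
``ImageDescription`` tag per page carrying the channel name, frame index and
physical pixel size; this is the closest open analogue of the archive
exports produced by semi-automated rare-cell scanners and is readable by any
TIFF-aware tool.

Cohort tables (per-patient counts, survival outcomes and clinical
covariates) are plain CSV with a documented header; readers validate every
field against the controlled vocabularies in ``schema.json`` and never
silently coerce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("DAPI", "CK", "CD45", "MARKER1", "MARKER2")
REQUIRED_CHANNELS = ("DAPI", "CK", "CD45")

#: Physical scale assumed when a cartridge file carries no pixel-size tag.
#: Micrometre-denominated gates need an explicit scale; this default is a
#: documented, overridable constant rather than a hidden assumption.
DEFAULT_PIXEL_SIZE_UM = 0.64

SEX_LEVELS = ("F", "M")
RAS_LEVELS = ("wild-type", "mutated")
SIDEDNESS_LEVELS = ("left", "right", "rectum")
GRADE_LEVELS = ("G1", "G2", "G3")
NODE_LEVELS = ("N0", "N1", "N2")
THERAPY_LINES = (1, 2, 3, 4)
ECOG_LEVELS = (0, 1, 2)
METASTATIC_SITES = ("liver", "lung", "peritoneum", "bone")

COUNT_COLUMNS = ("ctc_manual", "ctc_auto", "chc_manual", "chc_auto")
SURVIVAL_COLUMNS = ("os_months", "os_event", "pfs_months", "pfs_event")


class CartridgeFormatError(ValueError):
    """A cartridge file violates the stack contract (missing channel/tag)."""


class CohortValidationError(ValueError):
    """A cohort table contains invalid rows; ``errors`` lists each offence."""

    def __init__(self, errors: list[tuple[Any, str, str]]):
        self.errors = errors
        lines = "; ".join(f"row {r}, field '{f}': {m}" for r, f, m in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid field(s): {lines}{more}")


@dataclass
class ChannelFrame:
    """One channel of one field of view; intensities in arbitrary units."""

    channel_name: str
    pixels: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        if self.channel_name not in CHANNELS:
            raise CartridgeFormatError(
                f"unknown channel {self.channel_name!r}; expected one of {CHANNELS}"
            )
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise CartridgeFormatError(
                f"channel {self.channel_name} frame {self.frame_index}: pixels must be 2-D"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise CartridgeFormatError(
                f"channel {self.channel_name} frame {self.frame_index}: non-finite pixels"
            )
        if np.any(self.pixels < 0):
            raise CartridgeFormatError(
                f"channel {self.channel_name} frame {self.frame_index}: negative pixels"
            )
        if self.frame_index < 0:
            raise CartridgeFormatError("frame_index must be >= 0")


@dataclass
class CartridgeStack:
    """All frames of one sample plus the physical pixel size (um/pixel)."""

    sample_id: str
    frames: list[ChannelFrame] = field(default_factory=list)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.frames:
            raise CartridgeFormatError(f"cartridge {self.sample_id!r} has no frames")
        if not (self.pixel_size_um > 0):
            raise CartridgeFormatError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )
        shape = self.frames[0].pixels.shape
        for fr in self.frames:
            if fr.pixels.shape != shape:
                raise CartridgeFormatError(
                    f"frame {fr.frame_index} channel {fr.channel_name}: shape "
                    f"{fr.pixels.shape} differs from {shape}"
                )
        for idx in self.frame_indices:
            present = {f.channel_name for f in self.frames if f.frame_index == idx}
            for ch in REQUIRED_CHANNELS:
                if ch not in present:
                    raise CartridgeFormatError(
                        f"frame {idx} is missing required channel {ch}"
                    )

    @property
    def frame_indices(self) -> list[int]:
        return sorted({f.frame_index for f in self.frames})

    def channels(self, frame_index: int) -> list[str]:
        return [f.channel_name for f in self.frames if f.frame_index == frame_index]

    def get_frame(self, frame_index: int, channel: str) -> ChannelFrame | None:
        for fr in self.frames:
            if fr.frame_index == frame_index and fr.channel_name == channel:
                return fr
        return None


def _sort_key(frame: ChannelFrame) -> tuple[int, int]:
    return frame.frame_index, CHANNELS.index(frame.channel_name)


def write_cartridge(stack: CartridgeStack, path: str | Path) -> Path:
    """Write ``stack`` as a multi-page TIFF readable by :func:`read_cartridge`."""
    stack.validate()
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for fr in sorted(stack.frames, key=_sort_key):
            meta = {
                "channel_name": fr.channel_name,
                "frame_index": fr.frame_index,
                "pixel_size_um": stack.pixel_size_um,
                "sample_id": stack.sample_id,
            }
            tif.write(fr.pixels, description=json.dumps(meta), contiguous=False)
    return path


def read_cartridge(path: str | Path) -> CartridgeStack:
    """Read a multi-page TIFF cartridge; validates channels and metadata."""
    path = Path(path)
    frames: list[ChannelFrame] = []
    sample_id = path.stem
    pixel_size = None
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            desc = page.tags.get("ImageDescription")
            if desc is None:
                raise CartridgeFormatError(f"page {i}: missing ImageDescription tag")
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError) as exc:
                raise CartridgeFormatError(
                    f"page {i}: ImageDescription is not valid JSON"
                ) from exc
            for key in ("channel_name", "frame_index"):
                if key not in meta:
                    raise CartridgeFormatError(f"page {i}: missing metadata key {key!r}")
            frames.append(
                ChannelFrame(
                    channel_name=meta["channel_name"],
                    pixels=page.asarray(),
                    frame_index=int(meta["frame_index"]),
                )
            )
            sample_id = meta.get("sample_id", sample_id)
            if "pixel_size_um" in meta:
                pixel_size = float(meta["pixel_size_um"])
    if pixel_size is None:
        pixel_size = DEFAULT_PIXEL_SIZE_UM
    frames.sort(key=_sort_key)
    return CartridgeStack(sample_id=sample_id, frames=frames, pixel_size_um=pixel_size)


# ---------------------------------------------------------------------------
# Cohort tables


def _validate_row(idx: Any, row: pd.Series, errors: list) -> None:
    def bad(fieldname: str, msg: str) -> None:
        errors.append((idx, fieldname, msg))

    for col in COUNT_COLUMNS:
        if col not in row or pd.isna(row[col]):
            continue
        v = row[col]
        if float(v) != int(v) or int(v) < 0:
            bad(col, f"count must be a non-negative integer, got {v!r}")
    for col in ("os_months", "pfs_months"):
        if col in row and not pd.isna(row[col]):
            try:
                t = float(row[col])
            except (TypeError, ValueError):
                bad(col, f"non-numeric survival time {row[col]!r}")
                continue
            if not t > 0:
                bad(col, f"survival time must be > 0, got {t}")
    for col in ("os_event", "pfs_event"):
        if col in row and not pd.isna(row[col]):
            if float(row[col]) not in (0.0, 1.0):
                bad(col, f"event indicator must be 0 or 1, got {row[col]!r}")
    vocab = {
        "sex": SEX_LEVELS,
        "ras_status": RAS_LEVELS,
        "sidedness": SIDEDNESS_LEVELS,
        "grade": GRADE_LEVELS,
        "nodes": NODE_LEVELS,
    }
    for col, levels in vocab.items():
        if col in row and not pd.isna(row[col]) and row[col] not in levels:
            bad(col, f"unknown category {row[col]!r}; expected one of {levels}")
    if "therapy_line" in row and not pd.isna(row["therapy_line"]):
        try:
            line = int(row["therapy_line"])
        except (TypeError, ValueError):
            line = -1
        if line not in THERAPY_LINES:
            bad("therapy_line", f"must be in {THERAPY_LINES}, got {row['therapy_line']!r}")
    if "ecog" in row and not pd.isna(row["ecog"]):
        if int(row["ecog"]) not in ECOG_LEVELS:
            bad("ecog", f"must be in {ECOG_LEVELS}, got {row['ecog']!r}")
    if "metastatic_sites" in row and not pd.isna(row["metastatic_sites"]):
        for token in str(row["metastatic_sites"]).split(";"):
            token = token.strip()
            if token and token not in METASTATIC_SITES:
                bad("metastatic_sites", f"unknown site {token!r}")


def read_cohort_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a per-patient cohort CSV.

    Parameters
    ----------
    path
        CSV with a header row; missing values are empty fields.
    column_map
        Optional mapping from the file's column names to the canonical names
        documented in ``schema.json`` (e.g. ``{"CTC manual": "ctc_manual"}``).

    Raises
    ------
    CohortValidationError
        Listing every offending (row, field) pair; nothing is coerced.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "patient_id" not in df.columns:
        raise CohortValidationError([("header", "patient_id", "column missing")])
    errors: list[tuple[Any, str, str]] = []
    # Censoring status is never imputed: a survival-time column without its
    # event-indicator column makes hazard estimates meaningless.
    for tcol, ecol in (("os_months", "os_event"), ("pfs_months", "pfs_event")):
        if tcol in df.columns and ecol not in df.columns:
            errors.append(
                ("header", ecol, f"{tcol} present without {ecol}; censoring "
                                 "indicators are required, not imputed")
            )
    dupes = df["patient_id"][df["patient_id"].duplicated()]
    for idx, pid in dupes.items():
        errors.append((idx, "patient_id", f"duplicate patient id {pid!r}"))
    for idx, row in df.iterrows():
        _validate_row(idx, row, errors)
    if errors:
        raise CohortValidationError(errors)
    for col in COUNT_COLUMNS:
        if col in df.columns and df[col].notna().all():
            df[col] = df[col].astype(int)
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Reports


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_report(results: dict, path: str | Path) -> Path:
    """Serialize an analysis-results mapping to JSON (lossless for numerics)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, default=_jsonify, allow_nan=True)
    return path


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_schema() -> dict:
    """Return the shipped schema (column names, tag keys, vocabularies)."""
    with resources.files("ctcgate").joinpath("schema.json").open() as fh:
        return json.load(fh)
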