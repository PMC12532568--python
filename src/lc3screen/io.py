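"""Domain types and file I/O: image stacks, plate maps, results tables.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col) = (Y, X)``; ROIs are half-open
  ``[y0, y1) x [x0, x1)``.
* Stacks are ``(Z, Y, X)`` for single-channel data and ``(C, Y, X)`` for
  multi-channel planes.
* Areas are reported both in px^2 and um^2 (px^2 * pixel_size_um^2); relative
  areas are dimensionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, SchemaError, ValidationError

logger = logging.getLogger("lc3screen")

PHASES = ("pre_nh4cl", "post_nh4cl")
ROLES = ("vehicle", "treatment", "blank")

PLATEMAP_COLUMNS = ("plate", "well", "compound", "dose_um", "phase", "role", "toxic")

RESULTS_COLUMNS = (
    "plate",
    "well",
    "larva",
    "phase",
    "metric",
    "value",
    "units",
    "excluded",
    "exclusion_reason",
)


# ---------------------------------------------------------------------------
# ImageStack
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """A raw acquisition unit: 2D plane, Z-stack, or multi-channel plane.

    Parameters
    ----------
    pixels
        ``(Y, X)``, ``(Z, Y, X)`` or ``(C, Y, X)`` non-negative intensities.
    channels
        Ordered channel labels.  More than one label declares the leading
        axis to be channels rather than Z.
    pixel_size_um
        Physical pixel edge length in micrometres.
    meta
        Acquisition annotations (well id, magnification, phase, ...).
    """

    pixels: np.ndarray
    channels: list[str] = field(default_factory=lambda: ["ch0"])
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("stack intensities must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("stack intensities must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        if len(self.channels) > 1:
            if self.pixels.ndim != 3 or self.pixels.shape[0] != len(self.channels):
                raise ValidationError(
                    f"{len(self.channels)} channel labels but pixel axis 0 is "
                    f"{self.pixels.shape[0] if self.pixels.ndim == 3 else 'absent'}"
                )

    @property
    def n_planes(self) -> int:
        """Number of Z planes (1 for 2D or multi-channel planes)."""
        if self.pixels.ndim == 2 or len(self.channels) > 1:
            return 1
        return self.pixels.shape[0]

    def channel(self, label: str) -> np.ndarray:
        """Return the 2D plane for a named channel."""
        idx = self.channels.index(label)
        return self.pixels[idx] if len(self.channels) > 1 else np.atleast_2d(self.pixels)


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    channels: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    The axis order is normalized to ``(Z, Y, X)`` for stacks and ``(C, Y, X)``
    for RGB/multi-sample files.  The pixel size is taken from TIFF resolution
    metadata when present, else from ``pixel_size_um``.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta_px = _pixel_size_from_tiff(tif)
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc

    px = meta_px if meta_px is not None else pixel_size_um
    if px is None:
        raise ConfigurationError(
            f"{path}: no pixel size in TIFF metadata and no fallback configured"
        )

    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] not in (3, 4):
        # interleaved RGB(A) -> (C, Y, X)
        data = np.moveaxis(data, -1, 0)
        labels = channels or ["R", "G", "B", "A"][: data.shape[0]]
    elif data.ndim == 3:
        labels = channels or ["ch0"]
        if len(labels) > 1 and data.shape[0] != len(labels):
            raise ValidationError(
                f"{path}: declared {len(labels)} channels, file has {data.shape[0]} planes"
            )
    else:
        labels = channels or ["ch0"]
    return ImageStack(pixels=data, channels=list(labels), pixel_size_um=float(px), meta={"path": str(path)})


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack back to TIFF, embedding the pixel size as resolution."""
    res = 1.0 / stack.pixel_size_um  # pixels per micrometre
    tifffile.imwrite(
        Path(path),
        stack.pixels,
        resolution=(res, res),
        metadata={"unit": "um"},
    )


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Pixel edge length (um) from resolution tags, None when unit-less."""
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num <= 0 or den <= 0:
        return None
    per_unit = num / den
    unit = None
    meta = tif.shaped_metadata or ()
    if meta and isinstance(meta[0], dict):
        unit = meta[0].get("unit")
    if unit is None and tif.imagej_metadata:
        unit = tif.imagej_metadata.get("unit")
    if unit in ("um", "µm", "micron", "micrometer"):
        return 1.0 / per_unit
    resunit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 1
    resunit = int(resunit)
    if resunit == 3:  # pixels per centimetre
        return 1e4 / per_unit
    if resunit == 2:  # pixels per inch
        return 25.4e3 / per_unit
    return None  # RESUNIT.NONE without a metadata unit: no physical size


# ---------------------------------------------------------------------------
# PlateMap
# ---------------------------------------------------------------------------


@dataclass
class PlateMap:
    """Well-level treatment metadata for one or more plates.

    One row per (plate, well, phase): compound, dose (uM), role and a
    visual-inspection toxicity flag.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"plate map missing column(s): {', '.join(missing)}")
        dup = df.duplicated(subset=["plate", "well", "phase"])
        if dup.any():
            rows = df.loc[dup, ["plate", "well", "phase"]].iloc[0].tolist()
            raise ValidationError(f"duplicate plate-map row for {tuple(rows)}")
        bad_phase = set(df["phase"]) - set(PHASES)
        if bad_phase:
            raise ValidationError(f"unknown phase value(s): {sorted(bad_phase)}")
        bad_role = set(df["role"]) - set(ROLES)
        if bad_role:
            raise ValidationError(f"unknown role value(s): {sorted(bad_role)}")
        if (df["dose_um"] < 0).any():
            raise ValidationError("doses must be >= 0")
        if (df.loc[df["role"] == "vehicle", "dose_um"] != 0).any():
            raise ValidationError("vehicle rows must have dose 0")
        for plate, sub in df.groupby("plate"):
            if not (sub["role"] == "vehicle").any():
                raise ValidationError(f"plate {plate} has no vehicle well")

    def row_for(self, plate: str, well: str, phase: str) -> pd.Series:
        df = self.frame
        hit = df[(df["plate"] == plate) & (df["well"] == well) & (df["phase"] == phase)]
        if hit.empty:
            raise ValidationError(f"plate map has no row for ({plate}, {well}, {phase})")
        return hit.iloc[0]


def read_platemap(path: str | Path, vehicle_label: str = "DMSO") -> PlateMap:
    """Read and validate a plate-map CSV.

    Columns: ``plate,well,compound,dose_um,phase,role,toxic`` (``notes``
    optional).  Rows whose compound equals ``vehicle_label`` have their role
    inferred as ``vehicle`` when the role column is blank.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns and c != "role"]
    if missing:
        raise SchemaError(f"plate map missing column(s): {', '.join(missing)}")
    if "role" not in df.columns:
        df["role"] = np.where(df["compound"] == vehicle_label, "vehicle", "treatment")
    else:
        blank = df["role"].isna() | (df["role"].astype(str).str.strip() == "")
        df.loc[blank, "role"] = np.where(
            df.loc[blank, "compound"] == vehicle_label, "vehicle", "treatment"
        )
    df["toxic"] = df["toxic"].astype(bool)
    df["dose_um"] = df["dose_um"].astype(float)
    if "notes" not in df.columns:
        df["notes"] = ""
    return PlateMap(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# ResultsTable
# ---------------------------------------------------------------------------


@dataclass
class ResultsTable:
    """Long-format per-larva measurements keyed by (plate, well, larva, phase).

    Excluded larvae are retained as rows with ``excluded=True`` and an explicit
    ``exclusion_reason`` — exclusions are never silent deletions.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"results table missing column(s): {', '.join(missing)}")
        dup = df.duplicated(subset=["plate", "well", "larva", "phase", "metric"])
        if dup.any():
            raise ValidationError("duplicate (plate, well, larva, phase, metric) key")
        bad = df["excluded"] & (df["exclusion_reason"].fillna("") == "")
        if bad.any():
            raise ValidationError("excluded records must carry an exclusion reason")

    @classmethod
    def from_records(cls, records: list[dict]) -> "ResultsTable":
        df = pd.DataFrame.from_records(records, columns=list(RESULTS_COLUMNS))
        df["excluded"] = df["excluded"].fillna(False).astype(bool)
        df["exclusion_reason"] = df["exclusion_reason"].fillna("")
        return cls(df)

    @classmethod
    def empty(cls) -> "ResultsTable":
        return cls.from_records([])

    def included(self) -> pd.DataFrame:
        return self.frame[~self.frame["excluded"]]


def write_results(table: ResultsTable, path: str | Path) -> None:
    """Write a results CSV with stable column order; round-trips exactly."""
    df = table.frame.loc[:, list(RESULTS_COLUMNS)]
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> ResultsTable:
    df = pd.read_csv(
        path,
        dtype={"plate": str, "well": str, "phase": str, "metric": str, "units": str},
    )
    if df.empty and list(df.columns) != list(RESULTS_COLUMNS):
        raise SchemaError("results file lacks the expected header")
    df["excluded"] = df.get("excluded", False)
    if df["excluded"].dtype != bool:
        df["excluded"] = df["excluded"].astype(str).str.lower().isin(["true", "1"])
    df["exclusion_reason"] = df.get("exclusion_reason", "").fillna("")
    df["units"] = df["units"].fillna("")
    return ResultsTable(df)


def log_exclusion(plate: str, well: str, larva, phase: str, reason: str) -> None:
    """Log an exclusion with full identity — every dropped n is auditable."""
    logger.info("excluded plate=%s well=%s larva=%s phase=%s: %s", plate, well, larva, phase, reason)
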