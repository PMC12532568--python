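"""Two-channel ratiometric quantifications of mitophagy and membrane potential.

Covers the mito-QC mitophagy index (mCherry-only mitolysosomes over the total
mitochondrial signal), mtRosella DsRed/GFP, the TMRM/MitoTracker area ratio,
the JC-10 monomer/aggregate ratio, and the flow-cytometry LC3 flux formula
((+Lys inhibitor) - (-Lys inhibitor)) / (-Lys inhibitor).

The mito-QC reporter quenches GFP in acidic lysosomes, so mitolysosomes are
bright in mCherry but dark in GFP: they are called on the per-pixel
mCherry/(GFP + eps) ratio restricted to the mitochondrial mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import RatiometricsConfig
from .errors import UsageError, ValidationError


@dataclass
class TwoChannelField:
    """A two-channel confocal field (or stack plane).

    ``a`` carries the pH-stable / potential-sensitive channel (mCherry,
    DsRed, TMRM, JC-10 monomer), ``b`` the reference channel (GFP,
    MitoTracker, JC-10 aggregate).  The biological role of each channel is
    explicit in the caller's configuration — never inferred from wavelength.
    """

    a: np.ndarray
    b: np.ndarray
    pixel_size_um: float = 1.0
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValidationError("channels must share shape")
        for ch in (self.a, self.b):
            if not np.all(np.isfinite(ch)) or (ch.size and ch.min() < 0):
                raise ValidationError("intensities must be finite and >= 0")
        if self.roi is not None and self.roi.shape != self.a.shape:
            raise ValidationError("ROI mask must share the channel shape")


@dataclass
class RatiometricResult:
    """Outcome of one ratiometric quantification; absent values stay None."""

    mitophagy_index: float | None = None
    foci_count: int | None = None
    mitochondrial_area_px2: float | None = None
    mitolysosome_area_px2: float | None = None
    mode: str = "area_based"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.mitophagy_index is not None and self.mode == "area_based":
            if not (0.0 <= self.mitophagy_index <= 1.0):
                raise ValidationError("area-mode mitophagy index must lie in [0, 1]")
        if self.foci_count is not None and self.foci_count < 0:
            raise ValidationError("foci count must be >= 0")


def mitophagy_index(
    field: TwoChannelField,
    config: RatiometricsConfig | None = None,
    mito_threshold: float | None = None,
) -> RatiometricResult:
    """Mito-QC mitophagy index with mCherry-foci counting.

    The mitochondrial mask is thresholded on channel A (mCherry, Otsu unless
    ``mito_threshold`` is given).  Pixels whose A/(B+eps) ratio exceeds the
    mitolysosome threshold, in components of at least ``min_focus_area`` px^2,
    form the mitolysosome mask.  Area mode reports mitolysosome area over
    mitochondrial area; count mode reports foci over mitochondrial objects.
    The foci count is reported in both modes.
    """
    cfg = config or RatiometricsConfig()
    a, b = field.a, field.b
    if field.roi is not None:
        sel = field.roi.astype(bool)
    else:
        sel = np.ones(a.shape, dtype=bool)

    if mito_threshold is None:
        vals = a[sel]
        if vals.size == 0 or np.ptp(vals) == 0:
            return RatiometricResult(reason="empty mitochondrial mask", mode=cfg.mode)
        mito_threshold = threshold_otsu(vals)
    mito = sel & (a > mito_threshold)
    if not mito.any():
        return RatiometricResult(reason="empty mitochondrial mask", mode=cfg.mode)

    ratio = a / (b + cfg.ratio_epsilon)
    log_ratio = np.log(np.maximum(ratio, 1e-12))
    cut = _mitolysosome_cut(log_ratio[mito], cfg)
    lyso_px = mito & (log_ratio > cut)

    labels, n = ndimage.label(lyso_px)
    keep = np.zeros_like(lyso_px)
    count = 0
    if n:
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(lyso_px, labels, index=idx)
        for lab, area in zip(idx, areas):
            if area >= cfg.min_focus_area:
                keep[labels == lab] = True
                count += 1

    mito_area = float(mito.sum())
    lyso_area = float(keep.sum())
    if cfg.mode == "area_based":
        index = lyso_area / mito_area
    elif cfg.mode == "count_based":
        _, n_mito = ndimage.label(mito)
        index = count / n_mito if n_mito else None
    else:
        raise UsageError(f"unknown mitophagy index mode {cfg.mode!r}")
    return RatiometricResult(
        mitophagy_index=index,
        foci_count=count,
        mitochondrial_area_px2=mito_area,
        mitolysosome_area_px2=lyso_area,
        mode=cfg.mode,
    )


def _mitolysosome_cut(log_ratios: np.ndarray, cfg: RatiometricsConfig) -> float:
    """Log-ratio cut separating mitolysosomes from colocalized mitochondria.

    Default: Otsu on the log ratio within the mitochondrial mask.  A unimodal
    histogram (all-colocalized or all-mitolysosome fields) has no meaningful
    Otsu split, so when the Otsu classes are not separated by at least the
    fixed cut the absolute ratio cutoff is used instead.
    """
    fixed = float(np.log(cfg.ratio_threshold_value))
    if cfg.ratio_threshold_method == "absolute":
        return fixed
    if cfg.ratio_threshold_method != "otsu_log":
        raise UsageError(f"unknown ratio threshold method {cfg.ratio_threshold_method!r}")
    if np.ptp(log_ratios) == 0:
        return fixed
    cut = float(threshold_otsu(log_ratios))
    lo = log_ratios[log_ratios <= cut]
    hi = log_ratios[log_ratios > cut]
    if lo.size == 0 or hi.size == 0:
        return fixed
    # accept the Otsu split only when it separates a colocalized mode (below
    # the fixed cut) from a mitolysosome mode (above it); a unimodal field on
    # either side keeps the absolute cutoff
    if not (lo.mean() < fixed < hi.mean()):
        return fixed
    return cut


def rosella_ratio(field: TwoChannelField, roi: np.ndarray | None = None) -> float | None:
    """mtRosella mitophagy readout: mean DsRed / mean GFP over the ROI.

    DsRed is pH-insensitive, GFP is quenched in acidic compartments, so the
    ratio rises with mitophagy.  Returns None when the GFP mean is zero.
    """
    mask = roi if roi is not None else field.roi
    if mask is None:
        mask = np.ones(field.a.shape, dtype=bool)
    mask = mask.astype(bool)
    if not mask.any():
        raise UsageError("empty ROI")
    gfp = float(field.b[mask].mean())
    if gfp == 0:
        return None
    return float(field.a[mask].mean()) / gfp


def membrane_potential_ratio(
    field: TwoChannelField,
    tmrm_threshold: float | None = None,
    mito_threshold: float | None = None,
) -> float | None:
    """TMRM/MitoTracker area ratio: fraction of mitochondria still polarized.

    Channel A is TMRM (potential-dependent), channel B MitoTracker
    (potential-independent).  Each channel is segmented above its threshold
    (Otsu unless given); the ratio is TMRM-positive area over
    MitoTracker-positive area within the cell ROI.  Returns None when the
    MitoTracker mask is empty.
    """
    sel = field.roi.astype(bool) if field.roi is not None else np.ones(field.a.shape, bool)
    mito = _segment_channel(field.b, sel, mito_threshold)
    if mito is None or not mito.any():
        return None
    tmrm = _segment_channel(field.a, sel, tmrm_threshold)
    tmrm_area = float(tmrm.sum()) if tmrm is not None else 0.0
    return tmrm_area / float(mito.sum())


def _segment_channel(channel, sel, threshold):
    vals = channel[sel]
    if threshold is None:
        if vals.size == 0 or np.ptp(vals) == 0:
            return None
        threshold = threshold_otsu(vals)
    return sel & (channel > threshold)


def jc10_ratio(monomer, aggregate) -> float | None:
    """JC-10 depolarization readout: monomer / aggregate signal.

    Accepts scalars (per flow event or per cell) or images (mean intensity).
    Depolarization shifts JC-10 from aggregates to monomers, increasing the
    ratio.  Returns None when the aggregate signal is zero.
    """
    m = float(np.mean(monomer))
    a = float(np.mean(aggregate))
    if m < 0 or a < 0:
        raise UsageError("JC-10 signals must be >= 0")
    if a == 0:
        return None
    return m / a


def flow_flux(mfi_plus_inhibitor: float, mfi_minus_inhibitor: float) -> float:
    """Flow-cytometry LC3 flux: ((+Lys inhibitor) - (-Lys inhibitor)) / (-Lys inhibitor).

    Negative values are returned as-is (the caller flags them); a
    non-positive baseline MFI has no defined flux.
    """
    if mfi_minus_inhibitor <= 0:
        raise UsageError("baseline (-Lys inhibitor) MFI must be > 0")
    return (mfi_plus_inhibitor - mfi_minus_inhibitor) / mfi_minus_inhibitor
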