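"""Whole-larva detection and LC3-puncta segmentation.

The chain mirrors the screening workflow: larvae are located on a
low-magnification well image, a Z-stack of each body region is collapsed by
maximum projection, the projection is smoothed (median then Gaussian) and the
smoothed image subtracted to isolate punctate signal, the smoothed image is
binarized/cleaned/shrunk into the fish body mask, and puncta are the
background-subtracted objects above the body-mean threshold that lie within
the body mask.  The per-larva readout is the total puncta area relative to
body area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .config import LarvaConfig
from .errors import NoLarvaDetectedError, UsageError, ValidationError
from .io import ImageStack, ResultsTable, log_exclusion

DISPLACED_REASON = "displaced during acquisition"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BodyROI:
    """Analysis region of one detected larva.

    ``box`` is a half-open ``(y0, y1, x0, x1)`` bounding box of the body
    segment between the two anchors; the anchors sit ``head_tail_offset``
    pixels inward from the head-side and tail-side extremes of the silhouette
    along its principal axis.
    """

    box: tuple[int, int, int, int]
    anchor_head: tuple[float, float]
    anchor_tail: tuple[float, float]
    centroid: tuple[float, float]
    well: str = ""
    larva_index: int = 0

    def __post_init__(self) -> None:
        y0, y1, x0, x1 = self.box
        if not (0 <= y0 < y1 and 0 <= x0 < x1):
            raise ValidationError(f"degenerate ROI box {self.box}")


@dataclass
class SegmentationResult:
    """All intermediates of the puncta segmentation for one larva."""

    projection: np.ndarray
    smoothed: np.ndarray
    subtracted: np.ndarray
    body_mask: np.ndarray
    puncta_labels: np.ndarray
    objects: pd.DataFrame  # label, area, centroid_y, centroid_x, mean_intensity
    threshold: float

    def __post_init__(self) -> None:
        puncta = self.puncta_labels > 0
        if np.any(puncta & ~self.body_mask):
            raise ValidationError("puncta mask extends outside the body mask")

    @property
    def puncta_mask(self) -> np.ndarray:
        return self.puncta_labels > 0


@dataclass
class PunctaMeasurement:
    """Per-larva readout: body area, puncta count/area, relative puncta area."""

    body_area_px2: float
    body_area_um2: float
    puncta_count: int
    puncta_total_area_px2: float
    puncta_total_area_um2: float
    relative_puncta_area: float
    displaced: bool = False
    displaced_reason: str = ""

    def __post_init__(self) -> None:
        if not self.displaced and not (0.0 <= self.relative_puncta_area <= 1.0):
            raise ValidationError(
                f"relative puncta area {self.relative_puncta_area} outside [0, 1]"
            )

    @classmethod
    def displaced_larva(cls, reason: str = DISPLACED_REASON) -> "PunctaMeasurement":
        """A displaced larva carries no metrics — absent, not zero."""
        return cls(
            body_area_px2=np.nan,
            body_area_um2=np.nan,
            puncta_count=0,
            puncta_total_area_px2=np.nan,
            puncta_total_area_um2=np.nan,
            relative_puncta_area=np.nan,
            displaced=True,
            displaced_reason=reason,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def locate_larvae(
    lowmag: ImageStack | np.ndarray,
    max_larvae: int = 3,
    head_tail_offset: int = 20,
    min_area: int = 300,
    smooth_sigma: float = 2.0,
    min_contrast: float = 10.0,
) -> list[BodyROI]:
    """Detect larva silhouettes in a single-channel 2D well image.

    Returns at most ``max_larvae`` ROIs sorted by position (row-major centroid
    order) for stable larva indexing.  An empty well yields an empty list.  A
    larva whose silhouette is too short for the head/tail offset window (or
    truncated by the image border) is logged and not returned.
    """
    image = lowmag.pixels if isinstance(lowmag, ImageStack) else np.asarray(lowmag)
    well = lowmag.meta.get("well", "") if isinstance(lowmag, ImageStack) else ""
    if image.ndim != 2:
        raise UsageError("locate_larvae expects a single-channel 2D image")

    smoothed = ndimage.gaussian_filter(image.astype(float), smooth_sigma)
    if np.ptp(smoothed) < min_contrast:
        return []  # nothing above the detection threshold
    mask = smoothed > threshold_otsu(smoothed)
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = [i + 1 for i in np.argsort(areas)[::-1] if areas[i] >= min_area]
    keep = keep[:max_larvae]

    rois: list[BodyROI] = []
    for lab in keep:
        roi = _roi_from_component(labels == lab, head_tail_offset, image.shape, well)
        if roi is not None:
            rois.append(roi)
    rois.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for i, roi in enumerate(rois):
        roi.larva_index = i
    return rois


def _roi_from_component(
    component: np.ndarray, offset: int, shape: tuple[int, int], well: str
) -> BodyROI | None:
    ys, xs = np.nonzero(component)
    coords = np.column_stack([ys, xs]).astype(float)
    center = coords.mean(axis=0)
    centered = coords - center
    # principal axis of the silhouette = head-tail direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    t = centered @ axis
    t_min, t_max = t.min(), t.max()
    if t_max - t_min <= 2 * offset:
        log_exclusion("", well, "?", "", "larva too short for head/tail offset window")
        return None
    anchor_head = tuple(center + (t_max - offset) * axis)
    anchor_tail = tuple(center + (t_min + offset) * axis)
    inside = (t >= t_min + offset) & (t <= t_max - offset)
    seg = coords[inside]
    y0, x0 = np.floor(seg.min(axis=0)).astype(int)
    y1, x1 = np.ceil(seg.max(axis=0)).astype(int) + 1
    if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
        log_exclusion("", well, "?", "", "offset window does not fit in the image")
        return None
    return BodyROI(
        box=(int(y0), int(y1), int(x0), int(x1)),
        anchor_head=anchor_head,
        anchor_tail=anchor_tail,
        centroid=(float(center[0]), float(center[1])),
        well=well,
    )


def max_project(stack: ImageStack | np.ndarray, channel: str | None = None) -> np.ndarray:
    """Per-pixel maximum over Z; dtype preserved.

    Multi-channel stacks require an explicit ``channel`` selection.
    """
    if isinstance(stack, ImageStack):
        if len(stack.channels) > 1:
            if channel is None:
                raise UsageError("multi-channel stack: select a channel for projection")
            return stack.channel(channel)
        pixels = stack.pixels
    else:
        pixels = np.asarray(stack)
    if pixels.ndim == 2:
        return pixels.copy()
    if pixels.ndim != 3:
        raise UsageError(f"cannot project array of ndim {pixels.ndim}")
    return pixels.max(axis=0)


def compute_body_mask(
    projection: np.ndarray,
    smooth_sigma: float = 10.0,
    min_body_area: int = 5000,
    shrink_radius: int = 5,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    min_contrast: float = 10.0,
    well: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth the projection and derive the fish body mask.

    The smoothing is a 3x3 median filter followed by a Gaussian blur of
    ``smooth_sigma`` px — heavy enough that subtracting it removes the diffuse
    body signal while leaving puncta.  The smoothed image is binarized (Otsu
    by default), components below ``min_body_area`` are dropped, the largest
    remaining component is kept, and the result is eroded by a disk of
    ``shrink_radius`` px to give the final body mask.

    Raises :class:`NoLarvaDetectedError` when nothing body-sized is present;
    the caller turns this into a displaced-larva exclusion.
    """
    if projection.ndim != 2:
        raise UsageError("compute_body_mask expects a 2D projection")
    smoothed = ndimage.median_filter(projection.astype(float), size=3)
    smoothed = ndimage.gaussian_filter(smoothed, smooth_sigma)

    if threshold_method == "otsu":
        if np.ptp(smoothed) < min_contrast:
            raise NoLarvaDetectedError(well=well)
        thr = threshold_otsu(smoothed)
    elif threshold_method == "absolute":
        if threshold_value is None:
            raise UsageError("absolute body threshold requires threshold_value")
        thr = threshold_value
    else:
        raise UsageError(f"unknown body threshold method {threshold_method!r}")

    pre_mask = smoothed > thr
    labels, n = ndimage.label(pre_mask)
    if n == 0:
        raise NoLarvaDetectedError(well=well)
    areas = ndimage.sum_labels(pre_mask, labels, index=np.arange(1, n + 1))
    if areas.max() < min_body_area:
        raise NoLarvaDetectedError(well=well)
    cleaned = labels == (int(np.argmax(areas)) + 1)
    body = ndimage.binary_erosion(cleaned, structure=disk(shrink_radius))
    if not body.any():
        raise NoLarvaDetectedError(well=well)
    return smoothed, body


def segment_puncta(
    projection: np.ndarray,
    smoothed: np.ndarray,
    body_mask: np.ndarray,
    threshold_factor: float = 1.0,
    min_punctum_area: int = 4,
    containment: str = "fully_inside",
) -> SegmentationResult:
    """Segment LC3 puncta on the background-subtracted projection.

    ``subtracted = max(projection - smoothed, 0)`` is thresholded at
    ``T = threshold_factor * mean(smoothed | body)``; connected components of
    at least ``min_punctum_area`` px^2 that satisfy the containment rule with
    respect to the body mask become the final puncta, labeled ``1..n``.
    """
    if projection.shape != smoothed.shape or projection.shape != body_mask.shape:
        raise UsageError("projection, smoothed and body mask must share shape")
    if not body_mask.any():
        raise UsageError("empty body mask")
    if containment not in ("fully_inside", "centroid_inside"):
        raise UsageError(f"unknown containment rule {containment!r}")

    subtracted = np.clip(projection.astype(float) - smoothed, 0, None)
    threshold = threshold_factor * float(smoothed[body_mask].mean())
    pre_labels, n = ndimage.label(subtracted > threshold)

    kept = np.zeros_like(pre_labels)
    records = []
    next_label = 0
    if n:
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(pre_labels > 0, pre_labels, index=idx)
        inside_areas = ndimage.sum_labels(body_mask.astype(float), pre_labels, index=idx)
        centroids = ndimage.center_of_mass(pre_labels > 0, pre_labels, index=idx)
        means = ndimage.mean(projection.astype(float), pre_labels, index=idx)
        for lab, area, inside, (cy, cx), mi in zip(idx, areas, inside_areas, centroids, means):
            if area < min_punctum_area:
                continue
            if containment == "fully_inside":
                ok = inside == area
            else:
                ok = body_mask[int(round(cy)), int(round(cx))]
            if not ok:
                continue
            next_label += 1
            kept[pre_labels == lab] = next_label
            records.append(
                {
                    "label": next_label,
                    "area": float(area),
                    "centroid_y": float(cy),
                    "centroid_x": float(cx),
                    "mean_intensity": float(mi),
                }
            )
    objects = pd.DataFrame.from_records(
        records, columns=["label", "area", "centroid_y", "centroid_x", "mean_intensity"]
    )
    return SegmentationResult(
        projection=np.asarray(projection),
        smoothed=smoothed,
        subtracted=subtracted,
        body_mask=body_mask,
        puncta_labels=kept,
        objects=objects,
        threshold=threshold,
    )


def measure_puncta(seg: SegmentationResult, pixel_size_um: float = 1.0) -> PunctaMeasurement:
    """Morphological readout: puncta total area relative to body area."""
    body_px2 = float(seg.body_mask.sum())
    total_px2 = float(seg.objects["area"].sum()) if len(seg.objects) else 0.0
    um2 = pixel_size_um**2
    return PunctaMeasurement(
        body_area_px2=body_px2,
        body_area_um2=body_px2 * um2,
        puncta_count=int(len(seg.objects)),
        puncta_total_area_px2=total_px2,
        puncta_total_area_um2=total_px2 * um2,
        relative_puncta_area=total_px2 / body_px2,
    )


# ---------------------------------------------------------------------------
# Per-well driver
# ---------------------------------------------------------------------------


def segment_larva(
    projection: np.ndarray, config: LarvaConfig, well: str | None = None
) -> SegmentationResult:
    """Body mask + puncta segmentation of one larva's projection."""
    smoothed, body = compute_body_mask(
        projection,
        smooth_sigma=config.smooth_sigma,
        min_body_area=config.min_body_area,
        shrink_radius=config.shrink_radius,
        threshold_method=config.body_threshold_method,
        threshold_value=config.body_threshold_value,
        min_contrast=config.min_contrast,
        well=well,
    )
    return segment_puncta(
        projection,
        smoothed,
        body,
        threshold_factor=config.threshold_factor,
        min_punctum_area=config.min_punctum_area,
        containment=config.containment,
    )


@dataclass
class _LarvaHit:
    roi: BodyROI
    measurement: PunctaMeasurement


def _analyze_stack(stack: ImageStack, config: LarvaConfig) -> list[_LarvaHit]:
    """Locate and measure every larva in one acquisition."""
    projection = max_project(stack)
    rois = locate_larvae(
        ImageStack(projection, pixel_size_um=stack.pixel_size_um, meta=stack.meta),
        max_larvae=config.max_larvae,
        head_tail_offset=config.head_tail_offset,
        min_area=config.min_body_area,
        min_contrast=config.min_contrast,
    )
    hits = []
    for roi in rois:
        y0, y1, x0, x1 = _pad_box(roi.box, config.shrink_radius + 10, projection.shape)
        crop = projection[y0:y1, x0:x1]
        try:
            seg = segment_larva(crop, config, well=stack.meta.get("well"))
        except NoLarvaDetectedError:
            continue
        hits.append(_LarvaHit(roi=roi, measurement=measure_puncta(seg, stack.pixel_size_um)))
    return hits


def _pad_box(box, pad, shape):
    y0, y1, x0, x1 = box
    return (max(0, y0 - pad), min(shape[0], y1 + pad), max(0, x0 - pad), min(shape[1], x1 + pad))


def _pair_rois(pre: list[_LarvaHit], post: list[_LarvaHit]) -> list[tuple[int | None, int | None]]:
    """Greedy nearest-centroid matching; ties by distance then lowest index."""
    pairs: list[tuple[int | None, int | None]] = []
    taken_post: set[int] = set()
    candidates = sorted(
        (
            (np.hypot(a.roi.centroid[0] - b.roi.centroid[0], a.roi.centroid[1] - b.roi.centroid[1]), i, j)
            for i, a in enumerate(pre)
            for j, b in enumerate(post)
        ),
    )
    taken_pre: set[int] = set()
    for _, i, j in candidates:
        if i in taken_pre or j in taken_post:
            continue
        taken_pre.add(i)
        taken_post.add(j)
        pairs.append((i, j))
    for i in range(len(pre)):
        if i not in taken_pre:
            pairs.append((i, None))
    for j in range(len(post)):
        if j not in taken_post:
            pairs.append((None, j))
    pairs.sort(key=lambda p: (p[0] if p[0] is not None else len(pre) + (p[1] or 0)))
    return pairs


_METRIC_UNITS = {
    "body_area_px2": "px2",
    "body_area_um2": "um2",
    "puncta_count": "count",
    "puncta_total_area_px2": "px2",
    "puncta_total_area_um2": "um2",
    "relative_puncta_area": "dimensionless",
}


def process_well(
    pre_stack: ImageStack,
    post_stack: ImageStack | None,
    platemap_row: pd.Series,
    config: LarvaConfig | None = None,
) -> ResultsTable:
    """Run the full chain for one well, both phases, all larvae.

    Larvae are paired across the two acquisitions by nearest ROI centroid.  A
    larva detectable in only one phase is emitted as a displaced exclusion for
    the pair — its metrics are flagged, never silently dropped.  With no
    post-NH4Cl stack (baseline-only screen), only pre-phase records are
    produced.
    """
    config = config or LarvaConfig()
    plate = str(platemap_row["plate"])
    well = str(platemap_row["well"])

    pre_hits = _analyze_stack(pre_stack, config)
    records: list[dict] = []

    def emit(larva: int, phase: str, m: PunctaMeasurement) -> None:
        if m.displaced:
            log_exclusion(plate, well, larva, phase, m.displaced_reason)
            records.append(
                dict(
                    plate=plate,
                    well=well,
                    larva=larva,
                    phase=phase,
                    metric="relative_puncta_area",
                    value=np.nan,
                    units="dimensionless",
                    excluded=True,
                    exclusion_reason=m.displaced_reason,
                )
            )
            return
        for metric, units in _METRIC_UNITS.items():
            records.append(
                dict(
                    plate=plate,
                    well=well,
                    larva=larva,
                    phase=phase,
                    metric=metric,
                    value=float(getattr(m, metric)),
                    units=units,
                    excluded=False,
                    exclusion_reason="",
                )
            )

    if post_stack is None:
        for k, hit in enumerate(pre_hits):
            emit(k, "pre_nh4cl", hit.measurement)
        return ResultsTable.from_records(records)

    post_hits = _analyze_stack(post_stack, config)
    for k, (i, j) in enumerate(_pair_rois(pre_hits, post_hits)):
        if i is not None and j is not None:
            emit(k, "pre_nh4cl", pre_hits[i].measurement)
            emit(k, "post_nh4cl", post_hits[j].measurement)
        elif i is not None:
            reason = f"{DISPLACED_REASON}: undetectable in post_nh4cl"
            emit(k, "pre_nh4cl", PunctaMeasurement.displaced_larva(reason))
            emit(k, "post_nh4cl", PunctaMeasurement.displaced_larva(reason))
        else:
            reason = f"{DISPLACED_REASON}: undetectable in pre_nh4cl"
            emit(k, "pre_nh4cl", PunctaMeasurement.displaced_larva(reason))
            emit(k, "post_nh4cl", PunctaMeasurement.displaced_larva(reason))
    return ResultsTable.from_records(records)
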