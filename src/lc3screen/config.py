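"""Configuration for every tunable in the analysis chain.

A single YAML or JSON document with one section per module.  Every threshold,
kernel size and factor used downstream lives here with its default, so a run
is fully reproducible from (images, plate map, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class LarvaConfig:
    """Tunables of the larva localization and puncta segmentation chain."""

    #: maximum larvae expected per well (three embryos are placed per well)
    max_larvae: int = 3
    #: anchor offset inward from the head/tail extremes, px (4x image)
    head_tail_offset: int = 20
    #: analysis-area half width around the mid-body anchor, px
    roi_half_size: int = 80
    #: minimum silhouette area for a larva at low magnification, px^2
    min_larva_area_lowmag: int = 300
    #: detection threshold: minimum image contrast (intensity units) before
    #: any object is called — blank wells fall below it
    min_contrast: float = 10.0
    #: Gaussian sigma of the body-smoothing blur, px (order of half body width)
    smooth_sigma: float = 10.0
    #: body binarization: "otsu" or "absolute"
    body_threshold_method: str = "otsu"
    #: absolute body threshold, used when body_threshold_method == "absolute"
    body_threshold_value: float | None = None
    #: minimum connected-component area kept as candidate body, px^2
    min_body_area: int = 5000
    #: erosion radius shrinking the cleaned mask to the final body mask, px
    shrink_radius: int = 5
    #: puncta threshold factor k in T = k * mean(smoothed | body)
    threshold_factor: float = 1.0
    #: minimum punctum area, px^2
    min_punctum_area: int = 4
    #: containment rule: "fully_inside" or "centroid_inside"
    containment: str = "fully_inside"


@dataclass
class ScreenConfig:
    """Tunables of the screen-level analytics."""

    #: compound label identifying vehicle wells in the plate map
    vehicle_label: str = "DMSO"
    #: group summary statistic: "mean" or "median"
    estimator: str = "mean"
    #: normalize each phase to its own vehicle ("per_phase") or both phases
    #: to the -NH4Cl vehicle ("pre_vehicle")
    normalization: str = "per_phase"
    #: hit call threshold on E_max (fold change vs vehicle, +NH4Cl)
    hit_fc_threshold: float = 1.5
    #: flat-series tolerance below which fit_ic50 reports "no transition"
    no_transition_range: float = 0.2


@dataclass
class RatiometricsConfig:
    """Tunables of the two-channel ratiometric quantifications."""

    #: mitolysosome calling on the A/(B+eps) ratio: "otsu_log" or "absolute"
    ratio_threshold_method: str = "otsu_log"
    #: absolute ratio cutoff; also the fallback when the log-ratio histogram
    #: is unimodal (all-colocalized or all-mitolysosome fields)
    ratio_threshold_value: float = 2.0
    #: epsilon added to the denominator channel, intensity units
    ratio_epsilon: float = 1.0
    #: minimum mitolysosome focus area, px^2
    min_focus_area: int = 4
    #: mitophagy index mode: "area_based" or "count_based"
    mode: str = "area_based"


@dataclass
class TracesConfig:
    """Tunables of the physiological trace summaries."""

    #: maximal-OCR convention: "mean_last3_before_raa" or "max_after_fccp"
    maximal_rule: str = "mean_last3_before_raa"
    #: nearest-timestamp alignment tolerance as a fraction of the median
    #: sampling interval (None -> half the median interval)
    align_tolerance_frac: float = 0.5
    #: activity score >= this value calls a worm active
    active_threshold: float = 0.5
    #: changed-pixel rule: "vacated" or "symmetric"
    activity_rule: str = "vacated"


@dataclass
class IOConfig:
    """I/O fallbacks."""

    #: pixel size used when TIFF metadata carries none, um per pixel edge
    pixel_size_um: float | None = None


@dataclass
class Config:
    io: IOConfig = field(default_factory=IOConfig)
    larva: LarvaConfig = field(default_factory=LarvaConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    ratiometrics: RatiometricsConfig = field(default_factory=RatiometricsConfig)
    traces: TracesConfig = field(default_factory=TracesConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "io": IOConfig,
    "larva": LarvaConfig,
    "screen": ScreenConfig,
    "ratiometrics": RatiometricsConfig,
    "traces": TracesConfig,
}


def load_config(path: str | Path | None = None) -> Config:
    """Load a config document, filling unspecified values with defaults.

    Accepts YAML or JSON; unknown sections or keys raise
    :class:`ConfigurationError` so typos never silently fall back to defaults.
    """
    cfg = Config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if doc is None:
        return cfg
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(doc).__name__}")
    for section, values in doc.items():
        if section not in _SECTIONS:
            raise ConfigurationError(f"unknown config section {section!r}")
        target = getattr(cfg, section)
        known = {f.name for f in dataclasses.fields(target)}
        for key, value in (values or {}).items():
            if key not in known:
                raise ConfigurationError(f"unknown key {section}.{key}")
            setattr(target, key, value)
    return cfg
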