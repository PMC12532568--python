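"""Physiological time-series summaries: Seahorse OCR metrics and worm activity.

OCR conventions follow the respirometry protocol: basal respiration is the
mean of the last three measurement points before the FCCP injection; maximal
respiration is either the post-FCCP maximum or the mean of the last three
points before rotenone + antimycin A (the figure-parity default);
nonmitochondrial respiration is the residual after R+AA.  Larvae whose
post-FCCP OCR never exceeds basal did not respond to the uncoupler and are
flagged excluded, never silently dropped.

Worm activity scores the fraction of bounding-box pixels covered by the worm
at t0 that are vacated by t1: a fully departed worm scores 1, an immobile
worm scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TracesConfig
from .errors import UsageError, ValidationError

FCCP = "FCCP"
RAA = "rotenone+antimycinA"


@dataclass
class OCRTrace:
    """An annotated oxygen-consumption time series for one well/chamber."""

    time_min: np.ndarray
    ocr: np.ndarray  # pmol O2 / min
    injections: dict = field(default_factory=dict)  # label -> time (min)
    subject: str = ""
    role: str = "treatment"  # or "control_chamber"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.time_min.shape != self.ocr.shape or self.time_min.ndim != 1:
            raise ValidationError("time and OCR must be matching 1D arrays")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if len(set(self.injections)) != len(self.injections):
            raise ValidationError("injection labels must be unique per trace")

    @classmethod
    def from_csv(cls, path, subject: str = "", role: str = "treatment") -> "OCRTrace":
        """Read a trace CSV with columns time_min, ocr, injection_label.

        Rows with an empty ``ocr`` value are injection-only markers: they
        annotate the injection time without contributing a measurement.
        """
        df = pd.read_csv(path)
        for col in ("time_min", "ocr"):
            if col not in df.columns:
                raise UsageError(f"trace CSV missing column {col!r}")
        injections = {}
        if "injection_label" in df.columns:
            marked = df[df["injection_label"].notna() & (df["injection_label"] != "")]
            for _, row in marked.iterrows():
                injections[str(row["injection_label"])] = float(row["time_min"])
        measured = df[df["ocr"].notna()]
        return cls(measured["time_min"].to_numpy(), measured["ocr"].to_numpy(), injections, subject, role)


@dataclass
class OCRSummary:
    """Derived respiration metrics for one trace."""

    basal: float
    maximal: float | None
    nonmitochondrial: float | None
    mitochondrial_basal: float | None
    maximal_rule: str
    excluded: bool
    exclusion_reason: str = ""


def ocr_summary(trace: OCRTrace, maximal_rule: str = "mean_last3_before_raa") -> OCRSummary:
    """Summarize basal / maximal / nonmitochondrial respiration.

    ``maximal_rule`` selects between the two conventions in use:
    ``"max_after_fccp"`` (maximum value observed after FCCP injection) and
    ``"mean_last3_before_raa"`` (mean of the last three points before the
    R+AA injection; the default).  The non-responder exclusion always uses
    the post-FCCP values: a trace whose OCR never exceeds basal after FCCP
    is flagged, with its metrics retained.
    """
    if FCCP not in trace.injections:
        raise UsageError("trace has no FCCP injection")
    t_fccp = trace.injections[FCCP]
    pre = trace.ocr[trace.time_min < t_fccp]
    if len(pre) < 3:
        raise UsageError("need at least 3 measurement points before FCCP")
    basal = float(np.mean(pre[-3:]))

    t_raa = trace.injections.get(RAA, np.inf)
    after_fccp = trace.ocr[(trace.time_min > t_fccp) & (trace.time_min < t_raa)]

    if maximal_rule == "max_after_fccp":
        maximal = float(after_fccp.max()) if len(after_fccp) else None
    elif maximal_rule == "mean_last3_before_raa":
        if np.isfinite(t_raa):
            window = trace.ocr[trace.time_min < t_raa][-3:]
            maximal = float(np.mean(window)) if len(window) else None
        else:
            maximal = float(np.mean(after_fccp[-3:])) if len(after_fccp) else None
    else:
        raise UsageError(f"unknown maximal rule {maximal_rule!r}")

    nonmito = None
    mito_basal = None
    if np.isfinite(t_raa):
        post_raa = trace.ocr[trace.time_min > t_raa]
        if len(post_raa):
            nonmito = float(np.mean(post_raa))
            mito_basal = basal - nonmito

    excluded = bool(len(after_fccp) and after_fccp.max() <= basal)
    return OCRSummary(
        basal=basal,
        maximal=maximal,
        nonmitochondrial=nonmito,
        mitochondrial_basal=mito_basal,
        maximal_rule=maximal_rule,
        excluded=excluded,
        exclusion_reason="did not respond to FCCP" if excluded else "",
    )


def normalize_to_control_chamber(
    treated: OCRTrace, control: OCRTrace, align_tolerance_min: float | None = None
) -> pd.DataFrame:
    """Normalize a titration trace to the parallel control chamber.

    Each treated point is matched to the nearest control timestamp (within
    half the median sampling interval unless a tolerance is given) and
    divided by the control-chamber baseline OCR at that step.  The resulting
    normalized series feeds the 4PL IC50 fit.
    """
    if align_tolerance_min is None:
        align_tolerance_min = 0.5 * float(np.median(np.diff(treated.time_min)))
    rows = []
    for t, v in zip(treated.time_min, treated.ocr):
        j = int(np.argmin(np.abs(control.time_min - t)))
        if abs(control.time_min[j] - t) > align_tolerance_min:
            continue
        baseline = control.ocr[j]
        if baseline <= 0:
            raise UsageError(f"control-chamber baseline <= 0 at t={control.time_min[j]} min")
        rows.append({"time_min": t, "ocr": v, "control_ocr": baseline, "normalized": v / baseline})
    if not rows:
        raise UsageError("no treated point aligns with the control chamber")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Worm activity
# ---------------------------------------------------------------------------


@dataclass
class ActivityRecord:
    """One worm's activity score between a frame pair."""

    worm_id: str
    timepoint_h: float
    score: float | None
    alive: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError("activity score must lie in [0, 1]")

    @property
    def effective_score(self) -> float | None:
        """Dead worms score 0 (flagged); missing worms have no score."""
        if self.score is None:
            return None
        return 0.0 if not self.alive else self.score


def activity_score(
    worm_mask_t0: np.ndarray, worm_mask_t1: np.ndarray, rule: str = "vacated"
) -> float | None:
    """Fraction of t0 worm pixels that changed by t1, clamped to [0, 1].

    The default ``"vacated"`` rule counts t0-covered pixels no longer covered
    at t1 — identical masks score 0, full departure from the box scores 1.
    The ``"symmetric"`` variant scores the symmetric difference against the
    union of both masks.  Returns None ("worm not found") for an empty t0
    mask.
    """
    m0 = np.asarray(worm_mask_t0, dtype=bool)
    m1 = np.asarray(worm_mask_t1, dtype=bool)
    if m0.shape != m1.shape:
        raise UsageError("mask pair must share the bounding-box frame")
    n0 = int(m0.sum())
    if n0 == 0:
        return None
    if rule == "vacated":
        score = float((m0 & ~m1).sum()) / n0
    elif rule == "symmetric":
        union = int((m0 | m1).sum())
        score = float((m0 ^ m1).sum()) / union
    else:
        raise UsageError(f"unknown activity rule {rule!r}")
    return min(max(score, 0.0), 1.0)


def active_fraction(
    records: list[ActivityRecord], active_threshold: float = 0.5
) -> pd.DataFrame:
    """Percentage of active animals per timepoint (score >= threshold)."""
    rows = []
    for rec in records:
        s = rec.effective_score
        if s is None:
            continue
        rows.append({"timepoint_h": rec.timepoint_h, "active": s >= active_threshold})
    if not rows:
        raise UsageError("no scored records")
    df = pd.DataFrame(rows)
    out = df.groupby("timepoint_h", as_index=False).agg(
        n=("active", "size"), active_pct=("active", lambda s: 100.0 * s.mean())
    )
    return out
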