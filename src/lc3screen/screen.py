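"""Screen-level analytics: vehicle normalization, autophagic flux, dose
response with toxicity masking, E_max ranking and 4PL IC50 fits.

Fold change (FC) for a (compound, dose, phase) group is the group mean
relative puncta area divided by the vehicle mean on the same plate and phase.
Autophagic flux compares accumulation with versus without the lysosomal
blocker NH4Cl: flux ratio = group mean(+NH4Cl) / group mean(-NH4Cl).  E_max
is the maximum +NH4Cl fold change across a compound's non-toxic doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import ScreenConfig
from .errors import FitError, NoTransitionError, UsageError, ValidationError
from .io import PlateMap, ResultsTable

TOXIC_SENTINEL = "TOXIC"


# ---------------------------------------------------------------------------
# Vehicle normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizedResponse:
    """Per-group fold changes vs vehicle with per-larva values retained.

    ``groups`` has one row per (plate, phase, compound, dose_um) with the
    group mean relative puncta area, the matching vehicle mean, the fold
    change and n; ``larvae`` keeps each larva's normalized value.
    """

    groups: pd.DataFrame
    larvae: pd.DataFrame

    def group(self, compound: str, dose_um: float, phase: str) -> pd.Series:
        g = self.groups
        hit = g[
            (g["compound"] == compound)
            & (g["dose_um"] == dose_um)
            & (g["phase"] == phase)
        ]
        if hit.empty:
            raise KeyError((compound, dose_um, phase))
        return hit.iloc[0]


def normalize_to_vehicle(
    records: ResultsTable,
    platemap: PlateMap,
    config: ScreenConfig | None = None,
    metric: str = "relative_puncta_area",
) -> NormalizedResponse:
    """Compute fold changes vs the vehicle group, within plate and phase.

    Displaced/excluded larvae are omitted from every mean.  A (plate, phase)
    stratum without vehicle larvae raises; a vehicle mean of zero leaves the
    stratum's fold changes absent (NaN) with a reason rather than infinite.
    """
    config = config or ScreenConfig()
    est = {"mean": "mean", "median": "median"}.get(config.estimator)
    if est is None:
        raise UsageError(f"unknown estimator {config.estimator!r}")

    df = records.included()
    df = df[df["metric"] == metric].copy()
    pm = platemap.frame[["plate", "well", "phase", "compound", "dose_um", "role", "toxic"]]
    merged = df.merge(pm, on=["plate", "well", "phase"], how="left", validate="m:1")
    if merged["compound"].isna().any():
        missing = merged.loc[merged["compound"].isna(), ["plate", "well", "phase"]].iloc[0]
        raise ValidationError(f"plate map has no row for {tuple(missing)}")

    # vehicle summary per (plate, phase) stratum
    veh = merged[merged["role"] == "vehicle"]
    strata = merged.groupby(["plate", "phase"]).size().index
    veh_means = veh.groupby(["plate", "phase"])["value"].agg(est)
    for stratum in strata:
        if stratum not in veh_means.index:
            raise ValidationError(f"stratum {stratum} has no vehicle larvae")

    if config.normalization == "per_phase":
        merged["vehicle_mean"] = merged.set_index(["plate", "phase"]).index.map(veh_means)
    elif config.normalization == "pre_vehicle":
        pre = veh_means.xs("pre_nh4cl", level="phase")
        merged["vehicle_mean"] = merged["plate"].map(pre)
    else:
        raise UsageError(f"unknown normalization {config.normalization!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        merged["normalized"] = np.where(
            merged["vehicle_mean"] > 0, merged["value"] / merged["vehicle_mean"], np.nan
        )

    grouped = (
        merged.groupby(["plate", "phase", "compound", "dose_um", "role"], as_index=False)
        .agg(
            group_mean=("value", est),
            vehicle_mean=("vehicle_mean", "first"),
            n=("value", "size"),
            any_toxic=("toxic", "any"),
        )
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        grouped["fold_change"] = np.where(
            grouped["vehicle_mean"] > 0,
            grouped["group_mean"] / grouped["vehicle_mean"],
            np.nan,
        )
    grouped["fc_reason"] = np.where(
        grouped["vehicle_mean"] > 0, "", "vehicle mean is 0"
    )
    larvae = merged[
        ["plate", "well", "larva", "phase", "compound", "dose_um", "value", "normalized"]
    ].copy()
    return NormalizedResponse(groups=grouped, larvae=larvae)


# ---------------------------------------------------------------------------
# Autophagic flux
# ---------------------------------------------------------------------------


def compute_flux(response: NormalizedResponse) -> pd.DataFrame:
    """Per-group flux summary across the two NH4Cl phases.

    One row per (plate, compound, dose): fold changes in both phases and the
    flux ratio = group mean(+NH4Cl) / group mean(-NH4Cl) of the raw relative
    puncta areas.  Groups measured in only one phase get an absent flux with
    a reason.
    """
    g = response.groups
    pre = g[g["phase"] == "pre_nh4cl"].set_index(["plate", "compound", "dose_um"])
    post = g[g["phase"] == "post_nh4cl"].set_index(["plate", "compound", "dose_um"])
    keys = pre.index.union(post.index)
    rows = []
    for key in keys:
        plate, compound, dose = key
        has_pre, has_post = key in pre.index, key in post.index
        row = {
            "plate": plate,
            "compound": compound,
            "dose_um": dose,
            "fc_pre_nh4cl": pre.loc[key, "fold_change"] if has_pre else np.nan,
            "fc_post_nh4cl": post.loc[key, "fold_change"] if has_post else np.nan,
            "n_pre": int(pre.loc[key, "n"]) if has_pre else 0,
            "n_post": int(post.loc[key, "n"]) if has_post else 0,
        }
        if has_pre and has_post and pre.loc[key, "group_mean"] > 0:
            row["flux_ratio"] = post.loc[key, "group_mean"] / pre.loc[key, "group_mean"]
            row["flux_reason"] = ""
        else:
            row["flux_ratio"] = np.nan
            row["flux_reason"] = (
                "missing phase" if not (has_pre and has_post) else "pre-phase mean is 0"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def flux_ratio(pre_values: np.ndarray, post_values: np.ndarray) -> float:
    """Flux ratio of two per-larva samples: mean(+NH4Cl) / mean(-NH4Cl)."""
    pre_values = np.asarray(pre_values, dtype=float)
    post_values = np.asarray(post_values, dtype=float)
    pre_mean = np.nanmean(pre_values)
    if not pre_mean > 0:
        raise UsageError("pre-NH4Cl mean must be > 0 to form a flux ratio")
    return float(np.nanmean(post_values) / pre_mean)


# ---------------------------------------------------------------------------
# Dose response, E_max, ranking
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseProfile:
    """Per-compound dose-response across both phases with toxicity masking."""

    compound: str
    doses_um: list[float]
    fc_post: list[float]  # +NH4Cl fold change per dose
    fc_pre: list[float]  # -NH4Cl fold change per dose
    toxic: list[bool]
    excluded: bool = False
    fit: "FourPLFit | None" = None

    @property
    def e_max(self) -> float | None:
        """Maximum +NH4Cl fold change over non-toxic doses; None if excluded."""
        valid = [fc for fc, tox in zip(self.fc_post, self.toxic) if not tox and np.isfinite(fc)]
        return max(valid) if valid else None

    @property
    def e_max_dose(self) -> float | None:
        """Lowest dose achieving E_max (the tie-break dose for ranking)."""
        e = self.e_max
        if e is None:
            return None
        for dose, fc, tox in zip(self.doses_um, self.fc_post, self.toxic):
            if not tox and np.isfinite(fc) and fc == e:
                return dose
        return None


def build_dose_response(
    response: NormalizedResponse, platemap: PlateMap | None = None
) -> list[DoseResponseProfile]:
    """Assemble per-compound profiles, doses ascending, toxic doses masked.

    Toxicity flags come from the plate map (visual-inspection calls); a
    compound whose doses are all toxic becomes an ``excluded`` profile with no
    E_max rather than disappearing.
    """
    g = response.groups
    treat = g[g["role"] == "treatment"]
    profiles = []
    for compound, sub in treat.groupby("compound"):
        doses = sorted(sub["dose_um"].unique())
        fc_post, fc_pre, toxic = [], [], []
        for dose in doses:
            at = sub[sub["dose_um"] == dose]
            post = at[at["phase"] == "post_nh4cl"]
            pre = at[at["phase"] == "pre_nh4cl"]
            fc_post.append(float(post["fold_change"].iloc[0]) if len(post) else np.nan)
            fc_pre.append(float(pre["fold_change"].iloc[0]) if len(pre) else np.nan)
            toxic.append(bool(at["any_toxic"].any()))
        profile = DoseResponseProfile(
            compound=str(compound),
            doses_um=[float(d) for d in doses],
            fc_post=fc_post,
            fc_pre=fc_pre,
            toxic=toxic,
        )
        profile.excluded = profile.e_max is None
        profiles.append(profile)
    return profiles


def rank_hits(
    profiles: list[DoseResponseProfile], hit_fc_threshold: float = 1.5
) -> pd.DataFrame:
    """Rank compounds by descending E_max (+NH4Cl).

    Ties are broken by the lower dose achieving E_max, then by compound name.
    The hit flag (E_max >= threshold) is threshold-dependent by construction.
    All-toxic compounds appear last, marked excluded.
    """
    rows = []
    for p in profiles:
        rows.append(
            {
                "compound": p.compound,
                "e_max": p.e_max if p.e_max is not None else np.nan,
                "e_max_dose_um": p.e_max_dose if p.e_max_dose is not None else np.nan,
                "excluded": p.excluded,
                "hit": (p.e_max is not None) and (p.e_max >= hit_fc_threshold),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["excluded", "e_max", "e_max_dose_um", "compound"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.index.name = "rank"
    return df.reset_index()


def export_heatmap_matrix(profiles: list[DoseResponseProfile]) -> pd.DataFrame:
    """Compound x dose matrix of +NH4Cl fold changes, rows ordered by E_max.

    Toxic cells carry the sentinel string ``"TOXIC"`` — distinct from missing
    fold changes, which stay NaN.
    """
    if not profiles:
        return pd.DataFrame()
    order = rank_hits(profiles)["compound"].tolist()
    doses = sorted({d for p in profiles for d in p.doses_um})
    by_name = {p.compound: p for p in profiles}
    data = {}
    for name in order:
        p = by_name[name]
        row = {}
        for dose in doses:
            if dose in p.doses_um:
                i = p.doses_um.index(dose)
                row[dose] = TOXIC_SENTINEL if p.toxic[i] else p.fc_post[i]
            else:
                row[dose] = np.nan
        data[name] = row
    mat = pd.DataFrame.from_dict(data, orient="index")
    mat.index.name = "compound"
    mat.columns.name = "dose_um"
    return mat


# ---------------------------------------------------------------------------
# 4PL IC50 fit
# ---------------------------------------------------------------------------


@dataclass
class FourPLFit:
    """Four-parameter logistic fit of an inhibition titration.

    response(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)
    """

    bottom: float
    top: float
    ic50: float
    hill: float
    residual_sd: float
    n: int

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValidationError("IC50 must be > 0")
        if self.bottom > self.top:
            raise ValidationError("4PL bottom must be <= top")

    def predict(self, doses: np.ndarray) -> np.ndarray:
        return _four_pl(np.asarray(doses, dtype=float), self.bottom, self.top, self.ic50, self.hill)


def _four_pl(x, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_ic50(
    doses_um: np.ndarray,
    responses: np.ndarray,
    no_transition_range: float = 0.2,
) -> FourPLFit:
    """Least-squares 4PL fit of normalized responses against dose.

    Deterministic initialization: top/bottom from the response extremes, IC50
    from the geometric mean of the doses bracketing the half response, Hill
    slope 1.  Responses spanning less than ``no_transition_range`` raise
    :class:`NoTransitionError` (monotonic-flat data carry no IC50).
    """
    x = np.asarray(doses_um, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("doses and responses must be matching 1D arrays")
    if len(np.unique(x[x > 0])) < 4:
        raise UsageError("need at least 4 positive dose levels spanning the transition")
    mask = x > 0
    x, y = x[mask], y[mask]

    y_top, y_bot = float(y.max()), float(y.min())
    if y_top - y_bot < no_transition_range:
        raise NoTransitionError(
            f"response range {y_top - y_bot:.3g} < {no_transition_range}: no inhibition transition"
        )

    half = 0.5 * (y_top + y_bot)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    below = np.nonzero(ys <= half)[0]
    ic50_init = float(np.sqrt(xs[below[0]] * xs[max(below[0] - 1, 0)])) if len(below) else float(np.median(xs))
    p0 = [y_bot, y_top, ic50_init, 1.0]
    bounds = ([-np.inf, -np.inf, 1e-12, 0.01], [np.inf, np.inf, np.inf, 20.0])
    try:
        popt, _ = curve_fit(_four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, ic50, hill = (float(v) for v in popt)
    if bottom > top:
        raise FitError("fitted curve is ascending: not an inhibition titration")
    resid = y - _four_pl(x, bottom, top, ic50, hill)
    return FourPLFit(
        bottom=bottom,
        top=top,
        ic50=ic50,
        hill=hill,
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        n=int(len(x)),
    )
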