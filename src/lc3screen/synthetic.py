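"""Seeded synthetic-data generators with exact ground truth.

Every input modality the toolkit consumes can be produced here with known
planted truth, so the whole chain is testable without any microscope:

* larva Z-stacks with planted bright puncta (:func:`make_larva_stack`) and
  low-magnification well images (:func:`make_well_image`),
* two-channel mito-QC fields with a planted mitolysosome area fraction
  (:func:`make_mitoqc_field`),
* plateaued OCR traces with injection steps (:func:`make_ocr_trace`) and
  titration pairs from a 4PL truth (:func:`make_titration_pair`),
* worm mask pairs with an exact vacated fraction (:func:`make_worm_frames`),
* whole screens of per-larva relative puncta areas (:func:`make_screen`) and
  paired flux groups (:func:`make_flux_groups`).

All generators are bit-deterministic for a fixed seed, and every planted
quantity (areas, fractions, fold changes, plateau levels) is exposed in the
returned :class:`GroundTruth` so downstream recovery tests never hard-code
expected numbers.

Noise model: Poisson shot noise plus additive Gaussian read noise for images;
lognormal between-larva biological variation for screen draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import UsageError
from .io import ImageStack, PlateMap, ResultsTable
from .ratiometrics import TwoChannelField
from .traces import FCCP, RAA, OCRTrace


@dataclass
class GroundTruth:
    """Planted objects and analytic expectations of one synthetic dataset."""

    objects: pd.DataFrame
    params: dict
    expectations: dict
    seed: int


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal draws with exact arithmetic mean ``mean`` and CV ``cv``."""
    if cv <= 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def _camera_noise(
    rng: np.random.Generator, clean: np.ndarray, read_noise_sd: float, shot_noise: bool
) -> np.ndarray:
    noisy = rng.poisson(clean).astype(float) if shot_noise else clean.astype(float)
    if read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, read_noise_sd, clean.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# Larva stacks
# ---------------------------------------------------------------------------


def make_larva_stack(
    n_puncta: int = 12,
    punctum_diameter: int = 4,
    snr: float = 3.0,
    body_area: float = 55_000.0,
    z_planes: int = 26,
    seed: int = 0,
    shape: tuple[int, int] = (288, 640),
    background: float = 20.0,
    body_level: float = 80.0,
    read_noise_sd: float = 3.0,
    shot_noise: bool = True,
    profile: str = "disk",
    margin: int = 14,
) -> tuple[ImageStack, GroundTruth]:
    """An elongated autofluorescent larva body with planted bright puncta.

    The body is an elongated ellipse of mid-level autofluorescence on a dark
    background, present in every Z plane; each punctum is placed in one
    random Z plane.  ``snr`` is the punctum peak amplitude relative to the
    clean body plateau (background + body level) — the signal-to-background
    contrast that governs detectability under a body-mean threshold.  Puncta
    are uniform-intensity disks by default so planted areas are exact
    (``profile="gaussian"`` renders Gaussian blobs instead; optics are not
    simulated).  Puncta are rejection-sampled to be non-overlapping and at
    least ``margin`` px inside the body edge; an infeasible packing raises.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    aspect = 2.75
    semi_b = np.sqrt(body_area / (np.pi * aspect))
    semi_a = aspect * semi_b
    cy, cx = ny / 2.0, nx / 2.0
    if semi_a * 2 + 10 > nx or semi_b * 2 + 10 > ny:
        raise UsageError("body does not fit in the image")

    yy, xx = np.mgrid[0:ny, 0:nx]
    body_mask = ((xx - cx) / semi_a) ** 2 + ((yy - cy) / semi_b) ** 2 <= 1.0
    inner_a, inner_b = semi_a - margin - punctum_diameter / 2, semi_b - margin - punctum_diameter / 2
    if inner_a <= 0 or inner_b <= 0:
        raise UsageError("margin leaves no room for puncta inside the body")

    amplitude = snr * (background + body_level)
    radius = punctum_diameter / 2.0

    centers: list[tuple[float, float]] = []
    min_sep = punctum_diameter + 3.0
    attempts = 0
    while len(centers) < n_puncta:
        attempts += 1
        if attempts > 20_000:
            raise UsageError(f"cannot pack {n_puncta} puncta inside the body")
        py = cy + rng.uniform(-inner_b, inner_b)
        px = cx + rng.uniform(-inner_a, inner_a)
        if ((px - cx) / inner_a) ** 2 + ((py - cy) / inner_b) ** 2 > 1.0:
            continue
        if any(np.hypot(py - qy, px - qx) < min_sep for qy, qx in centers):
            continue
        centers.append((py, px))

    clean = np.full((z_planes, ny, nx), background, dtype=float)
    clean[:, body_mask] += body_level

    records = []
    for k, (py, px) in enumerate(centers):
        z = int(rng.integers(0, z_planes))
        dist2 = (yy - py) ** 2 + (xx - px) ** 2
        if profile == "disk":
            blob = dist2 <= radius**2
            clean[z][blob] += amplitude
            area = int(blob.sum())
        elif profile == "gaussian":
            sigma = punctum_diameter / 2.355  # diameter as FWHM
            clean[z] += amplitude * np.exp(-dist2 / (2 * sigma**2))
            area = int(np.sum(dist2 <= radius**2))  # nominal FWHM-disk area
        else:
            raise UsageError(f"unknown punctum profile {profile!r}")
        records.append(
            {"type": "punctum", "z": z, "y": py, "x": px, "area_px2": area, "amplitude": amplitude}
        )

    pixels = _camera_noise(rng, clean, read_noise_sd, shot_noise)
    stack = ImageStack(pixels, pixel_size_um=0.65, meta={"magnification": "20x"})

    body_px = int(body_mask.sum())
    puncta_px = float(sum(r["area_px2"] for r in records))
    objects = pd.DataFrame.from_records(
        [{"type": "larva_body", "z": -1, "y": cy, "x": cx, "area_px2": body_px, "amplitude": body_level}]
        + records
    )
    truth = GroundTruth(
        objects=objects,
        params=dict(
            n_puncta=n_puncta,
            punctum_diameter=punctum_diameter,
            snr=snr,
            z_planes=z_planes,
            background=background,
            body_level=body_level,
            amplitude=amplitude,
            semi_a=semi_a,
            semi_b=semi_b,
            profile=profile,
        ),
        expectations=dict(
            body_area_px2=body_px,
            puncta_total_area_px2=puncta_px,
            relative_puncta_area=puncta_px / body_px,
            puncta_count=n_puncta,
        ),
        seed=seed,
    )
    return stack, truth


def make_well_image(
    n_larvae: int = 3,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    semi_a: float = 60.0,
    semi_b: float = 12.0,
    background: float = 10.0,
    body_level: float = 90.0,
    read_noise_sd: float = 3.0,
) -> tuple[ImageStack, GroundTruth]:
    """A low-magnification well image with up to three larva silhouettes.

    Larvae are elongated ellipses at random non-overlapping positions and
    orientations; the truth records each mid-body centre and pose.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    clean = np.full(shape, background, dtype=float)
    records = []
    placed: list[tuple[float, float]] = []
    pad = semi_a + 10
    attempts = 0
    while len(placed) < n_larvae:
        attempts += 1
        if attempts > 5000:
            raise UsageError(f"cannot place {n_larvae} larvae in the well")
        cy = rng.uniform(pad, ny - pad)
        cx = rng.uniform(pad, nx - pad)
        if any(np.hypot(cy - qy, cx - qx) < 2.2 * semi_a for qy, qx in placed):
            continue
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0
        clean[mask] += body_level
        placed.append((cy, cx))
        records.append(
            {"type": "larva_body", "y": cy, "x": cx, "theta": theta, "area_px2": int(mask.sum())}
        )
    pixels = _camera_noise(rng, clean, read_noise_sd, shot_noise=True)
    image = ImageStack(pixels, pixel_size_um=3.25, meta={"magnification": "4x"})
    truth = GroundTruth(
        objects=pd.DataFrame.from_records(records, columns=["type", "y", "x", "theta", "area_px2"]),
        params=dict(n_larvae=n_larvae, semi_a=semi_a, semi_b=semi_b),
        expectations=dict(n_larvae=n_larvae),
        seed=seed,
    )
    return image, truth


# ---------------------------------------------------------------------------
# mito-QC fields
# ---------------------------------------------------------------------------


def make_mitoqc_field(
    mitolysosome_fraction: float = 0.2,
    network_density: float = 0.04,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    background: float = 5.0,
    mcherry_level: float = 300.0,
    gfp_level: float = 280.0,
    read_noise_sd: float = 2.0,
) -> tuple[TwoChannelField, GroundTruth]:
    """A two-channel mitochondrial network with a planted mCherry-only fraction.

    Curvilinear mitochondria (thickened random walks) appear in both channels;
    a planted, connectivity-preserving subset of the network area is
    mCherry-only (GFP quenched: a mitolysosome).  The truth records the exact
    planted area fraction after pixel-level bookkeeping.
    """
    if not 0.0 <= mitolysosome_fraction <= 1.0:
        raise UsageError("mitolysosome_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    network = np.zeros(shape, dtype=bool)
    target_px = network_density * ny * nx
    while network.sum() < target_px:
        y, x = rng.uniform(20, ny - 20), rng.uniform(20, nx - 20)
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(int(rng.integers(40, 120))):
            theta += rng.normal(0, 0.3)
            y += np.sin(theta)
            x += np.cos(theta)
            iy, ix = int(round(y)), int(round(x))
            if not (1 <= iy < ny - 1 and 1 <= ix < nx - 1):
                break
            network[iy - 1 : iy + 2, ix - 1 : ix + 2] = True

    lyso = _plant_fraction(network, mitolysosome_fraction, rng)
    coloc = network & ~lyso

    a_clean = np.full(shape, background, dtype=float)
    a_clean[network] += mcherry_level
    b_clean = np.full(shape, background, dtype=float)
    b_clean[coloc] += gfp_level

    field_ = TwoChannelField(
        a=_camera_noise(rng, a_clean, read_noise_sd, shot_noise=True),
        b=_camera_noise(rng, b_clean, read_noise_sd, shot_noise=True),
        pixel_size_um=0.18,
    )
    network_px = int(network.sum())
    lyso_px = int(lyso.sum())
    truth = GroundTruth(
        objects=pd.DataFrame(
            [
                {"type": "mito_pixel", "area_px2": network_px},
                {"type": "mitolysosome", "area_px2": lyso_px},
            ]
        ),
        params=dict(
            mitolysosome_fraction=mitolysosome_fraction,
            network_density=network_density,
            mcherry_level=mcherry_level,
            gfp_level=gfp_level,
        ),
        expectations=dict(
            mitophagy_index=lyso_px / network_px if network_px else np.nan,
            mitochondrial_area_px2=network_px,
            mitolysosome_area_px2=lyso_px,
        ),
        seed=seed,
    )
    return field_, truth


def _plant_fraction(network: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Mark a connectivity-preserving subset of network pixels, ~fraction of area."""
    lyso = np.zeros_like(network)
    total = int(network.sum())
    target = int(round(fraction * total))
    if target == 0:
        return lyso
    if target >= total:
        return network.copy()
    labels, n = ndimage.label(network)
    order = rng.permutation(np.arange(1, n + 1))
    acc = 0
    for lab in order:
        comp = labels == lab
        size = int(comp.sum())
        if acc + size <= target:
            lyso |= comp
            acc += size
        else:
            need = target - acc
            if need > 0:
                lyso |= _carve_connected(comp, need)
            break
    return lyso


def _carve_connected(component: np.ndarray, n_pixels: int) -> np.ndarray:
    """Breadth-first carve of ``n_pixels`` connected pixels from a component."""
    ys, xs = np.nonzero(component)
    start = (ys[0], xs[0])
    out = np.zeros_like(component)
    frontier = [start]
    seen = {start}
    taken = 0
    while frontier and taken < n_pixels:
        y, x = frontier.pop(0)
        out[y, x] = True
        taken += 1
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                p = (y + dy, x + dx)
                if (
                    0 <= p[0] < component.shape[0]
                    and 0 <= p[1] < component.shape[1]
                    and component[p]
                    and p not in seen
                ):
                    seen.add(p)
                    frontier.append(p)
    return out


# ---------------------------------------------------------------------------
# OCR traces
# ---------------------------------------------------------------------------


def make_ocr_trace(
    basal_level: float = 210.0,
    uncoupled_level: float = 350.0,
    nonmito_level: float = 30.0,
    noise_sd: float = 5.0,
    responder: bool = True,
    seed: int = 0,
    interval_min: float = 5.0,
    n_basal: int = 10,
    n_uncoupled: int = 6,
    n_nonmito: int = 4,
) -> tuple[OCRTrace, GroundTruth]:
    """A plateaued respirometry trace with FCCP and R+AA injection steps.

    Respiration rates are sampled every ``interval_min`` minutes; a
    non-responder trace plateaus below basal after FCCP (its uncoupled level
    is forced to 70% of basal when not already below).
    """
    rng = np.random.default_rng(seed)
    if not responder and uncoupled_level >= basal_level:
        uncoupled_level = 0.7 * basal_level
    t_basal = interval_min * np.arange(1, n_basal + 1)
    t_fccp = t_basal[-1] + interval_min * 0.4
    t_unc = t_basal[-1] + interval_min * np.arange(1, n_uncoupled + 1)
    t_raa = t_unc[-1] + interval_min * 0.4
    t_post = t_unc[-1] + interval_min * np.arange(1, n_nonmito + 1)

    levels = np.concatenate(
        [
            np.full(n_basal, basal_level),
            np.full(n_uncoupled, uncoupled_level),
            np.full(n_nonmito, nonmito_level),
        ]
    )
    times = np.concatenate([t_basal, t_unc, t_post])
    ocr = levels + (rng.normal(0, noise_sd, levels.shape) if noise_sd > 0 else 0.0)
    trace = OCRTrace(times, ocr, injections={FCCP: float(t_fccp), RAA: float(t_raa)})
    truth = GroundTruth(
        objects=pd.DataFrame(),
        params=dict(
            basal_level=basal_level,
            uncoupled_level=uncoupled_level,
            nonmito_level=nonmito_level,
            noise_sd=noise_sd,
            responder=responder,
        ),
        expectations=dict(
            basal=basal_level,
            maximal=uncoupled_level,
            nonmitochondrial=nonmito_level,
            mitochondrial_basal=basal_level - nonmito_level,
            excluded=not responder,
        ),
        seed=seed,
    )
    return trace, truth


def make_titration_pair(
    ic50_um: float = 300.0,
    hill: float = 1.5,
    doses_um: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0),
    baseline: float = 200.0,
    bottom: float = 0.05,
    noise_sd: float = 2.0,
    seed: int = 0,
    interval_min: float = 2.0,
    points_per_step: int = 2,
) -> tuple[OCRTrace, OCRTrace, pd.DataFrame, GroundTruth]:
    """Paired treated/control chamber traces from a 4PL inhibition truth.

    The treated chamber receives incremental compound doses; the control
    chamber receives carrier only and stays at baseline.  Returns both
    traces, the dose schedule (time -> cumulative dose), and the 4PL truth.
    """
    rng = np.random.default_rng(seed)
    times, treated_vals, control_vals, dose_at = [], [], [], []
    t = 0.0
    for _ in range(3):  # pre-titration baseline
        t += interval_min
        times.append(t)
        dose_at.append(0.0)
    for dose in doses_um:
        for _ in range(points_per_step):
            t += interval_min
            times.append(t)
            dose_at.append(dose)
    for t_i, dose in zip(times, dose_at):
        frac = bottom + (1.0 - bottom) / (1.0 + (dose / ic50_um) ** hill) if dose > 0 else 1.0
        treated_vals.append(baseline * frac + rng.normal(0, noise_sd))
        control_vals.append(baseline + rng.normal(0, noise_sd))
    times_arr = np.asarray(times)
    treated = OCRTrace(times_arr, np.asarray(treated_vals), subject="treated")
    control = OCRTrace(times_arr, np.asarray(control_vals), subject="control", role="control_chamber")
    schedule = pd.DataFrame({"time_min": times_arr, "dose_um": dose_at})
    truth = GroundTruth(
        objects=pd.DataFrame(),
        params=dict(ic50_um=ic50_um, hill=hill, baseline=baseline, bottom=bottom, noise_sd=noise_sd),
        expectations=dict(ic50_um=ic50_um, hill=hill, top=1.0, bottom=bottom),
        seed=seed,
    )
    return treated, control, schedule, truth


# ---------------------------------------------------------------------------
# Worm frames
# ---------------------------------------------------------------------------


def make_worm_frames(
    displacement_fraction: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int] = (64, 96),
    worm_size: tuple[int, int] = (8, 40),
) -> tuple[tuple[np.ndarray, np.ndarray], GroundTruth]:
    """A worm blob at t0 and a displaced blob at t1 with an exact vacated fraction.

    Exactly ``round(fraction * n)`` of the t0 worm pixels are vacated at t1
    (the trailing columns), and the same number of fresh pixels are occupied
    ahead of the worm, so the planted activity score is exact by construction.
    """
    if not 0.0 <= displacement_fraction <= 1.0:
        raise UsageError("displacement_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    h, w = worm_size
    y0 = int(rng.integers(2, ny - h - 2))
    x0 = int(rng.integers(2, nx - 2 * w - 4))
    t0 = np.zeros(shape, dtype=bool)
    t0[y0 : y0 + h, x0 : x0 + w] = True
    n = int(t0.sum())
    k = int(round(displacement_fraction * n))

    ys, xs = np.nonzero(t0)
    order = np.lexsort((ys, xs))  # column-major: trailing columns vacate first
    vacate = (ys[order[:k]], xs[order[:k]])
    t1 = t0.copy()
    t1[vacate] = False
    # re-occupy ahead of the worm, never re-covering t0 pixels
    free = np.zeros(shape, dtype=bool)
    free[y0 : y0 + h, x0 + w :] = True
    fy, fx = np.nonzero(free)
    forder = np.lexsort((fy, fx))
    t1[fy[forder[:k]], fx[forder[:k]]] = True

    truth = GroundTruth(
        objects=pd.DataFrame(
            [{"type": "worm_blob", "y": y0, "x": x0, "area_px2": n, "vacated_px": k}]
        ),
        params=dict(displacement_fraction=displacement_fraction, worm_size=worm_size),
        expectations=dict(activity_score=k / n),
        seed=seed,
    )
    return (t0, t1), truth


# ---------------------------------------------------------------------------
# Screens and flux groups
# ---------------------------------------------------------------------------


def make_flux_groups(
    pre_mean: float = 0.03,
    flux_ratio: float = 1.5,
    noise_cv: float = 0.2,
    n_larvae: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Paired -NH4Cl / +NH4Cl relative-area samples with a planted flux ratio."""
    rng = np.random.default_rng(seed)
    pre = _lognormal(rng, pre_mean, noise_cv, n_larvae)
    post = _lognormal(rng, pre_mean * flux_ratio, noise_cv, n_larvae)
    truth = GroundTruth(
        objects=pd.DataFrame(),
        params=dict(pre_mean=pre_mean, flux_ratio=flux_ratio, noise_cv=noise_cv, n=n_larvae),
        expectations=dict(flux_ratio=flux_ratio),
        seed=seed,
    )
    return pre, post, truth


def make_screen(
    n_compounds: int = 20,
    active_indices: tuple[int, ...] = (0, 1),
    true_fc: float = 2.0,
    noise_cv: float = 0.2,
    n_larvae_per_group: int = 15,
    toxic_cells: tuple[tuple[int, float], ...] = (),
    seed: int = 0,
    doses_um: tuple[float, ...] = (10.0, 50.0, 100.0, 250.0),
    base_relative_area: float = 0.02,
    vehicle_flux: float = 1.5,
    pre_effect_fraction: float = 0.5,
    dose_ec50_um: float = 25.0,
    dose_hill: float = 2.0,
) -> tuple[ResultsTable, PlateMap, GroundTruth]:
    """A full one-plate screen of per-larva relative puncta areas.

    Each compound is tested at four ascending doses in both NH4Cl phases.
    Active compounds follow a sigmoidal dose dependence reaching ``true_fc``
    fold change over vehicle in the +NH4Cl phase (and a
    ``pre_effect_fraction`` of that effect at baseline); inactive compounds
    sit at fold change 1.  Per-larva draws are lognormal around the group
    means with CV ``noise_cv``.  ``toxic_cells`` are (compound index, dose)
    pairs flagged toxic in the plate map.  The truth records every group mean.
    """
    rng = np.random.default_rng(seed)
    plate = "P1"
    compounds = [f"C{i + 1:02d}" for i in range(n_compounds)]
    actives = {compounds[i] for i in active_indices}
    toxic = {(compounds[i], float(d)) for i, d in toxic_cells}

    phase_means = {"pre_nh4cl": base_relative_area, "post_nh4cl": base_relative_area * vehicle_flux}

    def dose_fc(dose: float, phase: str, active: bool) -> float:
        if not active:
            return 1.0
        top = true_fc if phase == "post_nh4cl" else 1.0 + (true_fc - 1.0) * pre_effect_fraction
        frac = dose**dose_hill / (dose**dose_hill + dose_ec50_um**dose_hill)
        return 1.0 + (top - 1.0) * frac

    records, pm_rows, truth_rows = [], [], []

    def add_group(well: str, compound: str, dose: float, role: str) -> None:
        is_toxic = (compound, dose) in toxic
        for phase in ("pre_nh4cl", "post_nh4cl"):
            fc = dose_fc(dose, phase, compound in actives) if role == "treatment" else 1.0
            mean = phase_means[phase] * fc
            values = _lognormal(rng, mean, noise_cv, n_larvae_per_group)
            for larva, value in enumerate(values):
                records.append(
                    dict(
                        plate=plate,
                        well=well,
                        larva=larva,
                        phase=phase,
                        metric="relative_puncta_area",
                        value=float(value),
                        units="dimensionless",
                        excluded=False,
                        exclusion_reason="",
                    )
                )
            pm_rows.append(
                dict(
                    plate=plate,
                    well=well,
                    compound=compound if role == "treatment" else "DMSO",
                    dose_um=dose,
                    phase=phase,
                    role=role,
                    toxic=is_toxic,
                    notes="",
                )
            )
            truth_rows.append(
                dict(compound=compound, dose_um=dose, phase=phase, true_mean=mean, true_fc=fc)
            )

    add_group("A01", "DMSO", 0.0, "vehicle")
    w = 0
    for compound in compounds:
        for dose in doses_um:
            w += 1
            add_group(f"W{w:03d}", compound, float(dose), "treatment")

    table = ResultsTable.from_records(records)
    platemap = PlateMap(pd.DataFrame(pm_rows))
    truth = GroundTruth(
        objects=pd.DataFrame(truth_rows),
        params=dict(
            n_compounds=n_compounds,
            active_indices=tuple(active_indices),
            true_fc=true_fc,
            noise_cv=noise_cv,
            n_larvae_per_group=n_larvae_per_group,
            doses_um=tuple(float(d) for d in doses_um),
            vehicle_flux=vehicle_flux,
        ),
        expectations=dict(
            active_compounds=sorted(actives),
            e_max_active=max(
                dose_fc(float(d), "post_nh4cl", True)
                for d in doses_um
                if (compounds[active_indices[0]], float(d)) not in toxic
            )
            if active_indices
            else np.nan,
            vehicle_flux=vehicle_flux,
        ),
        seed=seed,
    )
    return table, platemap, truth
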