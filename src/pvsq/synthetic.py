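"""Synthetic data with known ground truth.

Two generators back the test surface of the whole pipeline:

* :func:`generate_phantom` builds a T1w-like 3D volume — a bright
  white-matter compartment (thick-shelled ellipsoid) containing dark
  tube-like perivascular spaces, optional confounders (a catheter-like
  large tube, non-tubular hypointense blobs, sub-threshold speckle
  islands), acquisition blur, intensity noise and a global intensity
  scale — together with the WM mask and the exact ground-truth PVS
  mask/volume/ratio.

* :func:`generate_cohort` simulates a longitudinal exam table with the
  additive fixed-effect structure used by the full statistical model
  (time point, anesthesia, age, sex, radiation dose, shunt) plus a
  per-patient random intercept and residual noise. Its defaults encode
  the study conditions of the cohort the method was developed on:
  four time points (0M, 3M, 12M, FollowUp), 241 patients with per-TP
  retention 210/209/198/161, PVS-ratio group means near
  9.8/10.3/8.6/9.3 permil, anesthesia -0.5, shunt -1.1, male +0.6,
  age slope 0.18 permil/year, and dose offsets (RD baseline) SD +0.3,
  HD -0.4.

Everything is driven by a single integer seed; identical (spec, seed)
pairs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    BinaryMask3D,
    DOSE_LEVELS,
    TP_LEVELS,
    Volume3D,
    validate_cohort_frame,
)


class PhantomGeometryError(ValueError):
    """Raised when tubes cannot fit inside the WM compartment."""


@dataclass
class ConfounderFlags:
    catheter_tube: bool = False
    hypointense_blobs: bool = False
    speckle_islands: bool = False


@dataclass
class PhantomSpec:
    """Geometry and intensity model of a tube phantom.

    The WM compartment is a thick-shelled ellipsoid: an outer ellipsoid
    with semi-axes ``wm_outer_frac`` of the half-grid minus an inner
    cavity (ventricle-like) with semi-axes ``wm_inner_frac``. Tubes are
    mildly curved polylines rasterized by distance-to-centerline and
    kept strictly inside the compartment. Intensities: background near
    zero, cavity CSF-dark, WM bright, tubes/confounders dark; the clean
    image is blurred by a small point-spread sigma, Gaussian noise is
    added, and the whole volume is multiplied by ``global_scale``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wm_outer_frac: float = 0.84
    wm_inner_frac: float = 0.25
    n_tubes: int = 12
    tube_radius_range_mm: tuple[float, float] = (0.8, 1.2)
    tube_length_range_mm: tuple[float, float] = (8.0, 20.0)
    wm_intensity: float = 150.0
    pvs_intensity: float = 55.0
    csf_intensity: float = 30.0
    background_intensity: float = 10.0
    noise_sd: float = 1.5
    noise_smooth_sigma_vox: float = 0.0
    rician_noise: bool = False
    psf_sigma_vox: float = 0.5
    speckle_depth: float = 4.0
    global_scale: float = 1.0
    confounders: ConfounderFlags = field(default_factory=ConfounderFlags)

    def __post_init__(self) -> None:
        if isinstance(self.confounders, Mapping):
            self.confounders = ConfounderFlags(**self.confounders)
        if not self.global_scale > 0:
            raise ValueError("global_scale must be positive")
        if not self.pvs_intensity < self.wm_intensity:
            raise ValueError("PVS must be darker than WM on a T1w-like phantom")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be non-negative")
        lo, hi = self.tube_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("tube radius range must be positive and ordered")


@dataclass
class PhantomGroundTruth:
    pvs_mask: BinaryMask3D
    confounder_mask: BinaryMask3D
    true_pvs_volume_cm3: float
    true_pvs_ratio_permil: float


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _wm_compartment(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    center = [(s - 1) / 2.0 for s in shape]
    outer = [spec.wm_outer_frac * s / 2.0 for s in shape]
    inner = [spec.wm_inner_frac * s / 2.0 for s in shape]
    return _ellipsoid(shape, center, outer) & ~_ellipsoid(shape, center, inner)


def _stamp_tube(
    mask: np.ndarray,
    points: np.ndarray,
    radius_vox: float,
) -> None:
    """Mark voxels whose center lies within ``radius_vox`` of any
    centerline sample point (isotropic voxel units)."""
    shape = mask.shape
    r = radius_vox
    for p in points:
        lo = np.maximum(np.floor(p - r).astype(int), 0)
        hi = np.minimum(np.ceil(p + r).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        sub = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = (sub[0] - p[0]) ** 2 + (sub[1] - p[1]) ** 2 + (sub[2] - p[2]) ** 2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r


def _random_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    length_vox: float,
    allowed_dist: np.ndarray,
    radius_vox: float,
    n_segments: int = 3,
    max_bend_deg: float = 25.0,
    step: float = 0.25,
) -> np.ndarray | None:
    """A mildly curved centerline staying where ``allowed_dist`` exceeds
    the tube radius; None if it wanders out."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    seg_len = length_vox / n_segments
    pts = [start.astype(float)]
    pos = start.astype(float)
    for _ in range(n_segments):
        n_steps = max(int(round(seg_len / step)), 1)
        for _ in range(n_steps):
            pos = pos + direction * step
            idx = np.round(pos).astype(int)
            if np.any(idx < 0) or np.any(idx >= np.array(allowed_dist.shape)):
                return None
            if allowed_dist[tuple(idx)] <= radius_vox + 0.6:
                return None
            pts.append(pos.copy())
        # bounded random bend between segments
        bend = np.deg2rad(max_bend_deg)
        perturb = rng.normal(size=3)
        perturb -= perturb.dot(direction) * direction
        norm = np.linalg.norm(perturb)
        if norm > 0:
            angle = rng.uniform(0, bend)
            direction = direction * np.cos(angle) + (perturb / norm) * np.sin(angle)
            direction /= np.linalg.norm(direction)
    return np.asarray(pts)


def _place_tubes(
    rng: np.random.Generator,
    spec: PhantomSpec,
    wm: np.ndarray,
    n_tubes: int,
    radius_range_mm: tuple[float, float],
    length_range_mm: tuple[float, float],
    forbidden: np.ndarray,
    max_tries: int = 1500,
    n_segments: int = 3,
) -> np.ndarray:
    """Rasterize ``n_tubes`` non-touching tubes inside the WM shell."""
    spacing = float(np.mean(spec.voxel_size_mm))
    dist_in_wm = ndimage.distance_transform_edt(wm, sampling=spec.voxel_size_mm)
    out = np.zeros_like(wm)
    placed = 0
    tries = 0
    while placed < n_tubes:
        if tries >= max_tries * max(n_tubes, 1):
            raise PhantomGeometryError(
                f"could only place {placed}/{n_tubes} tubes; the WM shell is "
                "too thin for the requested tube radius"
            )
        tries += 1
        radius_mm = rng.uniform(*radius_range_mm)
        length_mm = rng.uniform(*length_range_mm)
        radius_vox = radius_mm / spacing
        if radius_vox + 0.6 >= dist_in_wm.max():
            raise PhantomGeometryError(
                f"tube radius {radius_mm} mm does not fit inside the WM shell"
            )
        candidates = np.argwhere(dist_in_wm > radius_vox + 0.6)
        if len(candidates) == 0:
            raise PhantomGeometryError(
                f"tube radius {radius_mm} mm does not fit inside the WM shell"
            )
        start = candidates[rng.integers(len(candidates))].astype(float)
        pts = _random_polyline(
            rng, start, length_mm / spacing, dist_in_wm, radius_vox,
            n_segments=n_segments,
        )
        if pts is None:
            continue
        tube = np.zeros_like(wm)
        _stamp_tube(tube, pts, radius_vox)
        tube &= wm
        # keep tubes separated so components stay individually countable
        grown = ndimage.binary_dilation(tube, iterations=2)
        if (grown & (out | forbidden)).any():
            continue
        out |= tube
        placed += 1
    return out


def _confounder_masks(
    rng: np.random.Generator,
    spec: PhantomSpec,
    wm: np.ndarray,
    pvs: np.ndarray,
) -> np.ndarray:
    conf = np.zeros_like(wm)
    occupied = pvs.copy()
    spacing = float(np.mean(spec.voxel_size_mm))
    if spec.confounders.catheter_tube:
        # near-straight thick tube: well above the 150-voxel cap
        # (pi r^2 L >= pi * 2.2^2 * 14 ~ 210 voxels)
        tube = _place_tubes(
            rng, spec, wm, 1,
            radius_range_mm=(2.2, 2.5),
            length_range_mm=(14.0, 20.0),
            forbidden=occupied,
            max_tries=4000,
            n_segments=1,
        )
        conf |= tube
        occupied |= ndimage.binary_dilation(tube, iterations=2)
    if spec.confounders.hypointense_blobs:
        # leukoencephalopathy-like patches: well above the 150-voxel cap
        dist = ndimage.distance_transform_edt(wm, sampling=spec.voxel_size_mm)
        for _ in range(2):
            r_mm = rng.uniform(3.6, 4.5)
            cand = np.argwhere(dist > r_mm / spacing + 0.6)
            for _ in range(100):
                c = cand[rng.integers(len(cand))]
                blob = _ellipsoid(
                    wm.shape, c.astype(float), [r_mm / spacing] * 3
                ) & wm
                grown = ndimage.binary_dilation(blob, iterations=2)
                if not (grown & occupied).any():
                    conf |= blob
                    occupied |= grown
                    break
    return conf, occupied


def _speckle_mask(
    rng: np.random.Generator,
    wm: np.ndarray,
    occupied: np.ndarray,
    n_speckles: int = 25,
) -> np.ndarray:
    """Noise-like dark islands: 1-2 voxel clusters scattered in the WM
    interior, away from tubes and other confounders."""
    speckles = np.zeros_like(wm)
    # wide berth from tubes/blobs so a speckle can never merge with the
    # detection halo of a genuine structure
    interior = ndimage.binary_erosion(wm, iterations=2) & ~ndimage.binary_dilation(
        occupied, iterations=5
    )
    coords = np.argwhere(interior)
    taken = occupied.copy()
    for _ in range(n_speckles):
        c = coords[rng.integers(len(coords))]
        speck = np.zeros_like(wm)
        speck[tuple(c)] = True
        if rng.random() < 0.5:
            off = rng.integers(-1, 2, size=3)
            idx = np.clip(c + off, 0, np.array(wm.shape) - 1)
            speck[tuple(idx)] = True
        speck &= wm
        grown = ndimage.binary_dilation(speck, iterations=2)
        if not (grown & taken).any():
            speckles |= speck
            taken |= grown
    return speckles


def generate_phantom(
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[Volume3D, BinaryMask3D, PhantomGroundTruth]:
    """Generate a noisy tube phantom, its WM mask and its ground truth.

    Deterministic in (spec, seed). The ground-truth ratio is defined
    exactly as 1000 x (true PVS voxels) / (WM voxels).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    wm = _wm_compartment(spec)
    if not wm.any():
        raise PhantomGeometryError("WM compartment is empty for this grid")

    pvs = _place_tubes(
        rng, spec, wm, spec.n_tubes,
        spec.tube_radius_range_mm, spec.tube_length_range_mm,
        forbidden=np.zeros_like(wm),
    )
    conf, occupied = _confounder_masks(rng, spec, wm, pvs)
    speckles = (
        _speckle_mask(rng, wm, occupied)
        if spec.confounders.speckle_islands
        else np.zeros_like(wm)
    )
    conf = conf | speckles

    center = [(s - 1) / 2.0 for s in spec.grid_shape]
    inner = [spec.wm_inner_frac * s / 2.0 for s in spec.grid_shape]
    cavity = _ellipsoid(spec.grid_shape, center, inner)

    clean = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    clean[cavity] = spec.csf_intensity
    clean[wm] = spec.wm_intensity
    clean[pvs | (conf & ~speckles)] = spec.pvs_intensity
    if spec.psf_sigma_vox > 0:
        clean = ndimage.gaussian_filter(clean, spec.psf_sigma_vox, mode="nearest")
    # speckles are shallow noise-like dips, applied after the blur
    clean[speckles] -= spec.speckle_depth

    # noise is spatially correlated (smoothed white noise rescaled to the
    # requested marginal SD), emulating the band-limiting of scanner
    # reconstruction and on-grid interpolation
    def _draw_noise() -> np.ndarray:
        n = rng.normal(0.0, 1.0, size=spec.grid_shape)
        if spec.noise_smooth_sigma_vox > 0:
            n = ndimage.gaussian_filter(n, spec.noise_smooth_sigma_vox, mode="wrap")
            sd = n.std()
            if sd > 0:
                n = n / sd
        return n * spec.noise_sd

    noise = _draw_noise()
    if spec.rician_noise:
        noise2 = _draw_noise()
        noisy = np.sqrt((clean + noise) ** 2 + noise2**2)
    else:
        noisy = clean + noise
    image = noisy * spec.global_scale

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    wm_mask = BinaryMask3D(wm, affine)
    pvs_mask = BinaryMask3D(pvs, affine)
    conf_mask = BinaryMask3D(conf, affine)
    voxel_cm3 = wm_mask.voxel_volume_mm3 / 1000.0
    n_wm = wm_mask.n_voxels
    gt = PhantomGroundTruth(
        pvs_mask=pvs_mask,
        confounder_mask=conf_mask,
        true_pvs_volume_cm3=pvs_mask.n_voxels * voxel_cm3,
        true_pvs_ratio_permil=1000.0 * pvs_mask.n_voxels / n_wm,
    )
    return Volume3D(image, affine), wm_mask, gt


# ---------------------------------------------------------------------------
# longitudinal cohort simulation
# ---------------------------------------------------------------------------

#: years by which age advances at each follow-up step (0M->3M->12M->FollowUp);
#: the last step is sampled uniformly in the given range per patient.
AGE_ADVANCE_YEARS = (0.25, 0.75)
FOLLOWUP_ADVANCE_RANGE = (0.5, 0.75)


@dataclass
class CohortSimParams:
    """Effect sizes and sampling design of the simulated cohort.

    All effects are on the PVS-ratio scale (permil); the PVS-volume
    response is generated from the same linear predictor scaled by
    ``volume_effect_scale`` with its own intercept and age slope, so
    the two responses are correlated within an exam as in real data.
    Defaults encode the developing study's printed conditions (group
    means, retention and prevalences); see the package methods note.
    """

    n_patients: int = 241
    intercept: float = 10.04
    tp_effects: Mapping[str, float] = field(
        default_factory=lambda: {"0M": 0.0, "3M": 0.455, "12M": -1.335, "FollowUp": -0.9}
    )
    anesthesia_effect: float = -0.5
    shunt_effect: float = -1.1
    sex_effect: float = 0.6  # male vs female
    age_slope: float = 0.18  # permil per year
    # reference age = expected baseline age of the sampling model
    # (3.3 + mean of Gamma(2.2, 3.2)), so the intercept is the 0M mean
    age_ref_years: float = 10.34
    dose_effects: Mapping[str, float] = field(
        default_factory=lambda: {"RD": 0.0, "SD": 0.3, "HD": -0.4}
    )
    patient_sd: float = 1.5
    residual_sd: float = 1.0
    age_range_years: tuple[float, float] = (3.3, 38.8)
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            # 1 - evaluable/enrolled per time point: 210/209/198/161 of 241
            "0M": 1 - 210 / 241,
            "3M": 1 - 209 / 241,
            "12M": 1 - 198 / 241,
            "FollowUp": 1 - 161 / 241,
        }
    )
    covariate_prevalences: Mapping[str, object] = field(
        default_factory=lambda: {
            "male": 0.62,
            "anesthesia": 0.58,
            "shunt": 0.25,
            "dose": {"RD": 0.12, "SD": 0.41, "HD": 0.47},
        }
    )
    volume_intercept: float = 4.7  # cm^3
    volume_age_slope: float = 0.14  # cm^3 per year
    volume_effect_scale: float = 0.55

    def __post_init__(self) -> None:
        if self.patient_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for tp, p in self.missingness.items():
            if not (0 <= p <= 1):
                raise ValueError(f"missingness for {tp} must be in [0,1], got {p}")
        if len(self.tp_effects) < 2:
            raise ValueError("at least 2 time points must be simulated")


def generate_cohort(params: CohortSimParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a longitudinal cohort table.

    One row per retained exam with patient id, time point, age
    (advancing along the exam calendar), sex, dose, anesthesia, shunt,
    and simulated pvs_ratio_permil / pvs_volume_cm3 following the
    additive fixed-effect model plus a per-patient random intercept and
    residual noise. Deterministic in (params, seed).
    """
    params = params or CohortSimParams()
    if params.n_patients <= 0:
        raise ValueError("n_patients must be positive; cannot build an empty table")
    rng = np.random.default_rng(seed)
    prev = params.covariate_prevalences
    dose_levels = [d for d in DOSE_LEVELS if d in params.dose_effects]
    dose_p = np.array([prev["dose"][d] for d in dose_levels], dtype=float)
    dose_p = dose_p / dose_p.sum()
    tps = [t for t in TP_LEVELS if t in params.tp_effects]

    lo, hi = params.age_range_years
    rows = []
    for i in range(params.n_patients):
        pid = f"P{i + 1:04d}"
        base_age = float(np.clip(lo + rng.gamma(2.2, 3.2), lo, hi))
        sex = "M" if rng.random() < prev["male"] else "F"
        dose = dose_levels[rng.choice(len(dose_levels), p=dose_p)]
        shunt = "yes" if rng.random() < prev["shunt"] else "no"
        b_i = rng.normal(0.0, params.patient_sd) if params.patient_sd > 0 else 0.0
        fu_advance = rng.uniform(*FOLLOWUP_ADVANCE_RANGE)
        advances = {
            "0M": 0.0,
            "3M": AGE_ADVANCE_YEARS[0],
            "12M": AGE_ADVANCE_YEARS[0] + AGE_ADVANCE_YEARS[1],
            "FollowUp": AGE_ADVANCE_YEARS[0] + AGE_ADVANCE_YEARS[1] + fu_advance,
        }
        for tp in tps:
            anesthesia = "yes" if rng.random() < prev["anesthesia"] else "no"
            eps = rng.normal(0.0, params.residual_sd) if params.residual_sd > 0 else 0.0
            dropped = rng.random() < params.missingness.get(tp, 0.0)
            age = base_age + advances[tp]
            fixed = (
                params.tp_effects[tp]
                + (params.anesthesia_effect if anesthesia == "yes" else 0.0)
                + (params.shunt_effect if shunt == "yes" else 0.0)
                + (params.sex_effect if sex == "M" else 0.0)
                + params.dose_effects[dose]
            )
            ratio = (
                params.intercept
                + fixed
                + params.age_slope * (age - params.age_ref_years)
                + b_i
                + eps
            )
            volume = (
                params.volume_intercept
                + params.volume_age_slope * (age - params.age_ref_years)
                + params.volume_effect_scale * (fixed + b_i + eps)
            )
            if dropped:
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "tp": tp,
                    "age_years": age,
                    "sex": sex,
                    "dose": dose,
                    "anesthesia": anesthesia,
                    "shunt": shunt,
                    "pvs_ratio_permil": ratio,
                    "pvs_volume_cm3": volume,
                }
            )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("simulation produced an empty table (missingness too high)")
    return validate_cohort_frame(df)


def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)


def phantom_spec_from_dict(d: Mapping) -> PhantomSpec:
    return PhantomSpec(**{
        k: (tuple(v) if isinstance(v, (list, tuple)) else v) for k, v in d.items()
    })
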