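"""Synthetic OCT phantoms and longitudinal cohorts with known ground truth.

The phantom emulates the geometry of a 12 x 12-mm swept-source OCT scan
of the posterior pole: a layered retina over a bright RPE band, a
choroidal slab between Bruch's membrane (BM) and the choroidal-scleral
interface (CSI) populated with hyporeflective vessel tubes, and sclera
beneath.  A forward model applies per-tissue extinction (cumulative
Beer-Lambert attenuation along each A-scan), optional focal shadow
artifacts, and multiplicative gamma speckle.  Ground truth (surfaces,
thickness, vessel voxels and per-A-scan vessel fraction) is recorded
before noise, so every downstream stage of the measurement pipeline can
be scored against known values.

The default grid is a desk-scale 64 x 64 x 256 volume covering the same
12-mm field of view (lateral spacing scaled accordingly); the full
device geometry (500 x 500 A-scans at 24 um) is available via
:meth:`PhantomParams.full_scale`.

A separate cohort generator simulates the study's measurement table
directly (no images): per-eye regional means across the three visits
with patient- and eye-level random effects, fellow-eye clustering and
programmed visit-to-visit mean shifts, for calibrating and testing the
longitudinal statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .registration import RigidTransform2D, apply_rigid
from .volume import OCTVolume

_TISSUES = ("vitreous", "retina", "retinal_vessel", "rpe", "stroma", "vessel", "sclera")


def _round_half_up(a):
    return np.floor(np.asarray(a, dtype=float) + 0.5).astype(int)


@dataclass
class SmoothField2D:
    """A band-limited random surface: mean + amplitude * smooth noise.

    ``amplitude`` bounds the maximum absolute deviation from the mean;
    ``correlation_px`` is the Gaussian smoothing length of the noise.
    """

    mean: float
    amplitude: float = 0.0
    correlation_px: float = 10.0

    def sample(self, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        if self.amplitude == 0:
            return np.full(shape, self.mean, dtype=float)
        noise = rng.standard_normal(shape)
        smooth = gaussian_filter(noise, self.correlation_px, mode="reflect")
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth = smooth / peak
        return self.mean + self.amplitude * smooth


@dataclass
class ShadowArtifact:
    """A focal multiplicative shadow under a lesion or opacity."""

    center_xy: tuple[float, float]  # pixels
    radius_um: float
    factor: float  # transmission multiplier in (0, 1]


@dataclass
class PhantomParams:
    """Geometry, optics and noise of the simulated scan."""

    grid_nx: int = 64
    grid_ny: int = 64
    grid_nz: int = 256
    lateral_spacing_um: float = 187.5  # 12 mm / 64 A-scans
    axial_spacing_um: float = 3.9
    bm_depth_field: SmoothField2D = field(
        default_factory=lambda: SmoothField2D(mean=420.0, amplitude=20.0)
    )
    thickness_field_um: SmoothField2D = field(
        default_factory=lambda: SmoothField2D(mean=200.0, amplitude=40.0)
    )
    retina_thickness_um: float = 250.0
    rpe_thickness_um: float = 20.0
    vessel_fraction_target: float = 0.6
    vessel_radius_um: tuple[float, float] = (50.0, 150.0)
    vessel_depth_band: tuple[float, float] = (0.15, 0.85)  # fraction of slab
    n_retinal_vessels: int = 12
    intensity_levels: dict = field(
        default_factory=lambda: {
            "vitreous": 10.0,
            "retina": 120.0,
            "retinal_vessel": 60.0,
            "rpe": 250.0,
            "stroma": 180.0,
            "vessel": 60.0,
            "sclera": 70.0,
        }
    )
    # extinction per um of tissue traversed (single pass)
    attenuation_coeffs: dict = field(
        default_factory=lambda: {
            "vitreous": 0.00005,
            "retina": 0.001,
            "retinal_vessel": 0.004,
            "rpe": 0.005,
            "stroma": 0.001,
            "vessel": 0.001,
            "sclera": 0.001,
        }
    )
    speckle_shape: float = 4.0  # gamma shape; 0 disables noise
    shadow_artifacts: list = field(default_factory=list)
    include_onh: bool = True
    onh_center_frac: tuple[float, float] = (0.85, 0.5)  # (x, y) as grid fraction
    onh_radius_um: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.vessel_fraction_target <= 1.0):
            raise ValueError("vessel_fraction_target must be in [0, 1]")
        if self.lateral_spacing_um <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("spacings must be positive")
        depth = self.grid_nz * self.axial_spacing_um
        deepest = (
            self.bm_depth_field.mean
            + abs(self.bm_depth_field.amplitude)
            + self.thickness_field_um.mean
            + abs(self.thickness_field_um.amplitude)
        )
        if deepest >= depth:
            raise ValueError(
                f"bm + thickness ({deepest:.0f} um) exceeds the axial extent "
                f"({depth:.0f} um)"
            )
        missing = set(_TISSUES) - set(self.intensity_levels)
        if missing:
            raise ValueError(f"intensity levels missing tissues: {sorted(missing)}")

    @classmethod
    def full_scale(cls, **overrides) -> "PhantomParams":
        """Device-geometry phantom: 500 x 500 A-scans at 24 um, 1536 axial
        samples at 1.95 um."""
        base = dict(
            grid_nx=500,
            grid_ny=500,
            grid_nz=1536,
            lateral_spacing_um=24.0,
            axial_spacing_um=1.95,
            bm_depth_field=SmoothField2D(mean=1200.0, amplitude=60.0, correlation_px=60),
            thickness_field_um=SmoothField2D(mean=200.0, amplitude=40.0, correlation_px=60),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PhantomTruth:
    """Ground truth recorded before speckle noise.

    Surfaces are voxel-unit depth grids (fractional); the fraction map
    is the integer count ratio of vessel to slab voxels per A-scan
    (zero where the slab is empty), recomputable from
    ``true_vessel_mask`` and the rounded surfaces.
    """

    true_thickness_map: np.ndarray  # um
    true_vessel_mask: np.ndarray  # 3-D bool
    true_vessel_fraction_map: np.ndarray
    true_bm: np.ndarray  # voxel units
    true_csi: np.ndarray
    achieved_vessel_fraction: float
    applied_transform: Optional[RigidTransform2D] = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "true_thickness_um.csv", self.true_thickness_map, delimiter=",")
        np.savetxt(directory / "true_vessel_fraction.csv", self.true_vessel_fraction_map, delimiter=",")
        np.savetxt(directory / "true_bm.csv", self.true_bm, delimiter=",")
        np.savetxt(directory / "true_csi.csv", self.true_csi, delimiter=",")
        meta = {"achieved_vessel_fraction": self.achieved_vessel_fraction}
        if self.applied_transform is not None:
            t = self.applied_transform
            meta["applied_transform"] = [t.dx_px, t.dy_px, t.dtheta_deg]
        (directory / "truth.json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# phantom construction


def _substream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % (2**31))


def _retinal_vessel_pattern(
    shape: tuple[int, int], n_vessels: int, rng: np.random.Generator
) -> np.ndarray:
    """Random straight dark-vessel lines across the en face grid."""
    ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pattern = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        angle = rng.uniform(0, np.pi)
        y0 = rng.uniform(0, ny - 1)
        x0 = rng.uniform(0, nx - 1)
        width = rng.uniform(0.6, 1.4)
        # perpendicular distance to the line through (y0, x0) at `angle`
        d = np.abs(-np.sin(angle) * (xx - x0) + np.cos(angle) * (yy - y0))
        pattern |= d <= width
    return pattern


def _place_vessels(
    slab_lo: np.ndarray,
    slab_hi: np.ndarray,
    params: PhantomParams,
    target: float,
    rng: np.random.Generator,
    max_attempts: int = 20000,
) -> tuple[np.ndarray, float]:
    """Fill the slab with random vessel tubes until the global vessel
    fraction lands within +-0.01 of ``target``.

    Tubes follow the slab curvature at a constant depth fraction, with
    random in-plane orientation; candidates overlapping existing vessels
    by more than half, or overshooting the band, are rejected.
    """
    ny, nx = slab_lo.shape
    nz = int(params.grid_nz)
    mask = np.zeros((ny, nx, nz), dtype=bool)
    z = np.arange(nz)
    slab = (z >= slab_lo[..., None]) & (z < slab_hi[..., None])
    total = int(slab.sum())
    if target <= 0 or total == 0:
        return mask, 0.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    sp, dz = params.lateral_spacing_um, params.axial_spacing_um
    r_lo, r_hi = params.vessel_radius_um
    f_lo, f_hi = params.vessel_depth_band
    count = 0
    for _ in range(max_attempts):
        frac = count / total
        if frac >= target - 0.005:
            break
        angle = rng.uniform(0, np.pi)
        y0 = rng.uniform(0, ny - 1)
        x0 = rng.uniform(0, nx - 1)
        r_um = rng.uniform(r_lo, r_hi)
        depth_frac = rng.uniform(f_lo, f_hi)
        d_lat = np.abs(-np.sin(angle) * (xx - x0) + np.cos(angle) * (yy - y0)) * sp
        near = d_lat < r_um
        if not near.any():
            continue
        zc = slab_lo + depth_frac * (slab_hi - slab_lo)  # voxel units
        half = np.zeros_like(d_lat)
        half[near] = np.sqrt(r_um**2 - d_lat[near] ** 2) / dz
        lo = zc - half
        hi = zc + half
        cand = near[..., None] & (z >= lo[..., None]) & (z <= hi[..., None]) & slab
        n_cand = int(cand.sum())
        if n_cand == 0:
            continue
        overlap = int((cand & mask).sum())
        if overlap > 0.5 * n_cand:
            continue
        new_count = count + n_cand - overlap
        if new_count / total > target + 0.01:
            continue
        mask |= cand
        count = new_count
    achieved = count / total
    if abs(achieved - target) > 0.01:
        raise RuntimeError(
            f"vessel placement failed: achieved fraction {achieved:.3f} "
            f"vs target {target:.3f}"
        )
    return mask, achieved


def _build_phantom(
    params: PhantomParams,
    bm_um: np.ndarray,
    th_um: np.ndarray,
    retinal_pattern: np.ndarray,
    vessel_rng: np.random.Generator,
    speckle_rng: np.random.Generator,
    fovea_center: tuple[float, float],
    visit_label: str = "exudation",
    transform: Optional[RigidTransform2D] = None,
) -> tuple[OCTVolume, PhantomTruth]:
    ny, nx, nz = params.grid_ny, params.grid_nx, params.grid_nz
    dz = params.axial_spacing_um
    csi_um = bm_um + th_um

    bm_px = bm_um / dz
    csi_px = csi_um / dz
    slab_lo = _round_half_up(bm_px)
    slab_hi = np.maximum(_round_half_up(csi_px), slab_lo)
    rpe_top = _round_half_up((bm_um - params.rpe_thickness_um) / dz)
    ilm = _round_half_up((bm_um - params.rpe_thickness_um - params.retina_thickness_um) / dz)
    if ilm.min() < 1:
        raise ValueError("retina extends above the volume: increase bm depth")
    if slab_hi.max() > nz - 1:
        raise ValueError("choroid extends below the volume: fields exceed grid")

    z = np.arange(nz)
    tissue = np.zeros((ny, nx, nz), dtype=np.uint8)  # vitreous
    names = {name: i for i, name in enumerate(_TISSUES)}
    zb = z[None, None, :]
    tissue[(zb >= ilm[..., None]) & (zb < rpe_top[..., None])] = names["retina"]
    tissue[(zb >= rpe_top[..., None]) & (zb < slab_lo[..., None])] = names["rpe"]
    tissue[(zb >= slab_lo[..., None]) & (zb < slab_hi[..., None])] = names["stroma"]
    tissue[zb >= slab_hi[..., None]] = names["sclera"]

    # dark retinal vessels in the inner third of the retina (cast shadows)
    inner_depth = ilm + (rpe_top - ilm) // 3
    rv = (
        retinal_pattern[..., None]
        & (zb >= ilm[..., None])
        & (zb < inner_depth[..., None])
    )
    tissue[rv] = names["retinal_vessel"]

    vessel_mask, achieved = _place_vessels(
        slab_lo, slab_hi, params, params.vessel_fraction_target, vessel_rng
    )
    tissue[vessel_mask] = names["vessel"]

    levels = np.array([params.intensity_levels[t] for t in _TISSUES])
    mus = np.array([params.attenuation_coeffs[t] for t in _TISSUES])
    intensity = levels[tissue]
    mu = mus[tissue] * dz
    # exclusive cumulative extinction above each voxel
    optical_depth = np.cumsum(mu, axis=2) - mu
    intensity = intensity * np.exp(-optical_depth)

    for art in params.shadow_artifacts:
        cx, cy = art.center_xy
        d_um = (
            np.sqrt(
                ((np.arange(nx)[None, :] - cx)) ** 2
                + ((np.arange(ny)[:, None] - cy)) ** 2
            )
            * params.lateral_spacing_um
        )
        cols = d_um <= art.radius_um
        shadowed = cols[..., None] & (zb >= ilm[..., None])
        intensity = np.where(shadowed, intensity * art.factor, intensity)

    slab_counts = (slab_hi - slab_lo).astype(int)
    vessel_counts = vessel_mask.sum(axis=2)
    with np.errstate(invalid="ignore"):
        fraction_map = np.where(
            slab_counts > 0, vessel_counts / np.maximum(slab_counts, 1), 0.0
        )
    truth = PhantomTruth(
        true_thickness_map=th_um.copy(),
        true_vessel_mask=vessel_mask,
        true_vessel_fraction_map=fraction_map,
        true_bm=bm_px,
        true_csi=csi_px,
        achieved_vessel_fraction=achieved,
        applied_transform=transform,
    )

    if params.speckle_shape > 0:
        speckle = speckle_rng.gamma(
            params.speckle_shape, 1.0 / params.speckle_shape, size=intensity.shape
        )
        intensity = intensity * speckle

    onh_mask = None
    if params.include_onh:
        ox = params.onh_center_frac[0] * (nx - 1)
        oy = params.onh_center_frac[1] * (ny - 1)
        d_um = (
            np.sqrt(
                (np.arange(nx)[None, :] - ox) ** 2 + (np.arange(ny)[:, None] - oy) ** 2
            )
            * params.lateral_spacing_um
        )
        onh_mask = d_um <= params.onh_radius_um

    volume = OCTVolume(
        intensity=intensity,
        lateral_spacing_um=params.lateral_spacing_um,
        axial_spacing_um=dz,
        fovea_center=fovea_center,
        onh_mask=onh_mask,
        visit_label=visit_label,
        signal_strength=10,
    )
    return volume, truth


def generate_phantom(params: PhantomParams) -> tuple[OCTVolume, PhantomTruth]:
    """Generate a single-visit phantom volume with its ground truth."""
    field_rng = _substream(params.seed, 1)
    vessel_rng = _substream(params.seed, 2)
    pattern_rng = _substream(params.seed, 3)
    speckle_rng = _substream(params.seed, 4)
    shape = (params.grid_ny, params.grid_nx)
    bm_um = params.bm_depth_field.sample(shape, field_rng)
    th_um = params.thickness_field_um.sample(shape, field_rng)
    pattern = _retinal_vessel_pattern(shape, params.n_retinal_vessels, pattern_rng)
    fovea = ((params.grid_nx - 1) / 2.0, (params.grid_ny - 1) / 2.0)
    return _build_phantom(
        params, bm_um, th_um, pattern, vessel_rng, speckle_rng, fovea
    )


def generate_longitudinal_phantoms(
    params: PhantomParams,
    deltas: Sequence[tuple[float, float]],
    transforms: Sequence[RigidTransform2D | tuple] | None = None,
    visit_labels: Sequence[str] = ("pretreatment", "exudation", "post_treatment"),
) -> list[tuple[OCTVolume, PhantomTruth]]:
    """Generate a visit series sharing one baseline anatomy.

    ``deltas[k] = (thickness_change_um, vessel_fraction_change)`` are
    additive offsets relative to the baseline parameters at visit ``k``;
    ``transforms[k]`` is the rigid scan-raster motion of visit ``k``
    relative to the baseline frame (identity if omitted).  The same
    vessel-placement substream is reused across visits so the vascular
    pattern is shared; speckle is redrawn per visit.
    """
    if len(deltas) < 2:
        raise ValueError("a longitudinal series needs at least 2 visits")
    if transforms is None:
        transforms = [RigidTransform2D() for _ in deltas]
    if len(transforms) != len(deltas):
        raise ValueError("one transform per visit required")
    transforms = [
        t if isinstance(t, RigidTransform2D) else RigidTransform2D(*t)
        for t in transforms
    ]
    field_rng = _substream(params.seed, 1)
    pattern_rng = _substream(params.seed, 3)
    shape = (params.grid_ny, params.grid_nx)
    bm_um = params.bm_depth_field.sample(shape, field_rng)
    th_um = params.thickness_field_um.sample(shape, field_rng)
    pattern = _retinal_vessel_pattern(shape, params.n_retinal_vessels, pattern_rng)
    fovea = np.array([(params.grid_nx - 1) / 2.0, (params.grid_ny - 1) / 2.0])

    out = []
    for k, ((d_th, d_frac), transform) in enumerate(zip(deltas, transforms)):
        label = visit_labels[k] if k < len(visit_labels) else f"visit{k}"
        new_fovea = _transform_point(fovea, transform, shape)
        if not (
            0 <= new_fovea[0] <= params.grid_nx - 1
            and 0 <= new_fovea[1] <= params.grid_ny - 1
        ):
            raise ValueError(
                f"visit {k} transform moves the fovea off-grid to {new_fovea}"
            )
        bm_v = _warp_field(bm_um, transform)
        th_v = _warp_field(th_um + d_th, transform)
        pat_v = _warp_field(pattern.astype(float), transform) > 0.5
        params_v = replace(
            params,
            vessel_fraction_target=float(
                np.clip(params.vessel_fraction_target + d_frac, 0.0, 1.0)
            ),
        )
        vol, truth = _build_phantom(
            params_v,
            bm_v,
            th_v,
            pat_v,
            _substream(params.seed, 2),
            _substream(params.seed, 100 + 7 * k),
            tuple(new_fovea),
            visit_label=label,
            transform=transform,
        )
        out.append((vol, truth))
    return out


def _transform_point(
    xy: np.ndarray, t: RigidTransform2D, shape: tuple[int, int]
) -> np.ndarray:
    th = np.deg2rad(t.dtheta_deg)
    c, s = np.cos(th), np.sin(th)
    cx = (shape[1] - 1) / 2.0
    cy = (shape[0] - 1) / 2.0
    x, y = xy[0] - cx, xy[1] - cy
    return np.array([c * x - s * y + cx + t.dx_px, s * x + c * y + cy + t.dy_px])


def _warp_field(arr: np.ndarray, t: RigidTransform2D) -> np.ndarray:
    if t.dx_px == 0 and t.dy_px == 0 and t.dtheta_deg == 0:
        return np.asarray(arr, dtype=float).copy()
    warped = apply_rigid(np.asarray(arr, dtype=float), t, order=1, cval=np.nan)
    if np.any(np.isnan(warped)):  # extend anatomy past the original border
        fill = _nearest_fill(warped)
        warped = np.where(np.isnan(warped), fill, warped)
    return warped


def _nearest_fill(arr: np.ndarray) -> np.ndarray:
    from scipy.ndimage import distance_transform_edt

    nan = np.isnan(arr)
    if not nan.any():
        return arr
    idx = distance_transform_edt(nan, return_indices=True, return_distances=False)
    return arr[tuple(idx)]


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortParams:
    """Mean/variance structure of the simulated measurement cohort.

    Defaults emulate a treatment-naive exudative-AMD population: ~37
    patients, a ~11% chance a patient contributes the fellow eye, a
    5-mm-circle baseline choroidal thickness near 200 um with its
    variance split across patient, eye and visit (residual) levels, a
    programmed thickening at the onset of exudation and a larger
    thinning after anti-VEGF therapy, and CVI analogues near 0.62.
    """

    n_patients: int = 37
    p_fellow_eye: float = 4 / 37
    mnv_type_probs: tuple[float, float, float] = (24 / 41, 4 / 41, 13 / 41)
    baseline_mean_um: float = 200.7
    between_patient_sd: float = 62.0
    between_eye_sd: float = 25.0
    residual_sd: float = 16.1
    delta_exudation_um: float = 12.7
    delta_treatment_um: float = -19.5
    cvi_baseline: float = 0.617
    cvi_between_patient_sd: float = 0.032
    cvi_between_eye_sd: float = 0.012
    cvi_residual_sd: float = 0.0163
    cvi_delta_exudation: float = 0.014
    cvi_delta_treatment: float = -0.017
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mnv_type_probs) - 1.0) > 1e-9:
            raise ValueError("mnv_type_probs must sum to 1")
        for sd in (
            self.between_patient_sd,
            self.between_eye_sd,
            self.residual_sd,
            self.cvi_between_patient_sd,
            self.cvi_between_eye_sd,
            self.cvi_residual_sd,
        ):
            if sd < 0:
                raise ValueError("SDs must be nonnegative")
        if not 0 <= self.p_fellow_eye <= 1:
            raise ValueError("p_fellow_eye must be a probability")


_VISITS = ("pretreatment", "exudation", "post_treatment")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate the per-eye-per-visit measurement table.

    Long format with one row per (eye, visit): columns patient_id,
    eye_id, mnv_type, visit, thickness_um, cvi.  Each value is
    baseline + patient effect + eye effect + cumulative visit delta +
    visit residual, all Gaussian; fellow eyes share the patient effect.
    """
    if params.n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = _substream(params.seed, 11)
    cum_th = {
        "pretreatment": 0.0,
        "exudation": params.delta_exudation_um,
        "post_treatment": params.delta_exudation_um + params.delta_treatment_um,
    }
    cum_cvi = {
        "pretreatment": 0.0,
        "exudation": params.cvi_delta_exudation,
        "post_treatment": params.cvi_delta_exudation + params.cvi_delta_treatment,
    }
    rows = []
    for p in range(params.n_patients):
        pid = f"P{p:03d}"
        b_p_th = rng.normal(0, params.between_patient_sd)
        b_p_cvi = rng.normal(0, params.cvi_between_patient_sd)
        n_eyes = 2 if rng.uniform() < params.p_fellow_eye else 1
        for e in range(n_eyes):
            eid = f"{pid}-{'OD' if e == 0 else 'OS'}"
            mnv = int(rng.choice([1, 2, 3], p=params.mnv_type_probs))
            b_e_th = rng.normal(0, params.between_eye_sd)
            b_e_cvi = rng.normal(0, params.cvi_between_eye_sd)
            for visit in _VISITS:
                rows.append(
                    {
                        "patient_id": pid,
                        "eye_id": eid,
                        "mnv_type": mnv,
                        "visit": visit,
                        "thickness_um": params.baseline_mean_um
                        + b_p_th
                        + b_e_th
                        + cum_th[visit]
                        + rng.normal(0, params.residual_sd),
                        "cvi": params.cvi_baseline
                        + b_p_cvi
                        + b_e_cvi
                        + cum_cvi[visit]
                        + rng.normal(0, params.cvi_residual_sd),
                    }
                )
    return pd.DataFrame(rows)


def cohort_to_records(cohort: pd.DataFrame, region: str = "circle5") -> pd.DataFrame:
    """Reshape a simulated cohort into the long measurement-record format
    used by the statistics module."""
    rows = []
    for r in cohort.itertuples(index=False):
        for metric, value in (("thickness_um", r.thickness_um), ("cvi", r.cvi)):
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "eye_id": r.eye_id,
                    "mnv_type": r.mnv_type,
                    "visit": r.visit,
                    "region": region,
                    "metric": metric,
                    "value": value,
                    "eligible": True,
                }
            )
    return pd.DataFrame(rows)
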