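"""Segmentation of Bruch's membrane (BM) and the choroidal-scleral interface (CSI).

Each surface is extracted per B-scan as a minimum-cost path through a
cost image built from the signed axial derivative of the (z-smoothed)
intensity: a ``bright_to_dark`` surface sits where intensity drops with
depth (BM at the base of the bright RPE band; CSI where the vascular
choroid gives way to the dimmer sclera in attenuation-compensated data),
a ``dark_to_bright`` surface where it rises.  The path visits one depth
per A-scan column, moves at most ``max_step`` voxels between adjacent
columns, and breaks ties toward smaller depth.  Depths are reported at
the edge centre (the midpoint of the voxel pair across which the
intensity steps), with optional sub-voxel parabolic refinement, then
median-filtered across B-scans for 3-D coherence.

Automatic surfaces can be overridden pointwise by externally supplied
manual corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d, median_filter

from .attenuation import AttenuationParams, compensate_attenuation
from .volume import OCTVolume

_BIG = 1e30

Polarity = Literal["bright_to_dark", "dark_to_bright"]


@dataclass
class SurfaceSet:
    """The BM/CSI surface pair delimiting the choroidal slab per A-scan.

    Depths are in voxel units (fractional allowed), ``bm <= csi``
    everywhere.  ``provenance`` records per A-scan whether the depth is
    automatic or manually corrected.
    """

    bm: np.ndarray
    csi: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]
    max_step: float | None = None

    def __post_init__(self) -> None:
        self.bm = np.asarray(self.bm, dtype=float)
        self.csi = np.asarray(self.csi, dtype=float)
        if self.bm.shape != self.csi.shape:
            raise ValueError("bm and csi grids must share a shape")
        if self.provenance is None:
            self.provenance = np.full(self.bm.shape, "auto", dtype=object)
        self.validate()

    def validate(self) -> None:
        if np.any(self.bm < 0):
            raise ValueError("bm depths must be nonnegative")
        bad = int(np.sum(self.bm > self.csi))
        if bad:
            raise ValueError(f"bm exceeds csi at {bad} A-scans")
        if self.max_step is not None:
            for surf in (self.bm, self.csi):
                step = np.abs(np.diff(surf, axis=1))
                # refinement and median filtering may add up to one voxel
                if step.size and step.max() > self.max_step + 1.0:
                    raise ValueError(
                        f"surface step {step.max():.2f} exceeds max_step "
                        f"{self.max_step} + 1"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.bm.shape


def _edge_cost(
    volume: OCTVolume,
    polarity: Polarity,
    smooth_sigma_z: float,
    smooth_sigma_lateral: float,
) -> np.ndarray:
    """Signed-derivative cost, (ny, nx, nz-1); cost[z] sits between z and z+1.

    Lateral smoothing suppresses speckle and the narrow edges of
    individual vessels, which would otherwise out-compete the laterally
    coherent layer boundary.
    """
    data = np.asarray(volume.intensity, dtype=float)
    if smooth_sigma_lateral > 0:
        data = gaussian_filter(
            data, (smooth_sigma_lateral, smooth_sigma_lateral, 0), mode="nearest"
        )
    if smooth_sigma_z > 0:
        data = gaussian_filter1d(data, smooth_sigma_z, axis=2, mode="nearest")
    d = np.diff(data, axis=2)
    return d if polarity == "bright_to_dark" else -d


def segment_surface(
    volume: OCTVolume,
    polarity: Polarity,
    max_step: int = 2,
    band: tuple | None = None,
    smooth_sigma_z: float = 1.5,
    smooth_sigma_lateral: float = 1.5,
    refine: bool = True,
    median_across_bscans: bool = True,
) -> np.ndarray:
    """Extract one surface as a per-B-scan minimum-cost path.

    ``band`` restricts candidate depths to ``lo <= z < hi``; ``lo``/``hi``
    may be scalars or per-A-scan ``(ny, nx)`` grids.  Returns a ``(ny, nx)``
    float depth grid (edge-centre convention: an intensity step between
    voxels ``z`` and ``z+1`` is reported as ``z + 0.5``).
    """
    ny, nx, nz = volume.shape
    cost = _edge_cost(volume, polarity, smooth_sigma_z, smooth_sigma_lateral)  # (ny, nx, nz-1)
    if not np.all(np.isfinite(cost)):
        raise ValueError("non-finite segmentation costs")
    nzc = nz - 1
    if band is None:
        lo_grid = np.zeros((ny, nx), dtype=int)
        hi_grid = np.full((ny, nx), nzc, dtype=int)
    else:
        lo_grid = np.broadcast_to(np.asarray(band[0]), (ny, nx)).astype(int)
        hi_grid = np.broadcast_to(np.asarray(band[1]), (ny, nx)).astype(int)
    lo_grid = np.clip(lo_grid, 0, nzc)
    hi_grid = np.clip(hi_grid, 0, nzc)
    if np.any(hi_grid <= lo_grid):
        raise ValueError("empty search band")

    zidx = np.arange(nzc)
    feasible = (zidx >= lo_grid[..., None]) & (zidx < hi_grid[..., None])
    masked = np.where(feasible, cost, _BIG)

    surface = np.empty((ny, nx), dtype=float)
    offsets = np.arange(-max_step, max_step + 1)
    for y in range(ny):
        path_z = _min_cost_path(masked[y], offsets)
        surface[y] = path_z
    if refine:
        surface = _parabolic_refine(masked, surface)
    surface = surface + 0.5  # edge-centre convention
    if median_across_bscans and ny >= 3:
        surface = median_filter(surface, size=(3, 1), mode="nearest")
    return surface


def _min_cost_path(cost: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Viterbi over one B-scan; cost is (nx, nz). Ties go to smaller z."""
    nx, nzc = cost.shape
    dp = cost[0].copy()
    back = np.zeros((nx, nzc), dtype=np.int32)
    for x in range(1, nx):
        # candidate predecessor values dp[z + off] for each offset
        stacked = np.full((offsets.size, nzc), _BIG)
        for i, off in enumerate(offsets):
            src_lo = max(0, off)
            src_hi = min(nzc, nzc + off)
            stacked[i, src_lo - off : src_hi - off] = dp[src_lo:src_hi]
        best = np.argmin(stacked, axis=0)  # first occurrence -> smallest z_prev
        back[x] = best
        dp = stacked[best, np.arange(nzc)] + cost[x]
    path = np.empty(nx, dtype=int)
    path[-1] = int(np.argmin(dp))
    for x in range(nx - 1, 0, -1):
        path[x - 1] = path[x] + offsets[back[x, path[x]]]
    return path


def _parabolic_refine(cost: np.ndarray, surface: np.ndarray) -> np.ndarray:
    """Sub-voxel vertex of the parabola through the cost minimum and neighbours."""
    ny, nx, nzc = cost.shape
    z0 = surface.astype(int)
    zm = np.clip(z0 - 1, 0, nzc - 1)
    zp = np.clip(z0 + 1, 0, nzc - 1)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cm, c0, cp = cost[yy, xx, zm], cost[yy, xx, z0], cost[yy, xx, zp]
    denom = cm - 2 * c0 + cp
    valid = (denom > 1e-12) & (np.abs(cm) < _BIG / 2) & (np.abs(cp) < _BIG / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(valid, 0.5 * (cm - cp) / denom, 0.0)
    return surface + np.clip(shift, -0.5, 0.5)


@dataclass
class ChoroidSegmentationParams:
    """Knobs for the two-surface choroid segmentation."""

    max_step: int = 2
    smooth_sigma_z: float = 1.5
    smooth_sigma_lateral: float = 1.5
    rpe_band_halfwidth: int = 10
    min_thickness_um: float = 20.0
    max_thickness_um: float = 600.0
    bottom_margin_vox: int = 8
    clamp_fail_fraction: float = 0.05
    attenuation: AttenuationParams = field(default_factory=AttenuationParams)


def segment_choroid(
    volume: OCTVolume,
    params: ChoroidSegmentationParams | None = None,
    precompensated: bool = False,
) -> SurfaceSet:
    """Segment BM and CSI on a raw volume.

    BM is found with bright-to-dark polarity in a band around the
    brightest axial reflection (the RPE); CSI with bright-to-dark
    polarity on the attenuation-compensated volume, in a band below BM
    bounded by plausible choroidal thickness.  ``csi >= bm`` is enforced
    by clamping; if more than ``clamp_fail_fraction`` of A-scans need
    clamping the segmentation is considered failed and an error raised.
    """
    if params is None:
        params = ChoroidSegmentationParams()
    ny, nx, nz = volume.shape
    dz = volume.axial_spacing_um

    smoothed = gaussian_filter(
        np.asarray(volume.intensity, dtype=float),
        (params.smooth_sigma_lateral, params.smooth_sigma_lateral, 2.0),
        mode="nearest",
    )
    rpe_z = np.argmax(smoothed, axis=2)
    med_rpe = int(np.median(rpe_z))
    hw = params.rpe_band_halfwidth
    bm = segment_surface(
        volume,
        "bright_to_dark",
        max_step=params.max_step,
        band=(max(med_rpe - hw, 1), min(med_rpe + hw, nz - 2)),
        smooth_sigma_z=params.smooth_sigma_z,
        smooth_sigma_lateral=params.smooth_sigma_lateral,
    )

    comp = volume if precompensated else compensate_attenuation(volume, params.attenuation)
    lo = bm + params.min_thickness_um / dz
    hi = bm + params.max_thickness_um / dz
    hi = np.minimum(hi, nz - 1 - params.bottom_margin_vox)
    csi = segment_surface(
        comp,
        "bright_to_dark",
        max_step=params.max_step,
        band=(np.floor(lo), np.ceil(hi)),
        smooth_sigma_z=params.smooth_sigma_z,
        smooth_sigma_lateral=params.smooth_sigma_lateral,
    )

    clamped = csi < bm
    n_clamped = int(clamped.sum())
    if n_clamped > params.clamp_fail_fraction * bm.size:
        raise RuntimeError(
            f"segmentation failure: csi < bm at {n_clamped}/{bm.size} A-scans"
        )
    csi = np.maximum(csi, bm)
    return SurfaceSet(bm=bm, csi=csi, max_step=params.max_step)


# ---------------------------------------------------------------------------
# manual corrections


def read_corrections(path: str | Path) -> pd.DataFrame:
    """Corrections CSV with columns (surface, y, x, z)."""
    df = pd.read_csv(path)
    expected = {"surface", "y", "x", "z"}
    if not expected.issubset(df.columns):
        raise ValueError(f"corrections file must have columns {sorted(expected)}")
    return df


def apply_corrections(
    surfaces: SurfaceSet, corrections: pd.DataFrame | Sequence[tuple]
) -> SurfaceSet:
    """Overwrite listed A-scan depths and mark them manually corrected.

    ``corrections`` rows are ``(surface, y, x, z)`` with surface in
    {"bm", "csi"}.  A correction that would leave ``csi < bm`` raises,
    listing the offending coordinates.
    """
    if not isinstance(corrections, pd.DataFrame):
        corrections = pd.DataFrame(
            list(corrections), columns=["surface", "y", "x", "z"]
        )
    bm = surfaces.bm.copy()
    csi = surfaces.csi.copy()
    prov = surfaces.provenance.copy()
    for row in corrections.itertuples(index=False):
        y, x = int(row.y), int(row.x)
        if row.surface == "bm":
            bm[y, x] = float(row.z)
        elif row.surface == "csi":
            csi[y, x] = float(row.z)
        else:
            raise ValueError(f"unknown surface '{row.surface}'")
        prov[y, x] = "corrected"
    offenders = np.argwhere(bm > csi)
    if offenders.size:
        coords = ", ".join(f"(y={y}, x={x})" for y, x in offenders[:10])
        raise ValueError(f"corrections leave csi < bm at: {coords}")
    out = SurfaceSet(bm=bm, csi=csi, provenance=prov, max_step=None)
    return out
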