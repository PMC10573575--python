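"""Rigid en face registration between visits of the same eye.

Follow-up visits of one eye are acquired with small translations and
rotations of the scan raster relative to the reference visit.  The
retinal vasculature provides stable landmarks, so visits are aligned by
registering en face retinal-vessel projection images with a rigid
(translation + rotation) model: translation is estimated by subpixel
phase correlation at each candidate rotation on a grid, and the
candidate maximizing the normalized cross-correlation wins.  Maps and
masks measured in a follow-up frame are then warped into the reference
frame (linear interpolation for scalar maps, nearest for masks).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .volume import EnFaceMap


@dataclass
class RigidTransform2D:
    """Rigid motion of the scan raster: rotate by ``dtheta_deg`` about the
    image centre, then translate by ``(dx_px, dy_px)``.

    The transform maps reference-frame anatomy onto the moving visit's
    pixel grid; its :meth:`inverse` brings moving-frame data back.
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    dtheta_deg: float = 0.0
    reference_visit: str = ""
    moving_visit: str = ""
    score: float = float("nan")

    def inverse(self) -> "RigidTransform2D":
        th = np.deg2rad(self.dtheta_deg)
        c, s = np.cos(th), np.sin(th)
        # undo: rotate -theta, translate by -R(-theta) @ t
        dx = -(c * self.dx_px + s * self.dy_px)
        dy = -(-s * self.dx_px + c * self.dy_px)
        return RigidTransform2D(
            dx_px=dx,
            dy_px=dy,
            dtheta_deg=-self.dtheta_deg,
            reference_visit=self.moving_visit,
            moving_visit=self.reference_visit,
            score=self.score,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform2D":
        return cls(**json.loads(Path(path).read_text()))


def apply_rigid(
    arr: np.ndarray,
    transform: RigidTransform2D,
    order: int = 1,
    cval: float = np.nan,
) -> np.ndarray:
    """Apply a rigid transform to a 2-D array (forward warp).

    The output at pixel ``p`` samples the input at ``T^{-1}(p)``; pixels
    mapping outside the grid get ``cval``.
    """
    arr = np.asarray(arr)
    th = np.deg2rad(transform.dtheta_deg)
    c, s = np.cos(th), np.sin(th)
    # rotation matrix acting on (y, x) vectors
    r = np.array([[c, s], [-s, c]])
    m = np.linalg.inv(r)
    center = (np.asarray(arr.shape, dtype=float) - 1) / 2.0
    t = np.array([transform.dy_px, transform.dx_px])
    offset = center - m @ (center + t)
    return ndimage.affine_transform(
        arr.astype(float), m, offset=offset, order=order, cval=cval, mode="constant"
    )


def register_enface(
    moving: EnFaceMap | np.ndarray,
    fixed: EnFaceMap | np.ndarray,
    rotation_bound_deg: float = 5.0,
    rotation_step_deg: float = 0.25,
    upsample_factor: int = 20,
) -> RigidTransform2D:
    """Estimate the rigid transform taking the fixed frame to the moving one.

    For each candidate rotation, the de-rotated moving image is aligned
    to the fixed image by subpixel phase correlation; the candidate with
    the highest normalized cross-correlation of the re-aligned overlap
    is returned, with its score.  Raises on flat (zero-variance) images.
    """
    mov = _as_array(moving)
    fix = _as_array(fixed)
    if mov.shape != fix.shape:
        raise ValueError("moving and fixed maps must share a shape")
    if np.nanstd(mov) == 0 or np.nanstd(fix) == 0:
        raise ValueError("cannot register flat (zero-variance) images")
    mov0 = np.nan_to_num(mov, nan=float(np.nanmean(mov)))
    fix0 = np.nan_to_num(fix, nan=float(np.nanmean(fix)))

    best: RigidTransform2D | None = None
    thetas = np.arange(
        -rotation_bound_deg, rotation_bound_deg + rotation_step_deg / 2, rotation_step_deg
    )
    for theta in thetas:
        derot = apply_rigid(
            mov0, RigidTransform2D(dtheta_deg=-theta), order=1, cval=0.0
        )
        shift, _, _ = phase_cross_correlation(
            fix0, derot, upsample_factor=upsample_factor, normalization=None
        )
        # derot is fixed translated by R^{-1} t; skimage returns the shift
        # that moves `derot` onto `fixed`, i.e. -R^{-1} t
        th = np.deg2rad(theta)
        c, s = np.cos(th), np.sin(th)
        r = np.array([[c, s], [-s, c]])
        t_yx = -r @ shift
        cand = RigidTransform2D(
            dx_px=float(t_yx[1]), dy_px=float(t_yx[0]), dtheta_deg=float(theta)
        )
        score = _ncc_after_undo(mov0, fix0, cand)
        if best is None or score > best.score:
            cand.score = score
            best = cand
    assert best is not None
    return best


def _as_array(m: EnFaceMap | np.ndarray) -> np.ndarray:
    if isinstance(m, EnFaceMap):
        return m.masked
    return np.asarray(m, dtype=float)


def _ncc_after_undo(mov: np.ndarray, fix: np.ndarray, t: RigidTransform2D) -> float:
    back = apply_rigid(mov, t.inverse(), order=1, cval=np.nan)
    valid = np.isfinite(back) & np.isfinite(fix)
    if valid.sum() < 16:
        return -np.inf
    a = back[valid] - back[valid].mean()
    b = fix[valid] - fix[valid].mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return -np.inf
    return float((a * b).sum() / denom)


def warp(
    data: EnFaceMap | np.ndarray, transform: RigidTransform2D
) -> EnFaceMap | np.ndarray:
    """Warp a map or mask by a rigid transform.

    Scalar maps are linearly interpolated, boolean masks use nearest
    neighbour; out-of-bounds pixels become missing (maps) or False
    (masks).
    """
    if isinstance(data, EnFaceMap):
        warped = apply_rigid(data.masked, transform, order=1, cval=np.nan)
        return EnFaceMap(values=warped, units=data.units, missing=~np.isfinite(warped))
    arr = np.asarray(data)
    if arr.dtype == bool:
        warped = apply_rigid(arr.astype(float), transform, order=0, cval=0.0)
        return warped > 0.5
    warped = apply_rigid(arr.astype(float), transform, order=1, cval=np.nan)
    return warped
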