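"""Volume and en face map containers, disk I/O, quality gating and slab projection.

An :class:`OCTVolume` holds the structural intensity data of a single
eye-visit scan, indexed ``(y, x, z)``: ``y`` is the B-scan row, ``x`` the
A-scan column within a B-scan, and ``z`` the axial (depth) sample, with
``z = 0`` on the vitreous side increasing toward the sclera.  Physical
positions are ``index * spacing`` (0-based).

Volumes round-trip through a multi-page TIFF (one page per ``z``) plus a
JSON metadata sidecar; en face grids (surfaces, maps, masks) round-trip
through CSV with one row per ``y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import tifffile

VISIT_LABELS = ("pretreatment", "exudation", "post_treatment")

_REQUIRED_META = (
    "lateral_spacing_um",
    "axial_spacing_um",
    "fovea_center",
    "laterality",
    "signal_strength",
    "visit_label",
    "patient_id",
    "eye_id",
)


@dataclass
class OCTVolume:
    """A structural OCT volume with its acquisition metadata.

    Parameters
    ----------
    intensity
        Nonnegative array of shape ``(ny, nx, nz)``.
    lateral_spacing_um
        Spacing between adjacent A-scans (identical in x and y).
    axial_spacing_um
        Axial sample spacing.
    fovea_center
        ``(x, y)`` pixel coordinates of the fovea on the en face grid.
    onh_mask
        Optional ``(ny, nx)`` boolean mask of the optic nerve head.
    signal_strength
        Device-reported scan quality on a 0-10 integer scale (opaque
        beyond the ordering).
    """

    intensity: np.ndarray
    lateral_spacing_um: float = 24.0
    axial_spacing_um: float = 1.95
    fovea_center: tuple[float, float] = (0.0, 0.0)
    onh_mask: Optional[np.ndarray] = None
    laterality: Literal["OD", "OS"] = "OD"
    signal_strength: int = 10
    visit_label: str = "exudation"
    mnv_type: Optional[int] = None
    patient_id: str = "P000"
    eye_id: str = "P000-OD"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3-D (y, x, z) array")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        if self.lateral_spacing_um <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("spacings must be positive")
        ny, nx, _ = self.intensity.shape
        fx, fy = self.fovea_center
        if not (0 <= fx <= nx - 1 and 0 <= fy <= ny - 1):
            raise ValueError(
                f"fovea center {self.fovea_center} outside the {ny}x{nx} grid"
            )
        if self.visit_label not in VISIT_LABELS:
            raise ValueError(f"visit_label must be one of {VISIT_LABELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def nz(self) -> int:
        return self.intensity.shape[2]

    def with_intensity(self, intensity: np.ndarray) -> "OCTVolume":
        """Copy of this volume with the intensity data replaced."""
        return replace(self, intensity=intensity)


@dataclass
class EnFaceMap:
    """A 2-D scalar map over the en face (y, x) grid with missing support.

    ``units`` is one of ``um`` (thickness), ``ratio`` (CVI, values in
    [0, 1] where present) or ``intensity`` (projections).
    """

    values: np.ndarray
    units: Literal["um", "ratio", "intensity"] = "intensity"
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape mismatch")
        if self.units == "ratio":
            present = self.values[~self.missing]
            if present.size and (present.min() < -1e-9 or present.max() > 1 + 1e-9):
                raise ValueError("ratio map values must lie in [0, 1]")

    @property
    def masked(self) -> np.ndarray:
        """Values with missing entries as NaN."""
        out = self.values.astype(float).copy()
        out[self.missing] = np.nan
        return out


class QualityGateResult(tuple):
    """(passed, reason) pair; truthy iff the scan passed."""

    def __new__(cls, passed: bool, reason: str):
        return super().__new__(cls, (passed, reason))

    def __bool__(self) -> bool:  # noqa: D105
        return bool(self[0])

    passed = property(lambda self: self[0])
    reason = property(lambda self: self[1])


def quality_gate(volume: OCTVolume, min_signal: int = 7) -> QualityGateResult:
    """Apply the scan-quality exclusion rule.

    A scan fails if and only if its signal strength is *below*
    ``min_signal``; a scan exactly at the threshold passes.
    """
    ss = volume.signal_strength
    if ss < min_signal:
        return QualityGateResult(
            False, f"signal_strength {ss} below minimum {min_signal}"
        )
    return QualityGateResult(True, f"signal_strength {ss} >= {min_signal}")


# ---------------------------------------------------------------------------
# disk I/O


def write_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (pages along z) + JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(volume.intensity, 2, 0)  # (nz, ny, nx)
    tifffile.imwrite(path, pages)
    meta = {
        "lateral_spacing_um": volume.lateral_spacing_um,
        "axial_spacing_um": volume.axial_spacing_um,
        "fovea_center": list(volume.fovea_center),
        "laterality": volume.laterality,
        "signal_strength": volume.signal_strength,
        "visit_label": volume.visit_label,
        "mnv_type": volume.mnv_type,
        "patient_id": volume.patient_id,
        "eye_id": volume.eye_id,
        "shape": list(volume.intensity.shape),
    }
    if volume.onh_mask is not None:
        meta["onh_mask"] = volume.onh_mask.astype(int).tolist()
    _sidecar(path).write_text(json.dumps(meta))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path: str | Path, metadata_path: str | Path | None = None) -> OCTVolume:
    """Read a volume written by :func:`write_volume`.

    Round-trips are bit-exact for integer volumes.  Raises ``KeyError``
    naming the first missing metadata field, and ``ValueError`` on a
    page-count/shape mismatch.
    """
    path = Path(path)
    meta_path = Path(metadata_path) if metadata_path is not None else _sidecar(path)
    meta = json.loads(meta_path.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise KeyError(f"metadata missing required field '{key}'")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    intensity = np.moveaxis(pages, 0, 2)
    if "shape" in meta and list(intensity.shape) != list(meta["shape"]):
        raise ValueError(
            f"TIFF shape {intensity.shape} does not match metadata {meta['shape']}"
        )
    onh = meta.get("onh_mask")
    return OCTVolume(
        intensity=intensity,
        lateral_spacing_um=meta["lateral_spacing_um"],
        axial_spacing_um=meta["axial_spacing_um"],
        fovea_center=tuple(meta["fovea_center"]),
        onh_mask=None if onh is None else np.asarray(onh, dtype=bool),
        laterality=meta["laterality"],
        signal_strength=meta["signal_strength"],
        visit_label=meta["visit_label"],
        mnv_type=meta.get("mnv_type"),
        patient_id=meta["patient_id"],
        eye_id=meta["eye_id"],
    )


def write_grid(grid: np.ndarray, path: str | Path) -> None:
    """Write a 2-D grid (surface, map or mask) as CSV, one row per y."""
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",")


def read_grid(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_map(m: EnFaceMap, path: str | Path) -> None:
    """Write an en face map as CSV with NaN marking missing pixels."""
    np.savetxt(path, m.masked, delimiter=",")


def read_map(path: str | Path, units: str = "intensity") -> EnFaceMap:
    values = read_grid(path)
    return EnFaceMap(values=values, units=units)  # missing inferred from NaN


# ---------------------------------------------------------------------------
# slab projection


def project_slab(
    volume: OCTVolume,
    top: np.ndarray,
    bottom: np.ndarray,
    reducer: Literal["mean", "max", "sum"] = "mean",
) -> EnFaceMap:
    """Reduce intensities over the half-open slab ``z in [top, bottom)``.

    ``top`` and ``bottom`` are per-A-scan depth grids in voxel units
    (fractional allowed; a voxel at integer ``z`` is inside the slab when
    ``top <= z < bottom``).  A-scans with an empty slab are missing in the
    output.  Raises ``ValueError`` (with the offending count) if the
    surfaces cross.
    """
    top = np.broadcast_to(np.asarray(top, dtype=float), volume.shape[:2])
    bottom = np.broadcast_to(np.asarray(bottom, dtype=float), volume.shape[:2])
    crossing = int(np.sum(top > bottom))
    if crossing:
        raise ValueError(f"surfaces cross at {crossing} A-scans (top > bottom)")
    z = np.arange(volume.nz)
    inside = (z >= top[..., None]) & (z < bottom[..., None])
    counts = inside.sum(axis=2)
    data = volume.intensity.astype(float)
    if reducer == "mean":
        total = np.where(inside, data, 0.0).sum(axis=2)
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    elif reducer == "sum":
        values = np.where(inside, data, 0.0).sum(axis=2)
        values = np.where(counts > 0, values, np.nan)
    elif reducer == "max":
        values = np.where(inside, data, -np.inf).max(axis=2)
        values = np.where(counts > 0, values, np.nan)
    else:
        raise ValueError(f"unknown reducer '{reducer}'")
    return EnFaceMap(values=values, units="intensity", missing=counts == 0)
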