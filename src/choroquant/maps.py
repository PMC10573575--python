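"""En face choroidal thickness, Otsu vessel binarization and CVI maps.

The choroidal slab of an A-scan is the half-open voxel range
``[round(bm), round(csi))`` (round-half-up), so that voxel counts are
integers and adjacent slabs never share a voxel.  Choroidal thickness is
the BM-to-CSI distance in micrometres; the choroidal vascularity index
(CVI) of an A-scan is the fraction of its slab voxels classified as
vessel lumen.  Lumina are hyporeflective in structural OCT, so a voxel is
vessel when its (attenuation-compensated) intensity falls *below* a
global Otsu threshold computed from all slab voxels of the eye-visit.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .surfaces import SurfaceSet
from .volume import EnFaceMap, OCTVolume


def round_half_up(a: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 going up (unlike banker's rounding)."""
    return np.floor(np.asarray(a, dtype=float) + 0.5).astype(int)


def slab_bounds(surfaces: SurfaceSet) -> tuple[np.ndarray, np.ndarray]:
    """Integer voxel bounds ``[zlo, zhi)`` of the choroidal slab per A-scan."""
    zlo = round_half_up(surfaces.bm)
    zhi = round_half_up(surfaces.csi)
    return zlo, np.maximum(zhi, zlo)


def slab_mask(volume_shape: tuple[int, int, int], surfaces: SurfaceSet) -> np.ndarray:
    """3-D boolean mask of the choroidal slab."""
    zlo, zhi = slab_bounds(surfaces)
    z = np.arange(volume_shape[2])
    return (z >= zlo[..., None]) & (z < zhi[..., None])


def thickness_map(surfaces: SurfaceSet, axial_spacing_um: float) -> EnFaceMap:
    """Choroidal thickness in micrometres: ``(csi - bm) * axial_spacing``."""
    values = (surfaces.csi - surfaces.bm) * axial_spacing_um
    missing = np.zeros(values.shape, dtype=bool)
    return EnFaceMap(values=values, units="um", missing=missing)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Global Otsu threshold of a value sample over a ``nbins``-bin histogram.

    Returns the bin edge maximizing the between-class variance; ties are
    broken toward the lower threshold.  Raises on (near-)constant input,
    for which no threshold separates two classes.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2 or values.min() == values.max():
        raise ValueError("Otsu threshold undefined for constant input")
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    # The between-class variance ranking is invariant to affine rescaling of
    # the values, so it can be evaluated on integer bin indices with exact
    # arithmetic: between_k  (S0*N1 - S1*N0)^2 / (N0*N1) with N/S the class
    # counts and index sums.  Exactness makes near-ties deterministic.
    total_n = int(counts.sum())
    total_s = int((counts * np.arange(nbins)).sum())
    best_num, best_den, best_k = -1, 1, None
    n0 = 0
    s0 = 0
    for k in range(nbins - 1):
        n0 += int(counts[k])
        s0 += int(counts[k]) * k
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        s1 = total_s - s0
        num = (s0 * n1 - s1 * n0) ** 2
        den = n0 * n1
        # strict improvement only: ties stay at the lower threshold
        if num * best_den > best_num * den:
            best_num, best_den, best_k = num, den, k
    if best_k is None:
        raise ValueError("Otsu threshold undefined: all mass in one bin")
    return float(edges[best_k + 1])


def _representation(
    data: np.ndarray, despeckle_sigma_z: float, scale: str
) -> np.ndarray:
    """The intensity representation used for thresholding.

    ``scale='log'`` works on the logarithmic (dB-like) scale on which
    OCT data are conventionally displayed: multiplicative speckle
    becomes additive there, and the two reflectivity classes have
    comparable spreads, which suits a variance-based threshold.
    Optional axial Gaussian despeckling is applied in the same domain.
    """
    data = np.asarray(data, dtype=float)
    if scale == "log":
        data = np.log(np.maximum(data, 1e-300))
    elif scale != "linear":
        raise ValueError(f"unknown intensity scale '{scale}'")
    if despeckle_sigma_z > 0:
        data = gaussian_filter1d(data, despeckle_sigma_z, axis=2, mode="nearest")
    return data


def binarize_vessels(
    volume: OCTVolume,
    surfaces: SurfaceSet,
    threshold: float,
    despeckle_sigma_z: float = 0.0,
    scale: str = "log",
) -> np.ndarray:
    """Vessel mask: slab voxels whose representation falls strictly below
    ``threshold``.

    ``threshold`` must come from :func:`otsu_threshold` applied to
    :func:`slab_intensities` with the same ``despeckle_sigma_z`` and
    ``scale``, so both live in the same domain.
    """
    data = _representation(volume.intensity, despeckle_sigma_z, scale)
    inside = slab_mask(volume.shape, surfaces)
    return inside & (data < threshold)


def slab_intensities(
    volume: OCTVolume,
    surfaces: SurfaceSet,
    despeckle_sigma_z: float = 0.0,
    scale: str = "log",
) -> np.ndarray:
    """1-D array of the representation values of all slab voxels."""
    data = _representation(volume.intensity, despeckle_sigma_z, scale)
    return data[slab_mask(volume.shape, surfaces)]


def cvi_map(vessel_mask: np.ndarray, surfaces: SurfaceSet) -> EnFaceMap:
    """Per-A-scan vessel fraction over the choroidal slab.

    ``value(y, x) = vessel voxels / slab voxels`` over ``z in [bm, csi)``
    (integer counting); A-scans with an empty slab are missing.
    """
    zlo, zhi = slab_bounds(surfaces)
    z = np.arange(vessel_mask.shape[2])
    inside = (z >= zlo[..., None]) & (z < zhi[..., None])
    slab_counts = inside.sum(axis=2)
    vessel_counts = (vessel_mask & inside).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(slab_counts > 0, vessel_counts / np.maximum(slab_counts, 1), np.nan)
    return EnFaceMap(values=values, units="ratio", missing=slab_counts == 0)


def global_cvi(vessel_mask: np.ndarray, surfaces: SurfaceSet) -> float:
    """Pooled vessel fraction: total vessel voxels / total slab voxels."""
    inside = slab_mask(vessel_mask.shape, surfaces)
    total = int(inside.sum())
    if total == 0:
        return float("nan")
    return float((vessel_mask & inside).sum() / total)
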