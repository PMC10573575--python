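"""Fovea-centered regions, exclusion masks, eligibility and regional means.

Measurements are summarized over three fovea-centered regions of the en
face grid: a 5-mm-diameter circle, an 11-mm-diameter circle, and the
6-mm-wide annular rim between their outer boundaries (3 mm radially).
The optic nerve head and any per-visit manually outlined exclusion
areas (shadowing from exudation or pigment epithelial detachments) are
removed from every visit of a subject; an eye is ineligible for CVI
analysis when the excluded area covers more than 10% of the 5-mm
circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import EnFaceMap


@dataclass
class RegionSpec:
    """Geometry of the fovea-centered analysis regions."""

    fovea_center: tuple[float, float]  # (x, y) pixels
    lateral_spacing_um: float
    inner_diameter_mm: float = 5.0
    outer_diameter_mm: float = 11.0

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0 or self.outer_diameter_mm <= 0:
            raise ValueError("diameters must be positive")
        if self.lateral_spacing_um <= 0:
            raise ValueError("lateral spacing must be positive")


def circle_mask(
    spec: RegionSpec, diameter_mm: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within ``diameter/2`` of the fovea.

    Distances are Euclidean in physical units (pixel position = index
    times lateral spacing).  Raises if the circle extends beyond the
    grid, reporting the overflow in mm.
    """
    ny, nx = shape
    radius_um = diameter_mm * 1000.0 / 2.0
    fx, fy = spec.fovea_center
    sp = spec.lateral_spacing_um
    if radius_um > 0:
        over = max(
            radius_um - fx * sp,
            radius_um - fy * sp,
            radius_um - (nx - 1 - fx) * sp,
            radius_um - (ny - 1 - fy) * sp,
        )
        if over > sp / 2:  # allow sub-pixel slack at the border
            raise ValueError(
                f"{diameter_mm}-mm circle exceeds the grid by {over / 1000.0:.2f} mm"
            )
    y = (np.arange(ny) - fy) * sp
    x = (np.arange(nx) - fx) * sp
    dist2 = y[:, None] ** 2 + x[None, :] ** 2
    return dist2 <= radius_um**2


def region_masks(spec: RegionSpec, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """The three analysis regions: circle5, circle11 and rim = circle11 \\ circle5."""
    inner = circle_mask(spec, spec.inner_diameter_mm, shape)
    outer = circle_mask(spec, spec.outer_diameter_mm, shape)
    return {"circle5": inner, "circle11": outer, "rim": outer & ~inner}


@dataclass
class MaskSet:
    """ONH and per-visit exclusion masks, combined in the reference frame.

    ``combined_exclusion`` is the union of the (registered) per-visit
    exclusions, so an area unreliable at any visit is excluded from all
    visits of the subject.
    """

    shape: tuple[int, int]
    onh_mask: np.ndarray | None = None
    visit_exclusions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def combined_exclusion(self) -> np.ndarray:
        combined = np.zeros(self.shape, dtype=bool)
        for mask in self.visit_exclusions.values():
            if mask.shape != self.shape:
                raise ValueError("exclusion mask shape mismatch")
            combined |= mask
        return combined


def combine_exclusions(maskset: MaskSet, region: np.ndarray) -> np.ndarray:
    """Effective analysis mask: region minus ONH minus combined exclusions."""
    if region.shape != maskset.shape:
        raise ValueError(
            f"region shape {region.shape} does not match mask set {maskset.shape}"
        )
    out = region.copy()
    if maskset.onh_mask is not None:
        if maskset.onh_mask.shape != maskset.shape:
            raise ValueError("ONH mask shape mismatch")
        out &= ~maskset.onh_mask
    out &= ~maskset.combined_exclusion
    return out


def cvi_eligibility(
    combined_exclusion: np.ndarray,
    circle5_mask: np.ndarray,
    max_fraction: float = 0.10,
) -> tuple[bool, float]:
    """CVI eligibility rule: exclude the eye only when *more than* 10%
    of the 5-mm circle is masked out.

    Returns ``(eligible, excluded_fraction)``; a fraction of exactly
    ``max_fraction`` is still eligible.
    """
    n_circle = int(circle5_mask.sum())
    if n_circle == 0:
        raise ValueError("empty 5-mm circle mask")
    fraction = float((combined_exclusion & circle5_mask).sum() / n_circle)
    return fraction <= max_fraction, fraction


@dataclass
class RegionalMean:
    value: float
    n_pixels: int

    @property
    def missing(self) -> bool:
        return self.n_pixels == 0


def regional_mean(m: EnFaceMap, analysis_mask: np.ndarray) -> RegionalMean:
    """Unweighted mean of the map over included, non-missing pixels.

    A fully excluded/missing region yields an explicit missing result
    (NaN value, zero count), never a silent zero.
    """
    if analysis_mask.shape != m.values.shape:
        raise ValueError("analysis mask shape mismatch")
    include = analysis_mask & ~m.missing
    n = int(include.sum())
    if n == 0:
        return RegionalMean(value=float("nan"), n_pixels=0)
    return RegionalMean(value=float(m.values[include].mean()), n_pixels=n)
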