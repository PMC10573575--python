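"""Depth-resolved optical attenuation compensation.

Deep structures in OCT are shadowed by the cumulative extinction of the
tissue above them; in the choroid this depresses the signal under the RPE
and under exudative lesions, degrading the contrast of the
choroidal-scleral interface.  Compensation rescales each voxel by the
remaining (tail) signal energy beneath it:

    corrected(z) = I(z)**n / (2 * sum_{z' >= z} I(z')**n + eps)

per A-scan, with contrast exponent ``n`` (default 2).  A purely
multiplicative shadow acting on the whole tail of an A-scan cancels out of
this ratio, which is what suppresses shadowing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .volume import OCTVolume


@dataclass
class AttenuationParams:
    """Parameters of the compensation transform.

    ``epsilon`` stabilizes empty tails; if ``None`` it defaults to
    ``1e-8 * max(I)**n``, which makes the transform invariant to a global
    intensity rescaling of the input.
    """

    exponent_n: float = 2.0
    epsilon: float | None = None
    rescale: Literal["none", "max"] = "none"

    def __post_init__(self) -> None:
        if self.exponent_n <= 0:
            raise ValueError("exponent_n must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def compensate_column(column: np.ndarray, params: AttenuationParams | None = None) -> np.ndarray:
    """Compensate a single A-scan (1-D array); used as a readable reference."""
    column = np.asarray(column, dtype=float)[None, None, :]
    vol = OCTVolume(intensity=column)
    return compensate_attenuation(vol, params).intensity[0, 0]


def compensate_attenuation(
    volume: OCTVolume, params: AttenuationParams | None = None
) -> OCTVolume:
    """Return a new volume with attenuation-compensated intensities.

    Raises ``ValueError`` on negative input intensities.  The output is
    finite everywhere (all-zero tails map to 0 through ``epsilon``).
    """
    if params is None:
        params = AttenuationParams()
    data = np.asarray(volume.intensity, dtype=float)
    if np.any(data < 0):
        raise ValueError("attenuation compensation requires nonnegative intensities")
    n = params.exponent_n
    powered = data**n
    eps = params.epsilon
    if eps is None:
        peak = float(powered.max())
        eps = 1e-8 * peak if peak > 0 else 1e-8
    # tail[z] = sum over z' >= z, computed as a reversed cumulative sum
    tail = np.flip(np.cumsum(np.flip(powered, axis=2), axis=2), axis=2)
    corrected = powered / (2.0 * tail + eps)
    if params.rescale == "max":
        peak = corrected.max()
        if peak > 0:
            corrected = corrected / peak
    if not np.all(np.isfinite(corrected)):
        raise FloatingPointError("non-finite values after compensation")
    return volume.with_intensity(corrected)
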