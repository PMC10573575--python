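"""Optional rendering of en face maps to PNG (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .volume import EnFaceMap

_DEFAULT_RANGES = {"um": (0.0, 500.0), "ratio": (0.0, 1.0)}


def render_map(
    m: EnFaceMap,
    path: str | Path,
    cmap: str = "turbo",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Render a map with a fixed colormap and units-appropriate range;
    missing pixels are drawn black."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    lo, hi = _DEFAULT_RANGES.get(m.units, (None, None))
    vmin = lo if vmin is None else vmin
    vmax = hi if vmax is None else vmax
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    data = np.ma.masked_invalid(m.masked)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    im = ax.imshow(data, cmap=cm, vmin=vmin, vmax=vmax, origin="upper")
    fig.colorbar(im, ax=ax, shrink=0.8, label=m.units)
    ax.set_xlabel("x (A-scan)")
    ax.set_ylabel("y (B-scan)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
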