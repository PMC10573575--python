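"""Independent brute-force Otsu oracle shared by the test modules."""

from fractions import Fraction

import numpy as np


def brute_force_otsu(values, nbins=256):
    """Exhaustive search over all bin-edge thresholds, maximizing the
    between-class variance of the binned values; ties go to the lower edge.

    Uses exact rational arithmetic on the bin histogram so that near-ties
    are resolved deterministically.
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    idx = np.arange(nbins)
    total_n = int(counts.sum())
    total_s = int((counts * idx).sum())
    best, best_k = Fraction(-1), None
    for k in range(nbins - 1):
        n0 = int(counts[: k + 1].sum())
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        s0 = int((counts[: k + 1] * idx[: k + 1]).sum())
        s1 = total_s - s0
        mu0 = Fraction(s0, n0)
        mu1 = Fraction(s1, n1)
        between = Fraction(n0) * Fraction(n1) * (mu0 - mu1) ** 2
        if between > best:
            best, best_k = between, k
    return float(edges[best_k + 1])
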