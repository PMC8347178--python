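"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's spatial-index code paths: histograms
are computed from the full O(n²) distance matrix and colocalization from
explicit distance minima, so they can serve as ground truth for the k-d
tree implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist


def brute_pairwise_hist(points: np.ndarray, r_max: float, bin_width: float):
    """All-pairs relative distance histogram (unordered pairs, d < r_max)."""
    d = pdist(points)
    d = d[d < r_max]
    edges = np.arange(int(np.ceil(r_max / bin_width)) + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    n = counts.sum()
    return counts / n if n else counts.astype(float), int(n)


def brute_cross_hist(a: np.ndarray, b: np.ndarray, r_max: float, bin_width: float):
    """All ordered A–B pairs with d < r_max."""
    d = cdist(a, b).ravel()
    d = d[d < r_max]
    edges = np.arange(int(np.ceil(r_max / bin_width)) + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    n = counts.sum()
    return counts / n if n else counts.astype(float), int(n)


def brute_coloc(a: np.ndarray, b: np.ndarray, radius: float):
    """Percent of each channel with a partner within radius, via full cdist."""
    d = cdist(a, b)
    pct_a = 100.0 * (d.min(axis=1) <= radius).mean()
    pct_b = 100.0 * (d.min(axis=0) <= radius).mean()
    return pct_a, pct_b


def thompson_precision_nm(
    psf_sigma_nm: float, pixel_nm: float, photons: float, bg_noise_sd: float
) -> float:
    """Closed-form single-emitter localization precision (per axis, nm)."""
    s2 = psf_sigma_nm**2
    a2 = pixel_nm**2
    var = (
        s2 / photons
        + a2 / (12.0 * photons)
        + 8.0 * np.pi * s2**2 * bg_noise_sd**2 / (a2 * photons**2)
    )
    return float(np.sqrt(var))
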