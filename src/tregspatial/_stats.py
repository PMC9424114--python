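"""Small statistical primitives shared across the pipeline.

All percentile thresholds in this package use the nearest-rank order
statistic (the ceil(q*n)-th value of the ascending sort) rather than an
interpolated quantile: it is deterministic, matches how a rank cutoff on a
finite permuted distribution is defined, and is directly checkable against
a sort-based oracle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import gaussian_kde


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic.

    Parameters
    ----------
    values : array-like
        Finite sample, n >= 1.
    q : float
        Percentile as a fraction in (0, 1].
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("nearest-rank percentile of an empty sample is undefined")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    rank = math.ceil(q * n)  # 1-based
    return float(arr[rank - 1])


def kde_valley_cutoff(values, min_n: int = 30) -> float:
    """Cutoff between the two largest modes of a 1-D sample.

    Fits a Gaussian kernel-density estimate (Silverman bandwidth), locates its
    local maxima on a dense grid, and returns the position of the deepest
    local minimum between the two highest modes.  Raises ``ValueError`` when
    the density is unimodal (no interior minimum), in which case a manual
    cutoff must be supplied by the caller.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise ValueError(
            f"automatic cutoff needs at least {min_n} values, got {arr.size}"
        )
    kde = gaussian_kde(arr, bw_method="silverman")
    lo, hi = arr.min(), arr.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, 2048)
    dens = kde(grid)

    interior = np.arange(1, grid.size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    maxima = interior[is_max]
    if maxima.size < 2:
        raise ValueError(
            "density estimate is unimodal; supply a manual cutoff instead of 'auto'"
        )
    # two highest modes, in position order
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    seg = np.arange(left + 1, right)
    if seg.size == 0:
        raise ValueError(
            "density estimate has no interior minimum between modes; supply a manual cutoff"
        )
    cut_idx = seg[np.argmin(dens[seg])]
    return float(grid[cut_idx])
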