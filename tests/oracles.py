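"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: calibration is redone by
dense-grid numerical integration straight from the curve knots, and binning
by a naive agglomerative loop over pairwise distances.
"""

from __future__ import annotations

import numpy as np


def brute_force_calibration(cra: float, error: float, knots_calbp, knots_mu,
                            knots_sigma, step: float = 0.2):
    """Calibrate by direct integration on a dense calendar grid.

    Linearly interpolates the curve knots onto a ``step``-year grid,
    evaluates the normal density of the CRA at every grid year, and returns
    ``(grid, normalised weights)`` with the grid increasing in cal BP.
    """
    calbp = np.asarray(knots_calbp, dtype=float)
    mu = np.asarray(knots_mu, dtype=float)
    sig = np.asarray(knots_sigma, dtype=float)
    order = np.argsort(calbp)
    calbp, mu, sig = calbp[order], mu[order], sig[order]
    grid = np.arange(calbp[0], calbp[-1] + step / 2, step)
    m = np.interp(grid, calbp, mu)
    s = np.interp(grid, calbp, sig)
    w = np.sqrt(error ** 2 + s ** 2)
    dens = np.exp(-0.5 * ((cra - m) / w) ** 2) / w
    tot = dens.sum()
    if tot <= 0:
        raise ValueError("no mass anywhere on the curve")
    return grid, dens / tot


def brute_force_quantile(q: float, grid, weights) -> float:
    """Quantile of a brute-force density, scanning old -> young cal BP."""
    grid = np.asarray(grid)[::-1]       # decreasing, to match package scan
    weights = np.asarray(weights)[::-1]
    c = np.cumsum(weights) / weights.sum()
    return float(grid[int(np.searchsorted(c, q))])


def naive_complete_linkage(cras, h: float) -> list[tuple[float, ...]]:
    """Agglomerative complete-linkage clustering cut at height ``h``.

    Repeatedly merges the pair of clusters with the smallest maximum
    pairwise |dCRA| while that distance is <= h.  Returns the partition as a
    sorted list of sorted CRA tuples.
    """
    clusters = [[float(c)] for c in cras]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(abs(a - b) for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        if d > h:
            break
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(tuple(sorted(c)) for c in clusters)
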