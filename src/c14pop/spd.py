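"""Site-level binning and summed probability distributions (SPDs).

Heavily investigated sites contribute disproportionately many dates
("wealth" or ascertainment bias).  The standard correction clusters each
site's dates on their uncalibrated CRAs — complete-linkage agglomeration cut
at a threshold ``h`` (default 200 14C years) — and pools each cluster (bin)
into a single mean density before summing across bins.  The bin, not the
date, is the exchangeable unit of all significance tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .calibrate import CalDensity
from .dates_io import UncalDate

__all__ = [
    "Bin",
    "BinSet",
    "SPD",
    "make_bins",
    "bin_density",
    "sum_spd",
    "rolling_mean",
    "analysis_grid",
]


@dataclass(frozen=True)
class Bin:
    bin_id: str
    site_id: str
    set_label: str
    members: tuple[int, ...]  # indices into the originating date table


@dataclass
class BinSet:
    """Per-site clusters of dates, the exchangeable unit of the tests."""

    bins: list[Bin]
    h: float

    def labels(self) -> np.ndarray:
        return np.array([b.set_label for b in self.bins])

    def counts(self) -> dict[str, int]:
        lab, cnt = np.unique(self.labels(), return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))

    def subset(self, set_label: str) -> "BinSet":
        return BinSet([b for b in self.bins if b.set_label == set_label], self.h)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(i, b.bin_id, b.site_id, b.set_label)
                for b in self.bins for i in b.members]
        return pd.DataFrame(rows, columns=["date_index", "bin_id", "site_id",
                                           "set_label"])


@dataclass
class SPD:
    """Year-wise summed probability over an analysis range.

    ``density`` sums to at most ``n_bins`` — mass calibrated outside the
    analysis window is retained there, not renormalised away.
    """

    calbp: np.ndarray
    density: np.ndarray
    set_label: str = ""
    n_bins: int = 0
    n_dates: int = 0

    def __post_init__(self) -> None:
        self.calbp = np.asarray(self.calbp, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.calbp.shape != self.density.shape:
            raise ValueError("grid/density length mismatch")
        if (self.density < 0).any():
            raise ValueError("negative SPD density")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.calbp, self.density]),
                   delimiter=",", header="calbp,density", comments="")


def analysis_grid(range_: tuple[float, float]) -> np.ndarray:
    """Annual decreasing grid over an (old, young) cal BP analysis range."""
    old, young = float(range_[0]), float(range_[1])
    if not old > young:
        raise ValueError("range must be (old, young) with old > young")
    return np.arange(old, young - 0.5, -1.0)


def make_bins(table: list[UncalDate], h: float = 200.0) -> BinSet:
    """Cluster each site's dates on CRA by complete linkage, cut at ``h``.

    Every merge in a retained cluster has complete-linkage height <= h.  A
    site with one date yields one bin; ``h = 0`` separates distinct CRAs;
    ``h = inf`` gives one bin per site.  Bin ids are ``site__k`` with bins
    ordered oldest-first by mean CRA.  Deterministic: dates are sorted by
    (CRA, lab id) within site before clustering.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    # keyed site-first so bin ordering is independent of set labelling
    by_site: dict[tuple[str, str], list[int]] = {}
    for i, d in enumerate(table):
        by_site.setdefault((d.site_id, d.set_label), []).append(i)
    bins: list[Bin] = []
    for (site_id, set_label) in sorted(by_site):
        idx = sorted(by_site[(site_id, set_label)],
                     key=lambda i: (table[i].cra, table[i].lab_id))
        cras = np.array([table[i].cra for i in idx], dtype=float)
        if len(idx) == 1:
            assign = np.array([1])
        else:
            Z = linkage(cras[:, None], method="complete")
            assign = fcluster(Z, t=h, criterion="distance")
        clusters: dict[int, list[int]] = {}
        for i, c in zip(idx, assign):
            clusters.setdefault(int(c), []).append(i)
        ordered = sorted(clusters.values(),
                         key=lambda mem: -np.mean([table[i].cra for i in mem]))
        for k, mem in enumerate(ordered, start=1):
            bins.append(Bin(f"{site_id}__{k}", site_id, set_label, tuple(mem)))
    return BinSet(bins, float(h))


def _on_grid(dens: CalDensity, grid: np.ndarray) -> np.ndarray:
    """Project an annual density onto an annual decreasing target grid."""
    out = np.zeros(grid.size)
    off = int(round(grid[0] - dens.calbp[0]))  # both decreasing, 1-yr spacing
    lo = max(off, 0)
    hi = min(off + dens.calbp.size, grid.size)
    if hi > lo:
        out[lo:hi] = dens.prob[lo - off:hi - off]
    return out


def bin_density(members: list[CalDensity], grid: np.ndarray) -> CalDensity:
    """Pooled (arithmetic mean) density of a bin's member dates on ``grid``.

    Sums to <= 1; equal to 1 when every member's support lies inside
    the grid.
    """
    if not members:
        raise ValueError("bin has no member densities")
    acc = np.zeros(grid.size)
    for m in members:
        acc += _on_grid(m, grid)
    return CalDensity(grid, acc / len(members), normalised=False)


def sum_spd(binset: BinSet, densities: dict[int, CalDensity],
            range_: tuple[float, float], set_label: str | None = None) -> SPD:
    """Sum pooled bin densities over the analysis range.

    ``densities`` maps date-table indices to calibrated densities; every bin
    member must be present.  If ``set_label`` is given only that set's bins
    are summed.
    """
    grid = analysis_grid(range_)
    bins = binset.bins if set_label is None else binset.subset(set_label).bins
    acc = np.zeros(grid.size)
    n_dates = 0
    for b in bins:
        acc += bin_density([densities[i] for i in b.members], grid).prob
        n_dates += len(b.members)
    return SPD(grid, acc, set_label=set_label or "", n_bins=len(bins),
               n_dates=n_dates)


def rolling_mean(spd: SPD, window: int = 200) -> SPD:
    """Centred rolling mean for display; edges average truncated windows.

    The effective window is ``2*(window//2) + 1`` years (odd, centred);
    ``window = 1`` is the identity.  The raw density is left untouched.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    x = spd.density
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    sm = (cs[hi] - cs[lo]) / (hi - lo)
    return SPD(spd.calbp.copy(), sm, set_label=spd.set_label,
               n_bins=spd.n_bins, n_dates=spd.n_dates)
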