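"""Bin-label permutation test comparing the SPD shapes of k >= 2 date sets.

Null hypothesis: the sets' dates were generated from identically shaped
calendar-date densities, so bin-to-set labels are exchangeable.  Whole bins
(never individual dates) are randomly reassigned to sets, preserving each
set's observed bin count exactly; each permutation yields one SPD per set.
Per set, the observed SPD is z-scored against the permutation distribution
and compared with a 95% envelope of permuted z-scores; the total area
outside the envelope gives a per-set global statistic whose permutation
tail probability is the p-value.  Because everything is z-scored, the test
compares SPD *shapes* and is insensitive to inter-set differences in sample
size or research intensity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .calcurve import CalibrationCurve
from .calibrate import DEFAULT_EPS, _annual, calibrate
from .dates_io import UncalDate
from .model_test import EnvelopeResult, _envelope_stats, _intervals
from .spd import BinSet, analysis_grid, bin_density, make_bins

__all__ = ["PermTestResult", "permute_labels", "perm_test"]


def permute_labels(labels, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the multiset of set labels.

    Per-label counts are preserved exactly — only the assignment of labels
    to bins changes.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 distinct labels to permute")
    return labels[rng.permutation(labels.size)]


@dataclass
class PermTestResult:
    """Per-set envelope results of one permutation run."""

    sets: dict[str, EnvelopeResult]
    nsim: int
    range_: tuple[float, float]

    def pvalues(self) -> dict[str, float]:
        return {k: r.pvalue for k, r in self.sets.items()}

    def to_json(self, path=None) -> str:
        obj = {"nsim": self.nsim, "range": list(self.range_),
               "sets": {k: json.loads(r.to_json()) for k, r in self.sets.items()}}
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _bin_matrix(table, curve, binset, densities, grid):
    """(n_bins x T) matrix of pooled bin densities on the analysis grid."""
    B = np.empty((len(binset.bins), grid.size))
    for j, b in enumerate(binset.bins):
        B[j] = bin_density([densities[i] for i in b.members], grid).prob
    return B


def perm_test(table: list[UncalDate], curve: CalibrationCurve,
              nsim: int = 10000,
              range_: tuple[float, float] = (7000.0, 3000.0),
              h: float = 200.0, rng: np.random.Generator | None = None,
              seed: int | None = None, eps: float = DEFAULT_EPS,
              scale: str = "z", min_run: int = 1,
              binset: BinSet | None = None,
              densities: dict | None = None) -> PermTestResult:
    """Run the k-set bin-label permutation test.

    All sets present in ``table`` (>= 2) are compared against the pooled
    aggregate; for a strictly pairwise comparison pass a table restricted to
    the two sets.  ``range_`` clips the grid before any statistic is
    computed, so envelopes and global p-values refer to the clipped window.
    Significant intervals shorter than ``min_run`` years are dropped
    (default 1 = keep all).
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    curve = _annual(curve)
    if binset is None:
        binset = make_bins(table, h)
    if densities is None:
        densities = {i: calibrate(d.cra, d.error, curve, eps)
                     for i, d in enumerate(table)}
    grid = analysis_grid(range_)
    labels = binset.labels()
    set_names = sorted(np.unique(labels).tolist())
    if len(set_names) < 2:
        raise ValueError("perm_test needs >= 2 sets")
    counts = binset.counts()
    for name, c in counts.items():
        if c == 0:
            raise ValueError(f"set {name!r} has no bins")

    B = _bin_matrix(table, curve, binset, densities, grid)
    codes = np.searchsorted(set_names, labels)

    # one shared stream of label permutations, applied to every set
    perms = np.empty((nsim, labels.size), dtype=np.int32)
    for k in range(nsim):
        perms[k] = rng.permutation(labels.size)
    permcodes = codes[perms]  # (nsim, n_bins)

    results: dict[str, EnvelopeResult] = {}
    for ci, name in enumerate(set_names):
        obs = B[codes == ci].sum(axis=0)
        member = (permcodes == ci).astype(B.dtype)
        sims = member @ B  # (nsim, T)
        obs_z, lo, hi, stat, pvalue, n_zero = _envelope_stats(
            obs, sims, scale, include_obs=True)
        results[name] = EnvelopeResult(
            calbp=grid, obs_z=obs_z, lo=lo, hi=hi,
            pos_intervals=_intervals(obs_z > hi, grid, min_run),
            neg_intervals=_intervals(obs_z < lo, grid, min_run),
            global_stat=stat, pvalue=pvalue, nsim=nsim,
            set_label=name, kind="permutation", n_zero_sd=n_zero)
    return PermTestResult(results, nsim, (float(range_[0]), float(range_[1])))
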