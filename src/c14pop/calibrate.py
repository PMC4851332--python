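"""Single-date calibration and its inverse (back-calibration).

Calibration converts a CRA ± lab error into a probability mass function over
calendar years by direct numerical integration on an annual grid:

    p(t)  proportional to  phi(cra; mu(t), sqrt(error^2 + sigma_curve(t)^2))

where phi is the normal density and mu, sigma_curve come from the
calibration curve.  Masses are per calendar year and normalised to sum to 1.

Back-calibration is the engine of Monte-Carlo null tests: pick a calendar
year, look up mu and sigma_curve, and draw a synthetic CRA from
Normal(mu, sqrt(sigma_curve^2 + lab_error^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calcurve import CalibrationCurve, CurveError, interpolate_curve
from .dates_io import UncalDate

__all__ = [
    "CalDensity",
    "CalibrationError",
    "calibrate",
    "uncalibrate",
    "sample_cra",
]

#: default probability floor, as a fraction of the per-date maximum mass
DEFAULT_EPS = 1e-5


class CalibrationError(ValueError):
    pass


@dataclass
class CalDensity:
    """A calibrated probability mass function on an annual cal BP grid.

    ``calbp`` is decreasing with exactly 1-year spacing; ``prob`` sums to 1
    when ``normalised`` is true.
    """

    calbp: np.ndarray
    prob: np.ndarray
    normalised: bool = True

    def __post_init__(self) -> None:
        self.calbp = np.asarray(self.calbp, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.calbp.shape != self.prob.shape:
            raise CalibrationError("grid/prob length mismatch")
        if self.calbp.size > 1 and not np.all(np.diff(self.calbp) == -1):
            raise CalibrationError("grid spacing must be exactly 1 year, decreasing")
        if (self.prob < 0).any():
            raise CalibrationError("negative probability mass")
        if self.normalised and abs(self.prob.sum() - 1.0) > 1e-9:
            raise CalibrationError("normalised density must sum to 1 within 1e-9")

    def mean(self) -> float:
        return float(np.sum(self.calbp * self.prob) / self.prob.sum())

    def std(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum((self.calbp - m) ** 2 * self.prob) / self.prob.sum()))

    def quantile(self, q: float) -> float:
        """Smallest grid year (scanning old -> young) with CDF >= q."""
        c = np.cumsum(self.prob) / self.prob.sum()
        return float(self.calbp[int(np.searchsorted(c, q))])

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.calbp, self.prob]),
                   delimiter=",", header="calbp,prob", comments="")


def _annual(curve: CalibrationCurve) -> CalibrationCurve:
    return curve if curve.is_annual else interpolate_curve(curve)


def _gauss_mass(cra: float, error: float, curve: CalibrationCurve,
                eps: float) -> tuple[int, np.ndarray]:
    """Core integration against an annual curve.

    Returns ``(start_index, prob)`` where ``prob`` is the trimmed, normalised
    mass vector starting at ``curve.calbp[start_index]``.
    """
    w = np.sqrt(error * error + curve.sigma * curve.sigma)
    if not (w > 0).all():
        raise CalibrationError("error and curve sigma cannot both be zero")
    resid = curve.mu - cra
    # only years within 8 combined sigmas can carry mass above any floor
    mask = np.abs(resid) <= 8.0 * w
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise CalibrationError(
            f"CRA {cra} +/- {error} attains no mass on curve "
            f"{curve.name!r} (14C range {curve.mu.min():.0f}-{curve.mu.max():.0f})")
    p = np.zeros(curve.calbp.size)
    r = resid[idx] / w[idx]
    p[idx] = np.exp(-0.5 * r * r) / w[idx]
    pmax = p.max()
    if pmax <= 0:
        raise CalibrationError(f"CRA {cra} +/- {error}: zero mass everywhere")
    p[p < eps * pmax] = 0.0
    nz = np.nonzero(p)[0]
    start, stop = int(nz[0]), int(nz[-1]) + 1
    seg = p[start:stop]
    return start, seg / seg.sum()


def calibrate(cra: float, error: float, curve: CalibrationCurve,
              eps: float = DEFAULT_EPS) -> CalDensity:
    """Calibrate a CRA ± 1-sigma error against an (annualised) curve.

    Years with mass below ``eps`` times the per-date maximum are zeroed, the
    support is trimmed to the smallest contiguous window holding the
    remaining mass, and the result renormalised to sum to 1.
    """
    if error < 0:
        raise CalibrationError("error must be >= 0")
    curve = _annual(curve)
    start, p = _gauss_mass(float(cra), float(error), curve, eps)
    return CalDensity(curve.calbp[start:start + p.size], p)


def uncalibrate(cal_year: float, curve: CalibrationCurve) -> tuple[float, float]:
    """Curve lookup: ``(mu, sigma_curve)`` at a calendar year (interpolated)."""
    mu, sig = curve.lookup(cal_year)
    return float(mu), float(sig)


def sample_cra(cal_year: float, lab_error: float, curve: CalibrationCurve,
               rng: np.random.Generator, *, lab_id: str = "sim",
               site_id: str = "sim", set_label: str = "sim") -> UncalDate:
    """Back-calibrate: draw a synthetic integer CRA for a calendar year.

    CRA ~ Normal(mu(t), sqrt(sigma_curve(t)^2 + lab_error^2)), rounded to
    integer 14C years (the reporting convention for determinations); the
    returned date carries ``lab_error`` as its error.
    """
    if not lab_error > 0:
        raise CalibrationError("lab_error must be > 0")
    mu, sig = uncalibrate(cal_year, curve)
    cra = float(np.round(rng.normal(mu, np.hypot(sig, lab_error))))
    return UncalDate(lab_id=lab_id, site_id=site_id, set_label=set_label,
                     cra=cra, error=float(lab_error), method="AMS",
                     material_class="terrestrial")
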