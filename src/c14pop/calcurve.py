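"""Radiocarbon calibration curves.

A calibration curve maps calendar years BP (before AD 1950) to conventional
radiocarbon ages: ``mu(t)`` is the expected 14C age at calendar year *t* and
``sigma(t)`` its 1-sigma uncertainty, both in 14C years.  Real curves
(e.g. IntCal13) are distributed as plain-text tables at 5-20 year knot
spacing; analysis here happens on an annual grid obtained by linear
interpolation.

Grids are stored in *decreasing* cal BP order (older first), matching the
IntCal file convention: larger cal BP = older.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CalibrationCurve",
    "CurveError",
    "read_calcurve",
    "write_calcurve",
    "interpolate_curve",
    "toy_identity_curve",
    "toy_wiggly_curve",
]


class CurveError(ValueError):
    """Raised for malformed or inconsistent calibration-curve input."""


@dataclass
class CalibrationCurve:
    """A calendar-year -> 14C-age mapping with per-year curve error.

    Parameters
    ----------
    calbp
        Calendar years BP, strictly monotone (normalised to decreasing).
    mu
        14C age BP at each grid year.
    sigma
        1-sigma curve error (14C years) at each grid year; >= 0.
    name
        Free-text identifier, e.g. ``"intcal13"``.
    """

    calbp: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.calbp = np.asarray(self.calbp, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.calbp.shape == self.mu.shape == self.sigma.shape):
            raise CurveError("calbp, mu and sigma must have equal length")
        if self.calbp.size < 2:
            raise CurveError("a curve needs at least two grid points")
        d = np.diff(self.calbp)
        if np.all(d > 0):  # increasing input: normalise to decreasing
            self.calbp = self.calbp[::-1]
            self.mu = self.mu[::-1]
            self.sigma = self.sigma[::-1]
        elif not np.all(d < 0):
            raise CurveError("calbp grid must be strictly monotone (no duplicates)")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.sigma).all()
                and np.isfinite(self.calbp).all()):
            raise CurveError("curve values must be finite")
        if (self.sigma < 0).any():
            raise CurveError("sigma must be non-negative")

    # -- convenience ----------------------------------------------------

    @property
    def span(self) -> tuple[float, float]:
        """(oldest, youngest) cal BP covered by the grid."""
        return float(self.calbp[0]), float(self.calbp[-1])

    @property
    def is_annual(self) -> bool:
        return bool(np.all(np.diff(self.calbp) == -1))

    def lookup(self, cal_year):
        """Interpolated ``(mu, sigma)`` at ``cal_year`` (scalar or array)."""
        cal_year = np.asarray(cal_year, dtype=float)
        old, young = self.span
        if np.any(cal_year > old) or np.any(cal_year < young):
            raise CurveError(
                f"calendar year outside curve span [{young}, {old}] cal BP"
            )
        # np.interp wants increasing x
        x = self.calbp[::-1]
        mu = np.interp(cal_year, x, self.mu[::-1])
        sig = np.interp(cal_year, x, self.sigma[::-1])
        return mu, sig


def read_calcurve(path, dialect: str = "intcal", name: str | None = None) -> CalibrationCurve:
    """Read a calibration curve from a plain-text file.

    ``intcal`` dialect: comment lines start with ``#``; data rows are comma-
    or whitespace-delimited with columns ``cal BP, 14C age, 1-sigma error``
    (extra columns such as Delta-14C are ignored).  ``simple`` is the same
    minus the extra columns; both parse identically.
    """
    if dialect not in ("intcal", "simple"):
        raise CurveError(f"unknown curve dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) < 3:
                raise CurveError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise CurveError(f"{path}: line {lineno}: non-numeric value") from exc
    if len(rows) < 2:
        raise CurveError(f"{path}: fewer than 2 data rows")
    arr = np.array(rows)
    if name is None:
        name = str(path)
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2], name=name)


def write_calcurve(path, curve: CalibrationCurve) -> None:
    """Write a curve in the simple 3-column CSV dialect (bit-exact round-trip)."""
    buf = io.StringIO()
    buf.write(f"# calibration curve: {curve.name}\n# calBP,c14age,error\n")
    for t, m, s in zip(curve.calbp, curve.mu, curve.sigma):
        buf.write(f"{float(t)!r},{float(m)!r},{float(s)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def interpolate_curve(curve: CalibrationCurve, resolution: float = 1) -> CalibrationCurve:
    """Linearly interpolate ``mu`` and ``sigma`` onto a regular annual grid.

    The returned grid spans the curve's range at ``resolution``-year spacing
    (default 1 year), stored in decreasing cal BP.
    """
    if resolution <= 0:
        raise CurveError("resolution must be positive")
    old, young = curve.span
    grid = np.arange(old, young - resolution / 2, -resolution)
    mu, sig = curve.lookup(grid)
    return CalibrationCurve(grid, mu, sig, name=curve.name)


def toy_identity_curve(start: float, end: float, sigma: float = 0.0) -> CalibrationCurve:
    """Annual toy curve with ``mu(t) = t`` and constant curve error.

    With ``sigma=0`` calibration degenerates to a Gaussian in calendar time
    centred on the CRA — the closed-form limit used throughout the tests.
    """
    if not start > end or end < 0:
        raise CurveError("need start > end >= 0")
    grid = np.arange(float(start), float(end) - 0.5, -1.0)
    return CalibrationCurve(grid, grid.copy(), np.full(grid.size, float(sigma)),
                            name="toy-identity")


def toy_wiggly_curve(start: float, end: float, amplitude: float = 40.0,
                     period: float = 500.0, sigma: float = 15.0,
                     knot_step: int = 10) -> CalibrationCurve:
    """Synthetic IntCal-like curve with sinusoidal wiggles (test fixture).

    ``mu(t) = t + amplitude * sin(2*pi*t/period)`` sampled at ``knot_step``
    year knots, mimicking the knotted distribution format of real curves
    (plateaus and inversions appear once ``amplitude*2*pi/period > 1``).
    """
    if not start > end or end < 0:
        raise CurveError("need start > end >= 0")
    grid = np.arange(float(start), float(end) - 0.5, -float(knot_step))
    mu = grid + amplitude * np.sin(2 * np.pi * grid / period)
    return CalibrationCurve(grid, mu, np.full(grid.size, float(sigma)),
                            name="toy-wiggly")
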