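"""Reading, validating and filtering tables of radiocarbon determinations.

One row = one conventional radiocarbon age (CRA) with its 1-sigma lab error,
the site it came from, and a set label (typically a region).  Inclusion
filters mirror common SPD practice for mid-Holocene hunter-gatherer
datasets: AMS determinations only, marine samples excluded (reservoir
effects), charred remains with suspiciously high d13C excluded, and a CRA
window wide enough to buffer the calendar analysis range against edge
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "UncalDate",
    "FilterCriteria",
    "DateTableError",
    "read_dates",
    "write_dates",
    "filter_dates",
    "to_dataframe",
]


class DateTableError(ValueError):
    """Raised for malformed date tables."""


_METHODS = ("AMS", "conventional", "unknown")
_MATERIALS = ("terrestrial", "marine", "unknown")


@dataclass(frozen=True)
class UncalDate:
    """A single uncalibrated 14C determination."""

    lab_id: str
    site_id: str
    set_label: str
    cra: float            # conventional 14C age, 14C yr BP
    error: float          # 1-sigma lab error, 14C yr
    delta13c: float | None = None   # per mil, None if unmeasured
    method: str = "unknown"         # AMS / conventional / unknown
    material_class: str = "unknown"  # terrestrial / marine / unknown

    def __post_init__(self) -> None:
        if not self.site_id or not self.set_label:
            raise DateTableError("site_id and set_label must be non-empty")
        if not self.cra > 0:
            raise DateTableError(f"cra must be > 0 (lab_id={self.lab_id!r})")
        if not self.error > 0:
            raise DateTableError(f"error must be > 0 (lab_id={self.lab_id!r})")
        if self.method not in _METHODS:
            raise DateTableError(f"method must be one of {_METHODS}")
        if self.material_class not in _MATERIALS:
            raise DateTableError(f"material_class must be one of {_MATERIALS}")


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion rules applied jointly by :func:`filter_dates`.

    delta13c_max
        Exclude samples with a *measured* d13C strictly greater than this
        threshold (per mil); unmeasured d13C is never grounds for exclusion.
        The default -24 suits charred terrestrial material; -26 is the
        conservative alternative.
    cra_window
        Inclusive ``(max, min)`` window in 14C yr BP; dates outside are
        dropped.
    """

    ams_only: bool = True
    exclude_marine: bool = True
    delta13c_max: float | None = -24.0
    cra_window: tuple[float, float] | None = (7500.0, 2500.0)

    def __post_init__(self) -> None:
        if self.cra_window is not None and not self.cra_window[0] > self.cra_window[1]:
            raise DateTableError("cra_window must be (max, min) with max > min")


#: default file column -> field binding for read_dates
DEFAULT_COLUMNS = {
    "lab_id": "lab_id",
    "site_id": "site_id",
    "set_label": "set_label",
    "cra": "cra",
    "error": "error",
    "delta13c": "delta13c",
    "method": "method",
    "material_class": "material_class",
}

_MANDATORY = ("lab_id", "site_id", "set_label", "cra", "error")


def read_dates(path, column_map: dict[str, str] | None = None,
               delimiter: str = ",") -> list[UncalDate]:
    """Parse a delimited date table into a validated list of determinations.

    ``column_map`` binds field names to file column names; unmapped optional
    fields default to missing/unknown.  Rows failing validation raise with
    their (1-based, data) row number.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, delimiter=delimiter, dtype=str,
                     skipinitialspace=True)
    for f in _MANDATORY:
        if cmap[f] not in df.columns:
            raise DateTableError(f"{path}: mandatory column {cmap[f]!r} (field {f}) missing")
    out: list[UncalDate] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))

        def get(fieldname):
            col = cmap[fieldname]
            v = rec.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            v = str(v).strip()
            return v or None

        try:
            d13 = get("delta13c")
            out.append(UncalDate(
                lab_id=get("lab_id") or "",
                site_id=get("site_id") or "",
                set_label=get("set_label") or "",
                cra=float(get("cra")),
                error=float(get("error")),
                delta13c=float(d13) if d13 is not None else None,
                method=get("method") or "unknown",
                material_class=get("material_class") or "unknown",
            ))
        except (TypeError, ValueError, DateTableError) as exc:
            raise DateTableError(f"{path}: row {i}: {exc}") from exc
    return out


def to_dataframe(table: list[UncalDate]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in table])


def write_dates(path, table: list[UncalDate], delimiter: str = ",") -> None:
    to_dataframe(table).to_csv(path, index=False, sep=delimiter)


def filter_dates(table: list[UncalDate], criteria: FilterCriteria | None = None,
                 ) -> tuple[list[UncalDate], dict]:
    """Apply all active inclusion rules; return ``(kept, report)``.

    The report maps each set label to input / retained counts and the number
    dropped by each rule (a row failing several rules is counted once per
    rule it fails).  Row order is preserved; filtering is idempotent.
    """
    if criteria is None:
        criteria = FilterCriteria()
    rules = ("non_ams", "marine", "delta13c", "cra_window")
    report: dict[str, dict] = {}

    def rec(label):
        return report.setdefault(
            label, {"input": 0, "retained": 0,
                    "dropped_by_rule": {r: 0 for r in rules}})

    kept: list[UncalDate] = []
    for d in table:
        r = rec(d.set_label)
        r["input"] += 1
        ok = True
        if criteria.ams_only and d.method != "AMS":
            r["dropped_by_rule"]["non_ams"] += 1
            ok = False
        if criteria.exclude_marine and d.material_class == "marine":
            r["dropped_by_rule"]["marine"] += 1
            ok = False
        if (criteria.delta13c_max is not None and d.delta13c is not None
                and d.delta13c > criteria.delta13c_max):
            r["dropped_by_rule"]["delta13c"] += 1
            ok = False
        if criteria.cra_window is not None:
            cmax, cmin = criteria.cra_window
            if not (cmin <= d.cra <= cmax):
                r["dropped_by_rule"]["cra_window"] += 1
                ok = False
        if ok:
            kept.append(d)
            r["retained"] += 1
    return kept, report
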