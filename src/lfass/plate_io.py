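"""Plate-reader kinetic exports and plate-layout metadata.

A survival assay run is a set of per-well fluorescence time series recorded
on a shared time grid (typically every 2 min over 8 h for acute stress, or
every 5 min over 4 days for infection), plus a layout table mapping wells
to experimental conditions. This module reads the two supported kinetic
export schemas (wide: one row per well with a header row of times; long:
``well,time_min,fluorescence`` records), reads/validates layout CSVs, and
writes the per-well results table.

All times are minutes internally. Readers accept seconds or hours only via
an explicit ``time_unit`` flag, never by guessing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "TimeGrid",
    "RawTrace",
    "WellCondition",
    "PlateLayout",
    "PlateRun",
    "normalize_well_id",
    "well_sort_key",
    "read_kinetic_export",
    "read_layout",
    "write_kinetic_export",
    "write_results_table",
    "RESULT_COLUMNS",
]

STRESSORS = ("oxidative", "thermal", "infection", "other")

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")

#: fixed column order of the results table (byte-stable output contract)
RESULT_COLUMNS = [
    "well", "group", "strain", "age_days", "stressor", "dose", "n_worms",
    "t_half_min", "t_peak_min", "peak_prominence", "fit_rmse", "status",
    "flags",
]

_UNIT_TO_MIN = {"min": 1.0, "minute": 1.0, "minutes": 1.0,
                "s": 1.0 / 60.0, "sec": 1.0 / 60.0, "seconds": 1.0 / 60.0,
                "h": 60.0, "hr": 60.0, "hours": 60.0}


def normalize_well_id(well: str) -> str:
    """Canonicalize a well id: 'a01' -> 'A1'. Rows A-P, columns 1-24."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise FormatError(f"invalid well id {well!r} (expected e.g. 'A1' or 'A01')")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 24:
        raise FormatError(f"well id {well!r}: column {col} exceeds 24 (384-well limit)")
    return f"{row}{col}"


def well_sort_key(well: str):
    """Row-major sort key: A1, A2, ..., A24, B1, ..."""
    m = _WELL_RE.match(well)
    return (m.group(1).upper(), int(m.group(2)))


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times in minutes plus the nominal cadence.

    A gap larger than three nominal cadences indicates a reader dropout and
    is rejected.
    """

    times: np.ndarray
    nominal_cadence: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or len(t) < 10:
            raise FormatError(f"time grid must hold at least 10 points, got {len(t)}")
        if not np.all(np.isfinite(t)):
            raise FormatError("time grid contains non-finite values")
        if t[0] < 0:
            raise FormatError(f"time grid starts before 0 (t0={t[0]} min)")
        d = np.diff(t)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0)) + 1
            raise FormatError(
                f"non-monotone time header at column {i} (t={t[i]:g} after {t[i - 1]:g} min)")
        if self.nominal_cadence <= 0:
            raise FormatError("nominal cadence must be positive")
        if d.max() > 3.0 * self.nominal_cadence:
            raise FormatError(
                f"time gap {d.max():g} min exceeds 3x nominal cadence "
                f"({self.nominal_cadence:g} min); reader error")

    def __len__(self):
        return len(self.times)

    def __eq__(self, other):
        return (isinstance(other, TimeGrid)
                and len(self.times) == len(other.times)
                and np.allclose(self.times, other.times)
                and math.isclose(self.nominal_cadence, other.nominal_cadence))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def _nan_run_lengths(x: np.ndarray) -> int:
    """Length of the longest run of consecutive NaNs."""
    isnan = np.isnan(x)
    if not isnan.any():
        return 0
    best = run = 0
    for v in isnan:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


@dataclass
class RawTrace:
    """One well's fluorescence time series in arbitrary units.

    Up to two consecutive missing reads are tolerated (linearly interpolated
    during preprocessing); longer NaN runs invalidate the trace, which is
    reported as an UNFIT well downstream rather than raising.
    """

    well_id: str
    grid: TimeGrid
    fluorescence: np.ndarray
    meta: dict = field(default_factory=dict)
    valid: bool = True
    invalid_reason: str | None = None

    def __post_init__(self):
        self.well_id = normalize_well_id(self.well_id)
        f = np.asarray(self.fluorescence, dtype=float)
        self.fluorescence = f
        if len(f) != len(self.grid):
            raise FormatError(
                f"well {self.well_id}: {len(f)} readings for {len(self.grid)} timepoints")
        finite = f[np.isfinite(f)]
        if np.any(np.isinf(f)) or (finite.size and finite.min() < 0):
            self.valid = False
            self.invalid_reason = "negative or infinite fluorescence reading"
        run = _nan_run_lengths(f)
        if run > 2:
            self.valid = False
            self.invalid_reason = f"missing-data run of {run} consecutive reads (max 2)"


@dataclass
class WellCondition:
    """Experimental condition of one well. ``age_days`` counts from late L4
    (day 0); ``dose`` is free text such as '7% t-BHP'."""

    strain: str = "unknown"
    age_days: float = 1.0
    stressor: str = "other"
    dose: str = ""
    n_worms: int = 16
    group: str = ""

    def __post_init__(self):
        s = str(self.stressor).strip().lower()
        if s not in STRESSORS:
            raise FormatError(
                f"unknown stressor {self.stressor!r}; expected one of {STRESSORS}")
        self.stressor = s
        self.n_worms = int(self.n_worms)
        if self.n_worms < 1:
            raise FormatError(f"n_worms must be >= 1, got {self.n_worms}")
        self.age_days = float(self.age_days)
        if self.age_days < 0:
            raise FormatError(f"age_days must be >= 0, got {self.age_days}")
        if not self.group:
            self.group = self.strain

    @property
    def dose_value(self) -> float | None:
        """Leading numeric part of the dose text, if any."""
        m = re.match(r"\s*([-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)", str(self.dose))
        return float(m.group(1)) if m else None


@dataclass
class PlateLayout:
    """Well -> condition mapping with collected validation warnings."""

    wells: dict[str, WellCondition]
    warnings: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.wells)

    def get(self, well: str) -> WellCondition | None:
        return self.wells.get(well)

    def check_against(self, run: "PlateRun") -> list[str]:
        """Report layout wells absent from the export (non-fatal) and
        export wells missing a layout entry."""
        run_wells = {tr.well_id for tr in run.traces}
        msgs = [f"layout well {w} absent from kinetic export"
                for w in sorted(self.wells, key=well_sort_key) if w not in run_wells]
        msgs += [f"export well {w} has no layout entry"
                 for w in sorted(run_wells - set(self.wells), key=well_sort_key)]
        self.warnings.extend(msgs)
        return msgs


@dataclass
class PlateRun:
    """A full plate: traces on one shared grid plus optional layout."""

    traces: list[RawTrace]
    layout: PlateLayout | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.traces:
            g0 = self.traces[0].grid
            for tr in self.traces[1:]:
                if tr.grid != g0:
                    raise FormatError(
                        f"well {tr.well_id} is on a different time grid; all traces "
                        "of a run must share one grid")

    @property
    def grid(self) -> TimeGrid:
        return self.traces[0].grid

    def wells(self) -> list[str]:
        return [tr.well_id for tr in self.traces]

    def with_layout(self, layout: PlateLayout) -> "PlateRun":
        layout.check_against(self)
        return PlateRun(self.traces, layout, dict(self.meta))


# ---------------------------------------------------------------------------
# reading


def _read_rows(path: str | Path) -> list[list[str]]:
    """Return the file as rows of string fields. CSV by default; XLSX/XLS
    sheets are flattened through the same logic."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=None, dtype=object)
        return [["" if (v is None or (isinstance(v, float) and math.isnan(v))) else str(v)
                 for v in row] for row in df.itertuples(index=False)]
    rows = []
    with open(path, newline="") as fh:
        for line in fh:
            rows.append([c.strip() for c in line.rstrip("\r\n").split(",")])
    return rows


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return bool(s == "")


def _to_float(s: str) -> float:
    return math.nan if s == "" else float(s)


def _find_wide_header(rows: list[list[str]]) -> int:
    """Index of the header row: the first row whose trailing fields are all
    numeric times (>= 10 of them). Instrument preamble lines before it are
    skipped."""
    for i, r in enumerate(rows):
        body = [c for c in r[1:] if c != ""]
        if len(body) >= 10 and all(_is_number(c) and c != "" for c in body):
            return i
    raise FormatError("no parseable header row of timepoints found (wide format)")


def read_kinetic_export(path, format="wide", cadence_hint=None, time_unit="min"):
    """Read a kinetic export into a :class:`PlateRun` (without layout).

    Parameters
    ----------
    format : {'wide', 'long'}
        ``wide``: rows are wells, the header row holds times. ``long``:
        columns ``well, time_min, fluorescence`` in any row order.
    cadence_hint : float, optional
        Nominal cadence in minutes; defaults to the median time step.
    time_unit : {'min', 's', 'hr'}
        Unit of the time values in the file; converted to minutes.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"kinetic export not found: {path}")
    try:
        scale = _UNIT_TO_MIN[str(time_unit).lower()]
    except KeyError:
        raise FormatError(f"unknown time unit {time_unit!r}") from None
    rows = _read_rows(path)
    if format == "wide":
        run = _parse_wide(rows, scale, cadence_hint)
    elif format == "long":
        run = _parse_long(rows, scale, cadence_hint)
    else:
        raise FormatError(f"unknown export format {format!r}")
    run.meta.update({"source": str(path), "format": format})
    return run


def _make_grid(times: np.ndarray, cadence_hint) -> TimeGrid:
    d = np.diff(times)
    if np.any(d <= 0):
        i = int(np.argmax(d <= 0)) + 1
        raise FormatError(
            f"non-monotone time header at column {i + 1} (t={times[i]:g} "
            f"after {times[i - 1]:g} min)")
    cadence = float(cadence_hint) if cadence_hint else float(np.median(d))
    return TimeGrid(times, cadence)


def _parse_wide(rows, scale, cadence_hint) -> PlateRun:
    h = _find_wide_header(rows)
    header = rows[h]
    times = np.array([_to_float(c) for c in header[1:] if c != ""], dtype=float) * scale
    grid = _make_grid(times, cadence_hint)
    traces, seen = [], set()
    for r in rows[h + 1:]:
        if not r or all(c == "" for c in r):
            continue
        well = normalize_well_id(r[0])
        if well in seen:
            raise FormatError(f"duplicate well row {well}")
        seen.add(well)
        vals = [_to_float(c) for c in r[1:1 + len(times)]]
        if len(vals) != len(times):
            raise FormatError(
                f"well {well}: {len(vals)} readings for {len(times)} timepoints")
        traces.append(RawTrace(well, grid, np.array(vals)))
    traces.sort(key=lambda tr: well_sort_key(tr.well_id))
    return PlateRun(traces, meta={"skipped_preamble_lines": h})


def _parse_long(rows, scale, cadence_hint) -> PlateRun:
    header_idx = None
    for i, r in enumerate(rows):
        low = [c.lower() for c in r]
        if "well" in low and "fluorescence" in low and any(
                c in low for c in ("time_min", "time")):
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(
            "no header with columns {well, time_min, fluorescence} found (long format)")
    low = [c.lower() for c in rows[header_idx]]
    iw, iv = low.index("well"), low.index("fluorescence")
    it = low.index("time_min") if "time_min" in low else low.index("time")
    per_well: dict[str, dict[float, float]] = {}
    for r in rows[header_idx + 1:]:
        if not r or all(c == "" for c in r):
            continue
        well = normalize_well_id(r[iw])
        t = float(r[it]) * scale
        v = _to_float(r[iv])
        d = per_well.setdefault(well, {})
        if t in d:
            raise FormatError(f"duplicate record for well {well} at t={t:g} min")
        d[t] = v
    if not per_well:
        raise FormatError("long export holds no data rows")
    time_sets = {frozenset(d) for d in per_well.values()}
    if len(time_sets) != 1:
        raise FormatError("wells do not share a common set of timepoints")
    times = np.array(sorted(next(iter(time_sets))), dtype=float)
    grid = _make_grid(times, cadence_hint)
    traces = [RawTrace(w, grid, np.array([per_well[w][t] for t in times]))
              for w in sorted(per_well, key=well_sort_key)]
    return PlateRun(traces, meta={"skipped_preamble_lines": header_idx})


def read_layout(path) -> PlateLayout:
    """Read a layout CSV with columns
    ``well, strain, age_days, stressor, dose, n_worms, group``.

    Missing optional columns are filled with defaults (n_worms 16, stressor
    'other', age_days 1, group = strain).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"layout file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    if "well" not in cols:
        raise FormatError(f"layout {path} lacks a 'well' column")
    defaults = WellCondition()
    wells: dict[str, WellCondition] = {}
    warnings: list[str] = []
    for c in ("strain", "age_days", "stressor", "dose", "n_worms", "group"):
        if c not in cols:
            warnings.append(f"layout column '{c}' missing; using default")
    for _, row in df.iterrows():
        well = normalize_well_id(row[cols["well"]])
        if well in wells:
            raise FormatError(f"duplicate well {well} in layout")

        def val(c, default):
            if c not in cols:
                return default
            v = str(row[cols[c]]).strip()
            return v if v != "" else default

        wells[well] = WellCondition(
            strain=val("strain", defaults.strain),
            age_days=float(val("age_days", defaults.age_days)),
            stressor=val("stressor", defaults.stressor),
            dose=val("dose", defaults.dose),
            n_worms=int(float(val("n_worms", defaults.n_worms))),
            group=val("group", ""),
        )
    return PlateLayout(wells, warnings)


# ---------------------------------------------------------------------------
# writing


def _fmt(x, spec="%.6g") -> str:
    if x is None:
        return ""
    if isinstance(x, float) and math.isnan(x):
        return ""
    return spec % x


def write_kinetic_export(run: PlateRun, path) -> None:
    """Write a run as a wide CSV (round-trips through
    :func:`read_kinetic_export` to 1e-6 relative tolerance)."""
    lines = ["well," + ",".join("%.6g" % t for t in run.grid.times)]
    for tr in sorted(run.traces, key=lambda tr: well_sort_key(tr.well_id)):
        lines.append(tr.well_id + "," +
                     ",".join(_fmt(v, "%.10g") for v in tr.fluorescence))
    Path(path).write_text("\n".join(lines) + "\n")


def write_results_table(fits: Iterable, layout: PlateLayout | None, path) -> None:
    """Write one row per well with the estimated median time of death and
    fit diagnostics. Column order and float formatting are fixed so that
    identical inputs give byte-identical files."""
    lines = [",".join(RESULT_COLUMNS)]
    default = WellCondition()
    for fit in sorted(fits, key=lambda f: well_sort_key(f.well_id)):
        cond = (layout.get(fit.well_id) if layout else None) or default
        row = [
            fit.well_id,
            cond.group,
            cond.strain,
            _fmt(cond.age_days, "%.4g"),
            cond.stressor,
            str(cond.dose),
            str(cond.n_worms),
            _fmt(fit.t_half, "%.4f"),
            _fmt(fit.t_peak, "%.4f"),
            _fmt(fit.peak_prominence, "%.6g"),
            _fmt(fit.rmse, "%.6g"),
            fit.status,
            "|".join(sorted(fit.flags)),
        ]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
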