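"""Condition-level survival summaries and resistance-lifespan regression.

Per-well estimates are aggregated into group medians with percentile
bootstrap confidence intervals; per-age group medians build a strain's
resistance profile (min/mean/max of the per-age medians over the first
week of adulthood, days 1-7 inclusive), which is regressed against mean
lifespan across strains by ordinary least squares. Dose series are
checked for monotonicity with Kendall's tau (doses are few and ties
likely, so a rank statistic built from pair counts fits better than a
correlation coefficient).

"Resistance" of a condition is its group median time of death in minutes:
larger means more resistant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, FormatError
from .plate_io import PlateLayout
from .dfcurve import FitResult, STATUS_OK

__all__ = [
    "ConditionSummary", "ResistanceProfile", "RegressionResult",
    "DoseOrderingReport", "summarize_conditions", "build_profile",
    "regress_resistance_lifespan", "check_dose_ordering",
    "fits_to_frame", "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = ["group", "n_wells_ok", "median_t_half_min",
                   "ci_lo_min", "ci_hi_min", "cv"]

FIRST_WEEK = (1.0, 7.0)   # age_days window, inclusive


@dataclass(frozen=True)
class ConditionSummary:
    """Group-level median time of death with bootstrap CI and dispersion.
    ``n_wells_ok == 0`` marks a group with no usable wells (all fields
    NaN)."""

    group: str
    n_wells_ok: int
    median_t_half_min: float
    ci_lo_min: float
    ci_hi_min: float
    cv: float


@dataclass(frozen=True)
class ResistanceProfile:
    """Per-age resistance of one strain plus first-week min/mean/max."""

    strain: str
    by_age: dict          # age_days -> median t_half (min)
    res_min: float
    res_mean: float
    res_max: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int


@dataclass(frozen=True)
class DoseOrderingReport:
    monotone_nonincreasing: bool
    tau: float | None
    p: float | None
    n_doses: int


def fits_to_frame(fits: Iterable[FitResult], layout: PlateLayout | None = None
                  ) -> pd.DataFrame:
    """Flatten fit results (plus layout condition columns) to a DataFrame
    with columns well, group, strain, age_days, dose, t_half_min, status."""
    rows = []
    for f in fits:
        cond = layout.get(f.well_id) if layout else None
        rows.append({
            "well": f.well_id,
            "group": cond.group if cond else "",
            "strain": cond.strain if cond else "",
            "age_days": cond.age_days if cond else np.nan,
            "dose": cond.dose if cond else "",
            "t_half_min": np.nan if f.t_half is None else f.t_half,
            "status": f.status,
        })
    return pd.DataFrame(rows, columns=["well", "group", "strain", "age_days",
                                       "dose", "t_half_min", "status"])


def _coerce_frame(fits, layout) -> pd.DataFrame:
    if isinstance(fits, pd.DataFrame):
        need = {"well", "group", "t_half_min", "status"}
        missing = need - set(fits.columns)
        if missing:
            raise FormatError(f"results table lacks columns {sorted(missing)}")
        return fits
    return fits_to_frame(fits, layout)


def summarize_conditions(fits, layout: PlateLayout | None = None,
                         n_boot: int = 2000, seed: int = 0
                         ) -> list[ConditionSummary]:
    """Group medians of t_half over OK wells with percentile bootstrap CIs.

    ``fits`` may be FitResult objects (with a layout supplying groups) or a
    results DataFrame. A group without OK wells is reported with
    ``n_wells_ok = 0`` rather than dropped.
    """
    df = _coerce_frame(fits, layout)
    rng = np.random.default_rng(seed)
    out = []
    for group, sub in df.groupby("group", sort=True):
        vals = sub.loc[sub["status"] == STATUS_OK, "t_half_min"].dropna().to_numpy()
        if vals.size == 0:
            out.append(ConditionSummary(str(group), 0, np.nan, np.nan, np.nan, np.nan))
            continue
        med = float(np.median(vals))
        if vals.size == 1:
            lo = hi = med
        else:
            boot = np.median(
                vals[rng.integers(0, vals.size, size=(n_boot, vals.size))], axis=1)
            lo, hi = (float(x) for x in np.percentile(boot, [2.5, 97.5]))
        cv = float(np.std(vals, ddof=1) / np.mean(vals)) if vals.size > 1 else 0.0
        out.append(ConditionSummary(str(group), int(vals.size), med, lo, hi, cv))
    return out


def summaries_to_frame(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": s.group, "n_wells_ok": s.n_wells_ok,
          "median_t_half_min": s.median_t_half_min, "ci_lo_min": s.ci_lo_min,
          "ci_hi_min": s.ci_hi_min, "cv": s.cv} for s in summaries],
        columns=SUMMARY_COLUMNS)


def build_profile(medians_by_age: Mapping[float, float], strain: str
                  ) -> ResistanceProfile:
    """First-week resistance statistics of one strain.

    ``medians_by_age`` maps age (days of adulthood) to the group median
    t_half in minutes. Only ages within days 1-7 inclusive enter the
    min/mean/max; missing ages are excluded, never imputed.
    """
    by_age = {float(a): float(m) for a, m in medians_by_age.items()
              if np.isfinite(m)}
    week = [m for a, m in sorted(by_age.items())
            if FIRST_WEEK[0] <= a <= FIRST_WEEK[1]]
    if not week:
        raise ConfigError(
            f"strain {strain!r}: no ages within days {FIRST_WEEK[0]:g}-"
            f"{FIRST_WEEK[1]:g} of adulthood")
    return ResistanceProfile(strain, by_age, float(min(week)),
                             float(np.mean(week)), float(max(week)))


def regress_resistance_lifespan(profiles: Iterable[ResistanceProfile],
                                lifespans: Mapping[str, float]
                                ) -> dict[str, RegressionResult]:
    """OLS of first-week resistance (min/mean/max) against mean lifespan.

    ``lifespans`` maps strain to mean lifespan in days. Returns one
    regression per resistance statistic, with Pearson r and its two-sided
    p-value. Requires at least 3 strains present in both tables and a
    non-degenerate predictor.
    """
    profs = [p for p in profiles if p.strain in lifespans]
    if len(profs) < 3:
        raise ConfigError(
            f"regression needs >= 3 strains with both resistance and lifespan "
            f"data, got {len(profs)}")
    x = np.array([float(lifespans[p.strain]) for p in profs])
    if np.std(x) == 0:
        raise ConfigError("lifespan predictor has zero variance")
    out = {}
    for stat_name, attr in (("min", "res_min"), ("mean", "res_mean"),
                            ("max", "res_max")):
        y = np.array([getattr(p, attr) for p in profs])
        res = stats.linregress(x, y)
        out[stat_name] = RegressionResult(
            slope=float(res.slope), intercept=float(res.intercept),
            r=float(res.rvalue), r2=float(res.rvalue ** 2),
            p=float(res.pvalue), n=len(profs))
    return out


def check_dose_ordering(summaries: Iterable[ConditionSummary],
                        doses: Mapping[str, float]) -> DoseOrderingReport:
    """Is the group median time of death monotone non-increasing with dose?

    ``doses`` maps group label to a numeric dose. Groups without usable
    wells are skipped. With a single dose the series is trivially monotone
    and tau is undefined (None).
    """
    pairs = []
    for s in summaries:
        if s.group not in doses:
            continue
        try:
            d = float(doses[s.group])
        except (TypeError, ValueError):
            raise ConfigError(f"non-numeric dose {doses[s.group]!r} for group "
                              f"{s.group!r}") from None
        if s.n_wells_ok > 0:
            pairs.append((d, s.median_t_half_min))
    if not pairs:
        raise ConfigError("no usable dose groups")
    pairs.sort()
    d = np.array([p[0] for p in pairs])
    m = np.array([p[1] for p in pairs])
    if len(pairs) < 2:
        return DoseOrderingReport(True, None, None, 1)
    tau, p = stats.kendalltau(d, m)
    monotone = bool(np.all(np.diff(m) <= 0))
    return DoseOrderingReport(monotone, float(tau), float(p), len(pairs))
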