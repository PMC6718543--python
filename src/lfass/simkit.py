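"""Stochastic simulator of death-fluorescence survival assays.

Generates synthetic plates with known ground truth for validating the
analysis pipeline. The generative model follows the statistical structure
the analysis assumes:

* per-well death times — normally distributed around the condition's
  median (truncated at zero), the regime that holds once the median time
  of death exceeds ~30 min; a conditioned Poisson-process mode with a
  piecewise-constant event rate is available for skew stress-tests;
* per-worm fluorescence burst at death — an exponential-rise (tau ~ 2 min)
  times exponential-decay (tau ~ 120 min, the "decays over a few hours"
  timescale) kernel, with lognormal worm-to-worm amplitude variation;
* measurement noise — baseline autofluorescence with slow linear drift,
  multiplicative read noise, and additive instrument noise.

One seed drives a whole plate; each well uses an independent substream
derived from (seed, well index), so adding wells never perturbs the data
of existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .plate_io import (PlateLayout, PlateRun, RawTrace, TimeGrid,
                       WellCondition)

__all__ = [
    "DeathModel", "BurstKernel", "NoiseModel", "Scenario",
    "sample_death_times", "render_trace", "simulate_plate",
    "stress384", "infection96", "dose_series", "scenario_by_name",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["well", "group", "n_worms", "true_median_min", "seed",
                 "median_param_min", "sd_param_min"]


@dataclass(frozen=True)
class DeathModel:
    """Distribution of individual death times within one well.

    ``normal`` draws from Normal(median_min, sd_min) truncated at zero.
    ``poisson_process`` draws event times from a piecewise-constant rate
    profile ``[(t0, t1, rate), ...]`` conditioned on the worm count (given
    the count, events fall independently with density proportional to the
    rate).
    """

    mode: str = "normal"
    median_min: float = 90.0
    sd_min: float = 18.0
    rate_profile: tuple = ()

    def __post_init__(self):
        if self.mode not in ("normal", "poisson_process"):
            raise ConfigError(f"unknown death model mode {self.mode!r}")
        if self.median_min <= 0:
            raise ConfigError("median_min must be > 0")
        if self.sd_min < 0:
            raise ConfigError("sd_min must be >= 0")
        if self.mode == "poisson_process" and not self.rate_profile:
            raise ConfigError("poisson_process mode requires a rate_profile")


@dataclass(frozen=True)
class BurstKernel:
    """Single-worm death-fluorescence time course.

    ``kernel(t) = A * (1 - exp(-(t - t_death)/rise_tau)) *
    exp(-(t - t_death)/decay_tau)`` for t >= t_death, zero before.
    ``rise_tau = 0`` gives an instantaneous step; ``decay_tau = inf`` a
    non-decaying step. ``amplitude_cv`` is the worm-to-worm coefficient of
    variation of the burst amplitude (lognormal).
    """

    amplitude: float = 100.0
    rise_tau: float = 2.0
    decay_tau: float = 120.0
    amplitude_cv: float = 0.2

    def __post_init__(self):
        if self.amplitude <= 0 or self.rise_tau < 0 or self.decay_tau <= 0:
            raise ConfigError("kernel requires amplitude > 0, rise_tau >= 0, decay_tau > 0")
        if self.amplitude_cv < 0:
            raise ConfigError("amplitude_cv must be >= 0")

    def evaluate(self, t: np.ndarray, t_death: float) -> np.ndarray:
        dt = np.asarray(t, dtype=float) - t_death
        on = dt >= 0
        dtc = np.clip(dt, 0.0, None)
        rise = 1.0 if self.rise_tau == 0 else -np.expm1(-dtc / self.rise_tau)
        decay = 1.0 if np.isinf(self.decay_tau) else np.exp(-dtc / self.decay_tau)
        return np.where(on, self.amplitude * rise * decay, 0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: constant baseline, linear drift (units/hour),
    per-read multiplicative noise (CV) and additive Gaussian noise."""

    baseline_level: float = 100.0
    baseline_drift: float = 0.5
    additive_sd: float = 1.0
    multiplicative_cv: float = 0.10

    def __post_init__(self):
        for name in ("baseline_level", "baseline_drift", "additive_sd",
                     "multiplicative_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_death_times(n: int, model: DeathModel, seed) -> np.ndarray:
    """Draw ``n`` individual death times (minutes, sorted ascending)."""
    if n < 1:
        raise ConfigError("need at least one worm")
    rng = _as_rng(seed)
    if model.mode == "normal":
        if model.sd_min == 0:
            td = np.full(n, model.median_min)
        else:
            # truncated at zero by redraw (conditional distribution)
            td = rng.normal(model.median_min, model.sd_min, size=n)
            while (bad := td <= 0).any():
                td[bad] = rng.normal(model.median_min, model.sd_min, size=int(bad.sum()))
    else:
        segs = np.array([(float(a), float(b), float(r))
                         for a, b, r in model.rate_profile])
        if np.any(segs[:, 1] <= segs[:, 0]) or np.any(segs[:, 2] < 0):
            raise ConfigError("rate_profile segments must have t1 > t0 and rate >= 0")
        w = segs[:, 2] * (segs[:, 1] - segs[:, 0])
        if w.sum() <= 0:
            raise ConfigError("rate_profile has zero total mass")
        choice = rng.choice(len(segs), size=n, p=w / w.sum())
        td = rng.uniform(segs[choice, 0], segs[choice, 1])
    return np.sort(td)


def render_trace(death_times, kernel: BurstKernel, noise: NoiseModel,
                 grid: TimeGrid, seed, well_id: str = "A1",
                 amplitudes=None) -> RawTrace:
    """Render one well: baseline + drift + summed burst kernels, then
    multiplicative and additive noise, clipped at zero. Deterministic for
    a given seed."""
    rng = _as_rng(seed)
    td = np.asarray(death_times, dtype=float)
    t = grid.times
    if td.size and (td.min() < t[0] - 1e-9):
        raise ConfigError("grid does not span the death times")
    if amplitudes is None:
        if kernel.amplitude_cv > 0:
            s = np.sqrt(np.log1p(kernel.amplitude_cv ** 2))
            amplitudes = kernel.amplitude * rng.lognormal(-s * s / 2, s, size=td.size)
        else:
            amplitudes = np.full(td.size, kernel.amplitude)
    amplitudes = np.asarray(amplitudes, dtype=float)
    dt = t[None, :] - td[:, None]
    on = dt >= 0
    dtc = np.clip(dt, 0.0, None)
    rise = 1.0 if kernel.rise_tau == 0 else -np.expm1(-dtc / kernel.rise_tau)
    decay = 1.0 if np.isinf(kernel.decay_tau) else np.exp(-dtc / kernel.decay_tau)
    f = amplitudes @ np.where(on, rise * decay, 0.0)
    f = f + noise.baseline_level + noise.baseline_drift * t / 60.0
    if noise.multiplicative_cv > 0:
        f = f * (1.0 + noise.multiplicative_cv * rng.standard_normal(len(t)))
    if noise.additive_sd > 0:
        f = f + noise.additive_sd * rng.standard_normal(len(t))
    f = np.clip(f, 0.0, None)
    return RawTrace(well_id, grid, f,
                    meta={"excitation_nm": 360, "emission_nm": 435,
                          "temperature_C": 25.0})


@dataclass(frozen=True)
class GroupSpec:
    """One condition group within a scenario: a fixed median (and sd) for
    ``n_wells`` replicate wells, with an optional dose label."""

    label: str
    n_wells: int
    median_min: float
    sd_min: float | None = None       # default: scenario.sd_frac * median
    dose: str = ""


@dataclass(frozen=True)
class Scenario:
    """Full description of a simulated plate.

    Either ``median_range`` (per-well medians drawn uniformly) or
    ``groups`` (fixed per-group medians) defines the death-time medians;
    ``sd_frac`` sets the within-well dispersion as a fraction of the
    median unless a group overrides it.
    """

    name: str
    n_rows: int
    n_cols: int
    n_worms: int
    cadence_min: float
    duration_min: float
    median_range: tuple[float, float] | None = None
    groups: tuple[GroupSpec, ...] = ()
    sd_frac: float = 0.2
    kernel: BurstKernel = field(default_factory=BurstKernel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    stressor: str = "other"
    strain: str = "N2-sim"
    age_days: float = 1.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows > 16 or self.n_cols > 24:
            raise ConfigError("plate shape must fit a 384-well grid (<= 16 x 24)")
        if self.n_worms < 1:
            raise ConfigError("n_worms must be >= 1")
        if self.cadence_min <= 0 or self.duration_min <= 10 * self.cadence_min:
            raise ConfigError("need cadence > 0 and duration > 10 cadences")
        if (self.median_range is None) == (not self.groups):
            raise ConfigError("specify exactly one of median_range or groups")
        if self.median_range is not None:
            lo, hi = self.median_range
            if not 0 < lo <= hi:
                raise ConfigError("median_range must satisfy 0 < lo <= hi")
        if not 0 <= self.sd_frac < 1:
            raise ConfigError("sd_frac must be in [0, 1)")
        n = (sum(g.n_wells for g in self.groups) if self.groups
             else self.n_rows * self.n_cols)
        if n > self.n_rows * self.n_cols:
            raise ConfigError("groups request more wells than the plate holds")

    @property
    def n_wells(self) -> int:
        return (sum(g.n_wells for g in self.groups) if self.groups
                else self.n_rows * self.n_cols)

    def grid(self) -> TimeGrid:
        times = np.arange(0.0, self.duration_min + self.cadence_min / 2,
                          self.cadence_min)
        return TimeGrid(times, self.cadence_min)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stress384() -> Scenario:
    """Default acute-stress plate: 384 wells of 16 worms read every 2 min
    for 8 h, true medians uniform in 30-240 min with sd = 20% of the
    median."""
    return Scenario(name="stress384", n_rows=16, n_cols=24, n_worms=16,
                    cadence_min=2.0, duration_min=480.0,
                    median_range=(30.0, 240.0), sd_frac=0.2,
                    stressor="oxidative")


def infection96() -> Scenario:
    """Infection plate: 96 wells of 100 worms read every 5 min for 4 days.

    Long assays need many worms per well so consecutive deaths are close
    enough for single-worm bursts to sum into a clear population peak
    before they decay; dispersion is accordingly kept well below the
    burst decay time (sd = 5% of the median, medians 12-36 h).
    """
    return Scenario(name="infection96", n_rows=8, n_cols=12, n_worms=100,
                    cadence_min=5.0, duration_min=5760.0,
                    median_range=(720.0, 2160.0), sd_frac=0.05,
                    stressor="infection",
                    noise=NoiseModel(baseline_level=100.0, baseline_drift=0.5,
                                     additive_sd=1.0, multiplicative_cv=0.10))


def dose_series(medians=(240.0, 120.0, 60.0, 30.0), doses=(1.0, 2.0, 4.0, 8.0),
                wells_per_dose: int = 6, **kw) -> Scenario:
    """Dose-response plate: higher dose, shorter survival."""
    if len(medians) != len(doses):
        raise ConfigError("medians and doses must have equal length")
    groups = tuple(GroupSpec(label=f"dose{d:g}", n_wells=wells_per_dose,
                             median_min=m, dose=f"{d:g} au")
                   for m, d in zip(medians, doses))
    defaults = dict(name="dose_series", n_rows=16, n_cols=24, n_worms=16,
                    cadence_min=2.0, duration_min=480.0, stressor="oxidative")
    defaults.update(kw)
    return Scenario(groups=groups, **defaults)


_BUILTINS = {"stress384": stress384, "infection96": infection96,
             "dose_series": dose_series}


def scenario_by_name(name: str) -> Scenario:
    try:
        return _BUILTINS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; built-ins: {sorted(_BUILTINS)}") from None


def scenario_from_yaml(path) -> Scenario:
    """Load a scenario from YAML. Unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario file {path} must hold a mapping")
    known = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
    if "kernel" in raw:
        raw["kernel"] = BurstKernel(**raw["kernel"])
    if "noise" in raw:
        raw["noise"] = NoiseModel(**raw["noise"])
    if "groups" in raw:
        raw["groups"] = tuple(GroupSpec(**g) for g in raw["groups"])
    if "median_range" in raw and raw["median_range"] is not None:
        raw["median_range"] = tuple(raw["median_range"])
    try:
        return Scenario(**raw)
    except TypeError as e:
        raise ConfigError(str(e)) from None


def _well_ids(n_rows: int, n_cols: int) -> list[str]:
    return [f"{chr(ord('A') + r)}{c + 1}" for r in range(n_rows)
            for c in range(n_cols)]


def simulate_plate(scenario: Scenario | str, seed: int) -> tuple[PlateRun, pd.DataFrame]:
    """Simulate a full plate.

    Returns a :class:`PlateRun` (with layout) writable by
    :mod:`lfass.plate_io`, plus a ground-truth table with one row per well
    (``true_median_min`` is the exact sample median of the drawn death
    times). Each well's randomness comes from substream (seed, well index).
    """
    if isinstance(scenario, str):
        scenario = scenario_by_name(scenario)
    seed = int(seed) & 0x7FFFFFFF
    grid = scenario.grid()
    ids = _well_ids(scenario.n_rows, scenario.n_cols)

    # well -> (group label, median or None, sd or None, dose)
    assignments: list[tuple[str, float | None, float | None, str]] = []
    if scenario.groups:
        for g in scenario.groups:
            assignments += [(g.label, g.median_min, g.sd_min, g.dose)] * g.n_wells
    else:
        assignments = [(scenario.name, None, None, "")] * scenario.n_wells

    traces, layout_wells, truth = [], {}, []
    for i, (well, (label, med, sd, dose)) in enumerate(zip(ids, assignments)):
        rng = np.random.default_rng([seed, i])
        if med is None:
            med = float(rng.uniform(*scenario.median_range))
        if sd is None:
            sd = scenario.sd_frac * med
        model = DeathModel(mode="normal", median_min=med, sd_min=sd)
        td = sample_death_times(scenario.n_worms, model, rng)
        traces.append(render_trace(td, scenario.kernel, scenario.noise, grid,
                                   rng, well_id=well))
        layout_wells[well] = WellCondition(
            strain=scenario.strain, age_days=scenario.age_days,
            stressor=scenario.stressor, dose=dose,
            n_worms=scenario.n_worms, group=label)
        truth.append({"well": well, "group": label, "n_worms": scenario.n_worms,
                      "true_median_min": float(np.median(td)), "seed": seed,
                      "median_param_min": med, "sd_param_min": sd})
    run = PlateRun(traces, PlateLayout(layout_wells),
                   meta={"scenario": scenario.name, "seed": seed,
                         "instrument": "simulated", "assay": scenario.stressor})
    return run, pd.DataFrame(truth, columns=TRUTH_COLUMNS)
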