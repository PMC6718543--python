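"""Model/Results interface over the per-well analysis pipeline.

:class:`DFAssayModel` wraps a plate of death-fluorescence traces (from a
kinetic export, or simulated) together with the analysis parameters;
``fit()`` runs the per-well pipeline and returns a
:class:`DFAssayResults` carrying the per-well estimates, QC statuses,
condition summaries and a printable summary table.

    >>> model = DFAssayModel.from_simulation("stress384", seed=42)
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assaystats, dfcurve, plate_io, simkit
from .dfcurve import FitParams, FitResult, STATUS_OK, STATUS_REVIEW, STATUS_UNFIT
from .plate_io import PlateLayout, PlateRun

__all__ = ["DFAssayModel", "DFAssayResults"]


class DFAssayModel:
    """A plate-reader survival assay ready to be fitted.

    Parameters
    ----------
    run : PlateRun
        Traces (and optionally a layout) on a shared time grid.
    params : FitParams, optional
        Analysis parameters; defaults are the package defaults.
    """

    def __init__(self, run: PlateRun, params: FitParams | None = None):
        self.run = run
        self.params = params or FitParams()

    @classmethod
    def from_csv(cls, export_path, layout_path=None, format="wide",
                 params: FitParams | None = None, time_unit="min",
                 cadence_hint=None) -> "DFAssayModel":
        """Build a model from a kinetic export (wide or long CSV/XLSX) and
        an optional layout CSV."""
        run = plate_io.read_kinetic_export(export_path, format=format,
                                           cadence_hint=cadence_hint,
                                           time_unit=time_unit)
        if layout_path is not None:
            run = run.with_layout(plate_io.read_layout(layout_path))
        return cls(run, params)

    @classmethod
    def from_simulation(cls, scenario, seed: int,
                        params: FitParams | None = None) -> "DFAssayModel":
        """Build a model from a simulated plate; ground truth is kept on
        the model as ``.truth``."""
        run, truth = simkit.simulate_plate(scenario, seed)
        model = cls(run, params)
        model.truth = truth
        return model

    def fit(self, mode: str = "auto") -> "DFAssayResults":
        """Run the per-well pipeline and return the results object."""
        fits = dfcurve.batch_fit(self.run, self.params, mode=mode)
        return DFAssayResults(self, fits)


@dataclass
class DFAssayResults:
    """Fitted per-well estimates with QC and aggregation helpers."""

    model: DFAssayModel
    fits: list[FitResult]
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def layout(self) -> PlateLayout | None:
        return self.model.run.layout

    @property
    def frame(self) -> pd.DataFrame:
        """Per-well results as a DataFrame."""
        if self._frame is None:
            self._frame = assaystats.fits_to_frame(self.fits, self.layout)
        return self._frame

    @property
    def status_counts(self) -> dict[str, int]:
        return {s: sum(f.status == s for f in self.fits)
                for s in (STATUS_OK, STATUS_REVIEW, STATUS_UNFIT)}

    @property
    def unfit_fraction(self) -> float:
        return self.status_counts[STATUS_UNFIT] / max(len(self.fits), 1)

    def review_queue(self) -> pd.DataFrame:
        """Wells flagged for human re-analysis (REVIEW or UNFIT)."""
        df = self.frame
        return df[df["status"] != STATUS_OK].reset_index(drop=True)

    def summarize_conditions(self, n_boot: int = 2000, seed: int = 0):
        return assaystats.summarize_conditions(self.fits, self.layout,
                                               n_boot=n_boot, seed=seed)

    def to_csv(self, path) -> None:
        plate_io.write_results_table(self.fits, self.layout, path)

    def summary(self) -> str:
        """Human-readable summary: counts, and per-group medians if a
        layout is attached."""
        c = self.status_counts
        lines = [
            "Death-fluorescence survival assay fit",
            "=" * 46,
            f"wells analysed     : {len(self.fits)}",
            f"OK / REVIEW / UNFIT: {c[STATUS_OK]} / {c[STATUS_REVIEW]} / {c[STATUS_UNFIT]}",
            f"unfit fraction     : {100 * self.unfit_fraction:.1f}%",
        ]
        ok = [f.t_half for f in self.fits if f.status == STATUS_OK]
        if ok:
            lines.append(f"median t_half (OK) : {np.median(ok):.1f} min")
        if self.layout is not None:
            lines.append("-" * 46)
            lines.append(f"{'group':<20}{'n_ok':>5}{'median':>9}{'95% CI':>12}")
            for s in self.summarize_conditions():
                ci = (f"[{s.ci_lo_min:.0f},{s.ci_hi_min:.0f}]"
                      if s.n_wells_ok else "-")
                med = f"{s.median_t_half_min:.1f}" if s.n_wells_ok else "-"
                lines.append(f"{s.group:<20}{s.n_wells_ok:>5}{med:>9}{ci:>12}")
        return "\n".join(lines)

    def plot_well(self, well_id: str, ax=None):
        """QC plot of one well: raw and smoothed trace, detected peak and
        the estimated median time of death."""
        import matplotlib
        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        trace = next((tr for tr in self.model.run.traces
                      if tr.well_id == well_id), None)
        fit = next((f for f in self.fits if f.well_id == well_id), None)
        if trace is None or fit is None:
            raise KeyError(f"well {well_id} not in this run")
        if ax is None:
            _, ax = plt.subplots()
        t = trace.grid.times
        ax.plot(t, trace.fluorescence, lw=0.6, alpha=0.5, label="raw")
        p = dfcurve.preprocess(trace, self.model.params.smooth_window,
                               self.model.params.baseline_quantile,
                               self.model.params.analysis_window)
        if p.valid:
            ax.plot(t, p.f_smooth, lw=1.2, label="smoothed")
        if fit.t_peak is not None:
            ax.axvline(fit.t_peak, ls=":", color="grey", label="peak")
        if fit.t_half is not None:
            ax.axvline(fit.t_half, ls="--", color="C3",
                       label=f"t_half = {fit.t_half:.1f} min")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("fluorescence (au)")
        ax.set_title(f"{well_id} [{fit.status}]")
        ax.legend(fontsize=8)
        return ax
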