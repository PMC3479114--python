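"""Rupture-event detection: core exposure time and windowed force peak.

The event definition follows the analysed pulling protocol: the buried core's
exposure time is the first sample at which its (raw, unsmoothed) SASA
strictly exceeds the threshold (50 Å² by default); the rupture force peak is
the maximum of the 20-ps running-averaged force within a 400 ps window
centered on the exposure time, ties broken by the earliest time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .contacts import CoreSelection
from .geometry import Series, rmsd_series, running_average
from .pulling import KCAL_MOL_A_IN_PN, ForceSeries
from .structure import Selection, Structure, Trajectory
from .surface import sasa_series

__all__ = [
    "NoExposureError",
    "RuptureEvent",
    "RunReport",
    "detect_exposure",
    "peak_force",
    "analyze_pull_run",
    "core_selection_to_atom_selection",
]

DEFAULT_SASA_THRESHOLD = 50.0  # Å²
DEFAULT_PEAK_WINDOW = 400.0  # ps
DEFAULT_SMOOTHING = 20.0  # ps


class NoExposureError(RuntimeError):
    """The SASA series never exceeds the exposure threshold."""


@dataclass
class RuptureEvent:
    exposure_time: float  # ps
    peak_force: float  # kcal/mol/Å
    peak_time: float  # ps
    window: float = DEFAULT_PEAK_WINDOW
    threshold: float = DEFAULT_SASA_THRESHOLD

    @property
    def peak_force_pN(self) -> float:
        return self.peak_force * KCAL_MOL_A_IN_PN

    def to_dict(self) -> dict[str, float]:
        return {
            "exposure_time_ps": self.exposure_time,
            "peak_force_kcal_mol_A": self.peak_force,
            "peak_force_pN": self.peak_force_pN,
            "peak_time_ps": self.peak_time,
            "window_ps": self.window,
            "threshold_A2": self.threshold,
        }


@dataclass
class RunReport:
    """All per-run pulling observables sharing one time base."""

    label: str
    event: RuptureEvent | None
    force: ForceSeries
    series: dict[str, Series]
    parameters: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "event": self.event.to_dict() if self.event is not None else None,
            "parameters": self.parameters,
            "series_labels": sorted(self.series),
        }


def detect_exposure(sasa: Series, threshold: float = DEFAULT_SASA_THRESHOLD) -> float:
    """Time (ps) of the first sample strictly exceeding the SASA threshold.

    A series that starts above the threshold reports its first sample's time;
    a series that never exceeds it raises :class:`NoExposureError`.
    """
    if len(sasa) == 0:
        raise ValueError("empty SASA series")
    above = np.nonzero(sasa.values > threshold)[0]
    if len(above) == 0:
        raise NoExposureError(
            f"SASA never exceeded {threshold} Å² (max {sasa.values.max():.1f} Å²)"
        )
    return float(sasa.times[above[0]])


def peak_force(
    force: ForceSeries,
    exposure_time: float,
    window: float = DEFAULT_PEAK_WINDOW,
    smoothing: float = DEFAULT_SMOOTHING,
    threshold: float = DEFAULT_SASA_THRESHOLD,
) -> RuptureEvent:
    """Maximum of the smoothed force in a window centered on the exposure time.

    The force series is smoothed with a ``smoothing``-ps running average, the
    window spans ``[exposure_time − window/2, exposure_time + window/2]``, and
    ties go to the earliest sample.
    """
    series = Series(force.times, force.force, unit="kcal/mol/A", label="force")
    smooth = running_average(series, width=smoothing) if smoothing > 0 else series
    lo, hi = exposure_time - window / 2.0, exposure_time + window / 2.0
    mask = (smooth.times >= lo) & (smooth.times <= hi)
    if not np.any(mask):
        raise ValueError(f"no force samples within [{lo}, {hi}] ps")
    t_win = smooth.times[mask]
    v_win = smooth.values[mask]
    best = int(np.argmax(v_win))  # argmax returns the first (earliest) maximum
    return RuptureEvent(
        exposure_time=exposure_time,
        peak_force=float(v_win[best]),
        peak_time=float(t_win[best]),
        window=window,
        threshold=threshold,
    )


def core_selection_to_atom_selection(core: CoreSelection) -> Selection:
    return Selection(label="core", residue_numbers=list(core.residues))


def analyze_pull_run(
    traj: Trajectory,
    core_sel: Selection | CoreSelection,
    force: ForceSeries,
    reference: Structure | None = None,
    extra_selections: dict[str, Selection] | None = None,
    threshold: float = DEFAULT_SASA_THRESHOLD,
    window: float = DEFAULT_PEAK_WINDOW,
    smoothing: float = DEFAULT_SMOOTHING,
    sasa_points: int = 240,
    label: str = "run",
) -> RunReport:
    """Assemble the per-run observable bundle and the rupture event.

    Computes the core SASA series (side-chain atoms of the core residues,
    shaded by the whole structure), detects the exposure event and its
    windowed force peak, and adds a SASA series plus a segment RMSD series for
    every extra named selection.  A run whose core never exposes yields
    ``event = None`` rather than an error, so replicate loops can skip it.
    """
    if isinstance(core_sel, CoreSelection):
        core_sel = core_selection_to_atom_selection(core_sel)
    series: dict[str, Series] = {}
    core_sasa = sasa_series(traj, compute_sel=core_sel, n_points=sasa_points)
    series["core_sasa"] = core_sasa
    if extra_selections:
        ref = reference if reference is not None else traj.structure_ref
        for name, sel in extra_selections.items():
            series[f"{name}_sasa"] = sasa_series(traj, compute_sel=sel, n_points=sasa_points)
            series[f"{name}_rmsd"] = rmsd_series(traj, ref, fit_sel=sel)

    event: RuptureEvent | None
    try:
        t_exp = detect_exposure(core_sasa, threshold)
        event = peak_force(force, t_exp, window=window, smoothing=smoothing, threshold=threshold)
    except NoExposureError:
        event = None

    params = {
        "threshold_A2": threshold,
        "window_ps": window,
        "smoothing_ps": smoothing,
        "sasa_points": sasa_points,
        "spring_k": force.spring_k,
    }
    return RunReport(label=label, event=event, force=force, series=series, parameters=params)
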