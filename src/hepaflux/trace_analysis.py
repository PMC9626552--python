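"""Steady-state flux extraction from oxygraph oxygen traces.

An O2k-style oxygraph records chamber oxygen concentration (µM) at a fixed
interval (2 s by default) while substrates, uncouplers and inhibitors are
titrated. Respiration removes oxygen, so the mass-specific flux is recovered
from the (negative) concentration slope:

    J(t) = [ -dC/dt * 1000 - J0bg(C) ] / rho

with C in µM (= nmol mL⁻¹, hence the factor 1000 to pmol s⁻¹ mL⁻¹),
J0bg(C) = a + b·C the instrumental background flux per mL of chamber volume,
and rho the wet tissue mass per chamber volume (mg mL⁻¹). J is then in
pmol O₂ s⁻¹ mg⁻¹ wet mass.

After each titration the signal relaxes to a new steady state; this module
detects the earliest plateau after each event, reports the step flux as the
median over the plateau window together with quality-control flags, and merges
duplicate-chamber measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ProtocolError, TraceError
from .protocols import SuitProtocol, get_protocol

QC_OK = "ok"
QC_NO_PLATEAU = "no_plateau"
QC_SHORT_WINDOW = "short_window"

# worst-of ordering for merged duplicates
_QC_RANK = {QC_OK: 0, QC_SHORT_WINDOW: 1, QC_NO_PLATEAU: 2}


@dataclass(frozen=True)
class TitrationEvent:
    """A chamber addition: when it happened and the state it establishes."""

    time_s: float
    step_name: str
    titrant: str = ""
    concentration: str = ""


@dataclass
class RespiroTrace:
    """Timestamped oxygen-concentration series with titration events.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing.
    o2 : array of float
        Chamber oxygen concentration in µM; must be finite.
    events : sequence of TitrationEvent
        Titration marks, sorted by time.
    chamber_volume : float
        Chamber volume in mL (metadata; fluxes are per-volume already).
    mass_density : float
        Wet tissue mass per chamber volume in mg mL⁻¹.
    chamber_id : str
        Free-text chamber label, used when merging duplicates.
    """

    time: np.ndarray
    o2: np.ndarray
    events: tuple[TitrationEvent, ...]
    chamber_volume: float = 2.0
    mass_density: float = 1.0
    chamber_id: str = "A"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        self.events = tuple(self.events)
        if self.time.ndim != 1 or self.time.shape != self.o2.shape:
            raise TraceError("time and o2 must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise TraceError("trace needs at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise TraceError("time must be strictly increasing")
        if not np.all(np.isfinite(self.o2)):
            raise TraceError("o2 contains non-finite values")
        if self.mass_density <= 0:
            raise TraceError("mass_density must be positive")
        if self.chamber_volume <= 0:
            raise TraceError("chamber_volume must be positive")
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise TraceError("events must be sorted by time")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass(frozen=True)
class FluxExtractionConfig:
    """Settings of the flux extraction, analogous to oxygraph-software analysis
    marks.

    All times in seconds. ``slope_tolerance`` is the tolerated residual trend
    in a plateau window, as a fraction of the step flux per minute; ``cv_max``
    bounds the coefficient of variation of the flux within the window.
    ``background_a``/``background_b`` parameterize the instrumental background
    flux J0bg(C) = a + b·C in pmol s⁻¹ mL⁻¹ (zero by default, the convention
    for a freshly calibrated chamber).
    """

    skip_after_event: float = 60.0
    window_length: float = 120.0
    slope_tolerance: float = 0.01
    cv_max: float = 0.05
    max_wait: float = 600.0
    smoothing_halfwidth: int = 5
    background_a: float = 0.0
    background_b: float = 0.0

    def __post_init__(self) -> None:
        for name in ("skip_after_event", "window_length", "slope_tolerance",
                     "cv_max", "max_wait"):
            if getattr(self, name) <= 0:
                raise TraceError(f"{name} must be positive")
        if self.smoothing_halfwidth < 1:
            raise TraceError("smoothing_halfwidth must be >= 1")
        if self.window_length > self.max_wait:
            raise TraceError("window_length must not exceed max_wait")


@dataclass(frozen=True)
class FluxSeries:
    """Pointwise mass-specific flux derived from a trace. Edge samples, where
    the smoothing window does not fit, are flagged invalid."""

    time: np.ndarray
    flux: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class StepFlux:
    step_name: str
    flux: float
    window: tuple[float, float]
    cv: float
    qc_flag: str = QC_OK
    discordant: bool = False


@dataclass
class StepFluxTable:
    """Per-SUIT-step steady-state fluxes for one liver/timepoint/protocol."""

    liver_id: str
    timepoint: str
    protocol_id: str
    steps: list[StepFlux] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.step_name for s in self.steps]
        if len(set(names)) != len(names):
            raise ProtocolError("step names must be unique within a table")

    def flux(self, step_name: str) -> float:
        for s in self.steps:
            if s.step_name == step_name:
                return s.flux
        raise ProtocolError(f"no step {step_name!r} in table")

    def step(self, step_name: str) -> StepFlux:
        for s in self.steps:
            if s.step_name == step_name:
                return s
        raise ProtocolError(f"no step {step_name!r} in table")

    @property
    def step_names(self) -> list[str]:
        return [s.step_name for s in self.steps]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "liver_id": self.liver_id,
                "timepoint": self.timepoint,
                "protocol_id": self.protocol_id,
                "step_name": [s.step_name for s in self.steps],
                "flux": [s.flux for s in self.steps],
                "window_start": [s.window[0] for s in self.steps],
                "window_end": [s.window[1] for s in self.steps],
                "cv": [s.cv for s in self.steps],
                "qc_flag": [s.qc_flag for s in self.steps],
                "discordant": [s.discordant for s in self.steps],
            }
        )


def compute_flux_series(
    trace: RespiroTrace, config: FluxExtractionConfig | None = None
) -> FluxSeries:
    """Pointwise mass-specific flux by windowed local linear regression.

    The derivative at each sample is the least-squares slope of concentration
    over the ±``smoothing_halfwidth`` neighbouring samples — noise-robust at
    2 s sampling where a finite difference would be dominated by sensor noise.
    """
    config = config or FluxExtractionConfig()
    h = config.smoothing_halfwidth
    t, c = trace.time, trace.o2
    n = t.size
    if n < 2 * h + 1:
        raise TraceError(
            f"need at least {2 * h + 1} samples for smoothing halfwidth {h}"
        )
    w = 2 * h + 1
    tw = np.lib.stride_tricks.sliding_window_view(t, w)
    cw = np.lib.stride_tricks.sliding_window_view(c, w)
    tc = tw - tw.mean(axis=1, keepdims=True)
    cc = cw - cw.mean(axis=1, keepdims=True)
    slope = np.einsum("ij,ij->i", tc, cc) / np.einsum("ij,ij->i", tc, tc)

    flux = np.full(n, np.nan)
    core = slice(h, n - h)
    background = config.background_a + config.background_b * c[core]
    flux[core] = (-slope * 1000.0 - background) / trace.mass_density
    valid = np.zeros(n, dtype=bool)
    valid[core] = True
    return FluxSeries(time=t, flux=flux, valid=valid)


def _window_stats(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """(median, cv, slope per minute) of a flux window."""
    med = float(np.median(f))
    denom = max(abs(med), 1e-12)
    cv = float(np.std(f)) / denom
    tc = t - t.mean()
    slope = float(tc @ (f - f.mean()) / (tc @ tc)) * 60.0  # per minute
    return med, cv, slope


def detect_plateau(
    series: FluxSeries,
    event: TitrationEvent,
    config: FluxExtractionConfig | None = None,
    next_event_time: float | None = None,
) -> StepFlux:
    """Find the earliest steady-state window after a titration event.

    A window of ``window_length`` qualifies when the fitted flux trend is
    within ``slope_tolerance`` (fraction of the flux per minute) and the
    coefficient of variation is within ``cv_max``. The step flux is the median
    of the earliest qualifying window. If no window qualifies before
    min(next event, ``max_wait``) the step is flagged ``no_plateau`` (value
    from the last examined window); if the trace ends before a full window
    fits, ``short_window`` (value from the available samples).
    """
    config = config or FluxExtractionConfig()
    t = series.time
    if not (t[0] <= event.time_s <= t[-1]):
        raise TraceError(
            f"event {event.step_name!r} at {event.time_s} s outside trace span"
        )
    t_min = event.time_s + config.skip_after_event
    end_bound = event.time_s + config.max_wait
    if next_event_time is not None:
        end_bound = min(end_bound, next_event_time)

    idx = np.flatnonzero(series.valid & (t >= t_min))
    if idx.size == 0:
        raise TraceError(
            f"no usable samples after event {event.step_name!r} "
            f"(skip_after_event past trace end?)"
        )

    last_window: tuple[float, float, float, float, float] | None = None
    for s in idx:
        t_end = t[s] + config.window_length
        if t_end > end_bound:
            break
        if t_end > t[-1]:
            # trace ends before a full window fits: best effort from the tail
            sel = idx[idx >= s]
            med, cv, _ = _window_stats(t[sel], series.flux[sel])
            return StepFlux(
                event.step_name, med, (float(t[s]), float(t[sel[-1]])), cv,
                qc_flag=QC_SHORT_WINDOW,
            )
        sel = idx[(idx >= s) & (t[idx] <= t_end)]
        if sel.size < 3:
            continue
        med, cv, slope = _window_stats(t[sel], series.flux[sel])
        last_window = (float(t[s]), float(t[sel[-1]]), med, cv, slope)
        if abs(slope) <= config.slope_tolerance * max(abs(med), 1e-12) and cv <= config.cv_max:
            return StepFlux(event.step_name, med, (float(t[s]), float(t[sel[-1]])), cv)

    if last_window is None:
        sel = idx
        med, cv, _ = _window_stats(t[sel], series.flux[sel])
        return StepFlux(
            event.step_name, med, (float(t[sel[0]]), float(t[sel[-1]])), cv,
            qc_flag=QC_NO_PLATEAU,
        )
    w0, w1, med, cv, _ = last_window
    return StepFlux(event.step_name, med, (w0, w1), cv, qc_flag=QC_NO_PLATEAU)


def evaluate_protocol(
    trace: RespiroTrace,
    protocol: SuitProtocol | str,
    config: FluxExtractionConfig | None = None,
    step_configs: Mapping[str, FluxExtractionConfig] | None = None,
) -> StepFluxTable:
    """Extract one steady-state flux per protocol step, in protocol order.

    ``step_configs`` optionally overrides the extraction settings for named
    steps — useful when plateau windows are sized per step (low-flux LEAK
    states support much longer windows within the chamber oxygen budget).
    """
    if isinstance(protocol, str):
        protocol = get_protocol(protocol)
    config = config or FluxExtractionConfig()

    names = [e.step_name for e in trace.events]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ProtocolError(f"duplicate event names in trace: {sorted(dupes)}")
    by_name = {e.step_name: e for e in trace.events}
    missing = [s.name for s in protocol.steps if s.name not in by_name]
    if missing:
        raise ProtocolError(
            f"trace is missing events for protocol steps: {missing}"
        )
    t_last = trace.time[-1]
    for step in protocol.steps:
        if by_name[step.name].time_s >= t_last:
            raise ProtocolError(
                f"trace truncated before event {step.name!r} "
                f"({by_name[step.name].time_s} s >= trace end {t_last} s)"
            )

    event_times = sorted(e.time_s for e in trace.events)
    base_series = compute_flux_series(trace, config)
    series_cache: dict[int, FluxSeries] = {config.smoothing_halfwidth: base_series}

    steps: list[StepFlux] = []
    for step in protocol.steps:
        cfg = (step_configs or {}).get(step.name, config)
        if cfg.smoothing_halfwidth not in series_cache:
            series_cache[cfg.smoothing_halfwidth] = compute_flux_series(trace, cfg)
        series = series_cache[cfg.smoothing_halfwidth]
        ev = by_name[step.name]
        later = [te for te in event_times if te > ev.time_s]
        nxt = later[0] if later else None
        steps.append(detect_plateau(series, ev, cfg, next_event_time=nxt))

    return StepFluxTable(
        liver_id=trace.chamber_id,
        timepoint="",
        protocol_id=protocol.protocol_id,
        steps=steps,
    )


def merge_duplicates(
    a: StepFluxTable, b: StepFluxTable, cv_threshold: float = 0.15
) -> StepFluxTable:
    """Average duplicate-chamber measurements step by step.

    The merged flux is the mean of the two chambers; steps whose relative
    difference |a-b|/mean exceeds ``cv_threshold`` are flagged discordant.
    QC flags propagate as worst-of.
    """
    if (a.timepoint, a.protocol_id) != (b.timepoint, b.protocol_id):
        raise ProtocolError("duplicates must share timepoint and protocol")
    if set(a.step_names) != set(b.step_names):
        raise ProtocolError(
            f"mismatched step sets: {sorted(a.step_names)} vs {sorted(b.step_names)}"
        )
    merged: list[StepFlux] = []
    for sa in a.steps:
        sb = b.step(sa.step_name)
        mean = 0.5 * (sa.flux + sb.flux)
        if mean != 0:
            discordant = abs(sa.flux - sb.flux) / abs(mean) > cv_threshold
        else:
            discordant = sa.flux != sb.flux
        qc = max(sa.qc_flag, sb.qc_flag, key=_QC_RANK.__getitem__)
        merged.append(
            StepFlux(
                step_name=sa.step_name,
                flux=mean,
                window=(min(sa.window[0], sb.window[0]), max(sa.window[1], sb.window[1])),
                cv=0.5 * (sa.cv + sb.cv),
                qc_flag=qc,
                discordant=discordant or sa.discordant or sb.discordant,
            )
        )
    return StepFluxTable(a.liver_id, a.timepoint, a.protocol_id, merged)
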