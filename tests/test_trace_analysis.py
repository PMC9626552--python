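"""Flux extraction from oxygen traces: closed forms, plateau QC, merging."""

import numpy as np
import pytest

from hepaflux.errors import ProtocolError, TraceError
from hepaflux.synthetic_data import TraceSimParams, simulate_trace
from hepaflux.trace_analysis import (
    QC_NO_PLATEAU,
    QC_OK,
    QC_SHORT_WINDOW,
    FluxExtractionConfig,
    RespiroTrace,
    StepFlux,
    StepFluxTable,
    TitrationEvent,
    compute_flux_series,
    detect_plateau,
    evaluate_protocol,
    merge_duplicates,
)

from conftest import SUIT02_TRUTH, linear_trace_arrays


def _single_step_trace(flux=40.0, mass_density=1.0, duration=600.0):
    t, o2 = linear_trace_arrays(flux=flux, mass_density=mass_density, duration=duration)
    return RespiroTrace(
        time=t, o2=o2, events=(TitrationEvent(0.0, "STEP"),),
        mass_density=mass_density,
    )


class TestComputeFluxSeries:
    def test_linear_decline_gives_constant_flux(self):
        series = compute_flux_series(_single_step_trace(flux=40.0))
        core = series.flux[series.valid]
        assert np.allclose(core, 40.0, atol=1e-9)

    def test_background_subtracts_linearly(self):
        cfg = FluxExtractionConfig(background_a=2.0)
        series = compute_flux_series(_single_step_trace(flux=40.0), cfg)
        assert np.allclose(series.flux[series.valid], 38.0, atol=1e-9)

    def test_doubled_mass_density_halves_flux(self):
        t, o2 = linear_trace_arrays(flux=40.0, mass_density=1.0)
        ev = (TitrationEvent(0.0, "STEP"),)
        low = RespiroTrace(time=t, o2=o2, events=ev, mass_density=1.0)
        high = RespiroTrace(time=t, o2=o2, events=ev, mass_density=2.0)
        f_low = compute_flux_series(low)
        f_high = compute_flux_series(high)
        assert np.allclose(f_high.flux[f_high.valid], f_low.flux[f_low.valid] / 2.0)

    def test_piecewise_linear_matches_analytic_slopes(self):
        # two segments with different slopes; away from the break the local
        # regression must reproduce the analytic flux to machine precision
        dt = 2.0
        t = np.arange(0.0, 1200.0 + dt / 2, dt)
        o2 = np.where(t <= 600.0, 250.0 - 0.040 * t,
                      250.0 - 0.040 * 600.0 - 0.070 * (t - 600.0))
        trace = RespiroTrace(
            time=t, o2=o2,
            events=(TitrationEvent(0.0, "A"), TitrationEvent(600.0, "B")),
        )
        series = compute_flux_series(trace)
        seg1 = series.valid & (t > 20) & (t < 580)
        seg2 = series.valid & (t > 620) & (t < 1180)
        assert np.max(np.abs(series.flux[seg1] - 40.0) / 40.0) < 1e-9
        assert np.max(np.abs(series.flux[seg2] - 70.0) / 70.0) < 1e-9

    def test_non_monotone_time_rejected(self):
        t, o2 = linear_trace_arrays()
        t[5] = t[4]
        with pytest.raises(TraceError):
            RespiroTrace(time=t, o2=o2, events=())


class TestDetectPlateau:
    def test_noiseless_window_starts_at_skip_and_is_exact(self):
        trace = _single_step_trace(flux=40.0)
        series = compute_flux_series(trace)
        cfg = FluxExtractionConfig()
        step = detect_plateau(series, trace.events[0], cfg)
        assert step.qc_flag == QC_OK
        assert step.window[0] == pytest.approx(cfg.skip_after_event)
        assert step.flux == pytest.approx(40.0, abs=1e-9)
        assert step.cv == pytest.approx(0.0, abs=1e-12)

    def test_persistent_drift_flags_no_plateau(self):
        # flux rising 5% per minute: J(t) = 40*(1 + t/1200) -> C quadratic
        dt = 2.0
        t = np.arange(0.0, 600.0 + dt / 2, dt)
        o2 = 250.0 - 0.040 * (t + t**2 / 2400.0)
        trace = RespiroTrace(time=t, o2=o2, events=(TitrationEvent(0.0, "STEP"),))
        step = detect_plateau(compute_flux_series(trace), trace.events[0])
        assert step.qc_flag == QC_NO_PLATEAU

    def test_truncated_trace_yields_short_window(self):
        trace = _single_step_trace(flux=40.0, duration=120.0)  # skip 60 + window 120 > 120
        step = detect_plateau(compute_flux_series(trace), trace.events[0])
        assert step.qc_flag == QC_SHORT_WINDOW
        assert step.flux == pytest.approx(40.0, abs=1e-9)

    def test_exponential_transient_recovered_within_1pct(self):
        params = TraceSimParams(noise_sd=0.0, equilibration_tau=20.0, seed=0)
        trace = simulate_trace(params)
        table = evaluate_protocol(trace, "SUIT02")
        for name, truth in params.true_fluxes.items():
            assert table.flux(name) == pytest.approx(truth, rel=0.01)


class TestEvaluateProtocol:
    def test_suit02_structure_and_exact_recovery(self, noiseless_table):
        assert noiseless_table.step_names == [
            "LEAK", "OXPHOS", "OXPHOS_cytc", "CCCP1", "CCCP2", "CCCP3",
        ]
        assert noiseless_table.flux("LEAK") == pytest.approx(SUIT02_TRUTH["L"], rel=2e-2)
        assert noiseless_table.flux("OXPHOS") == pytest.approx(SUIT02_TRUTH["P"], rel=2e-2)
        assert noiseless_table.flux("OXPHOS_cytc") == pytest.approx(SUIT02_TRUTH["Pc"], rel=2e-2)
        assert noiseless_table.flux("CCCP2") == pytest.approx(SUIT02_TRUTH["E"], rel=2e-2)
        assert all(s.qc_flag == QC_OK for s in noiseless_table.steps)

    def test_missing_event_names_step(self, noiseless_trace):
        trace = RespiroTrace(
            time=noiseless_trace.time, o2=noiseless_trace.o2,
            events=tuple(e for e in noiseless_trace.events if e.step_name != "OXPHOS"),
        )
        with pytest.raises(ProtocolError, match="OXPHOS"):
            evaluate_protocol(trace, "SUIT02")

    def test_duplicate_event_names_rejected(self, noiseless_trace):
        events = noiseless_trace.events + (TitrationEvent(8000.0, "LEAK"),)
        trace = RespiroTrace(
            time=noiseless_trace.time, o2=noiseless_trace.o2, events=events
        )
        with pytest.raises(ProtocolError, match="duplicate"):
            evaluate_protocol(trace, "SUIT02")

    def test_trace_truncated_before_last_event_errors(self, noiseless_trace):
        cut = noiseless_trace.time < noiseless_trace.events[-1].time_s
        trace = RespiroTrace(
            time=noiseless_trace.time[cut], o2=noiseless_trace.o2[cut],
            events=noiseless_trace.events,
        )
        with pytest.raises(ProtocolError, match="truncated"):
            evaluate_protocol(trace, "SUIT02")


def _table(fluxes, liver="L1", tp="pre", qc=None):
    steps = [
        StepFlux(name, f, (0.0, 1.0), 0.01, qc_flag=(qc or {}).get(name, QC_OK))
        for name, f in fluxes.items()
    ]
    return StepFluxTable(liver, tp, "SUIT02", steps)


class TestMergeDuplicates:
    def test_identical_tables_unchanged(self):
        a = _table({"LEAK": 8.0, "OXPHOS": 40.0})
        merged = merge_duplicates(a, _table({"LEAK": 8.0, "OXPHOS": 40.0}))
        assert merged.flux("LEAK") == 8.0
        assert not any(s.discordant for s in merged.steps)

    @pytest.mark.parametrize(
        "fa, fb, expected, flagged",
        [(40.0, 44.0, 42.0, False),   # 9.5% < 15%
         (40.0, 60.0, 50.0, True)],   # 40% > 15%
    )
    def test_discordance_threshold(self, fa, fb, expected, flagged):
        merged = merge_duplicates(_table({"OXPHOS": fa}), _table({"OXPHOS": fb}))
        step = merged.step("OXPHOS")
        assert step.flux == pytest.approx(expected)
        assert step.discordant is flagged

    def test_mismatched_step_sets_rejected(self):
        with pytest.raises(ProtocolError, match="step sets"):
            merge_duplicates(_table({"LEAK": 8.0}), _table({"OXPHOS": 40.0}))

    def test_qc_propagates_worst_of(self):
        a = _table({"LEAK": 8.0}, qc={"LEAK": QC_NO_PLATEAU})
        merged = merge_duplicates(a, _table({"LEAK": 8.2}))
        assert merged.step("LEAK").qc_flag == QC_NO_PLATEAU
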