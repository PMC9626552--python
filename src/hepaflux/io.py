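"""CSV / YAML round-tripping for all pipeline artifacts.

File conventions (all plain text):

* trace: ``time_s,o2_uM`` plus a companion events file
  ``time_s,event_name,titrant,concentration``;
* step fluxes: tidy table keyed by (liver_id, timepoint, protocol_id);
* cohort biomarkers: long format ``liver_id,time_h,parameter,value``;
* outcomes: ``liver_id,lgraft,meaf,ead_flag``;
* perfusate: long per-sample rows per liver;
* simulation parameters: YAML mapping mirroring the params dataclasses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import HepafluxError
from .perfusate_viability import PerfusateSeries, ViabilityCriteria, ViabilityDecision
from .synthetic_data import CohortSimParams, OutcomeCoefs, TraceSimParams
from .trace_analysis import RespiroTrace, StepFlux, StepFluxTable, TitrationEvent


# ---------------------------------------------------------------- traces

def write_trace_csv(trace: RespiroTrace, trace_path, events_path) -> None:
    pd.DataFrame({"time_s": trace.time, "o2_uM": trace.o2}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(
        {
            "time_s": [e.time_s for e in trace.events],
            "event_name": [e.step_name for e in trace.events],
            "titrant": [e.titrant for e in trace.events],
            "concentration": [e.concentration for e in trace.events],
        }
    ).to_csv(events_path, index=False)


def read_trace_csv(
    trace_path,
    events_path,
    chamber_volume: float = 2.0,
    mass_density: float = 1.0,
    chamber_id: str = "A",
) -> RespiroTrace:
    data = pd.read_csv(trace_path)
    events = pd.read_csv(events_path).fillna({"titrant": "", "concentration": ""})
    return RespiroTrace(
        time=data["time_s"].to_numpy(),
        o2=data["o2_uM"].to_numpy(),
        events=tuple(
            TitrationEvent(
                float(r.time_s), str(r.event_name), str(r.titrant), str(r.concentration)
            )
            for r in events.itertuples()
        ),
        chamber_volume=chamber_volume,
        mass_density=mass_density,
        chamber_id=chamber_id,
    )


# ---------------------------------------------------------------- step fluxes

def write_step_tables_csv(tables: list[StepFluxTable], path) -> None:
    pd.concat([t.as_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )


def read_step_tables_csv(path) -> list[StepFluxTable]:
    frame = pd.read_csv(path).fillna({"timepoint": ""})
    tables = []
    keys = ["liver_id", "timepoint", "protocol_id"]
    for (liver, tp, proto), g in frame.groupby(keys, sort=False):
        steps = [
            StepFlux(
                step_name=str(r.step_name),
                flux=float(r.flux),
                window=(float(r.window_start), float(r.window_end)),
                cv=float(r.cv),
                qc_flag=str(r.qc_flag),
                discordant=bool(r.discordant),
            )
            for r in g.itertuples()
        ]
        tables.append(StepFluxTable(str(liver), str(tp), str(proto), steps))
    return tables


# ---------------------------------------------------------------- perfusate

def write_perfusate_csv(series_list: list[PerfusateSeries], path) -> None:
    frames = []
    for s in series_list:
        f = s.samples.copy()
        f.insert(0, "liver_id", s.liver_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_perfusate_csv(path) -> list[PerfusateSeries]:
    frame = pd.read_csv(path)
    if "liver_id" not in frame.columns:
        raise HepafluxError("perfusate CSV needs a liver_id column")
    return [
        PerfusateSeries(str(liver), g.drop(columns="liver_id").reset_index(drop=True))
        for liver, g in frame.groupby("liver_id", sort=True)
    ]


def write_decisions_jsonl(decisions: list[ViabilityDecision], path) -> None:
    with open(path, "w") as fh:
        for d in decisions:
            fh.write(json.dumps(dataclasses.asdict(d)) + "\n")


# ---------------------------------------------------------------- configs

def load_criteria_yaml(path) -> ViabilityCriteria:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "ph_range" in raw:
        raw["ph_range"] = tuple(raw["ph_range"])
    return ViabilityCriteria(**raw)


def load_trace_sim_params(path, seed: int | None = None) -> TraceSimParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    return TraceSimParams(**raw)


def load_cohort_sim_params(path, seed: int | None = None) -> CohortSimParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "outcome_coefs" in raw and isinstance(raw["outcome_coefs"], dict):
        raw["outcome_coefs"] = OutcomeCoefs(**raw["outcome_coefs"])
    if "sampling_times" in raw:
        raw["sampling_times"] = tuple(raw["sampling_times"])
    if "auc_window" in raw:
        raw["auc_window"] = tuple(raw["auc_window"])
    if seed is not None:
        raw["seed"] = seed
    return CohortSimParams(**raw)


def dump_cohort_sim_params(params: CohortSimParams, path) -> None:
    raw = dataclasses.asdict(params)
    raw["flux_location"] = dict(raw["flux_location"])
    raw["flux_scale"] = dict(raw["flux_scale"])
    raw["eff_mean"] = dict(raw["eff_mean"])
    raw["sampling_times"] = list(raw["sampling_times"])
    raw["auc_window"] = list(raw["auc_window"])
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
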