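"""Synthetic study generator with known ground truth.

No public dataset accompanies the liver-NMP bioenergetics study design this
package analyses, so every downstream stage is exercised against synthetic
cohorts whose generating parameters are known exactly:

* ``simulate_trace`` produces oxygraph oxygen traces for a SUIT run —
  piecewise-linear declines at the per-step true fluxes, first-order
  exponential relaxation after each titration, optional instrumental
  background flux and additive Gaussian sensor noise;
* ``simulate_liver`` produces one liver's longitudinal biomarkers (coupling
  states and efficiencies over the NMP sampling times), adenylate panels with
  ATP rising after the start of perfusion, and a perfusate series with
  declining lactate for well-performing livers;
* ``simulate_cohort`` links a continuous outcome score linearly to the AUC
  biomarkers — computed with the very same ``time_auc`` used by the analysis,
  so generator and analyzer can never drift apart definitionally — plus
  Gaussian noise.

Defaults emulate the study conditions: 2 mL chambers, 1 mg mL⁻¹ wet mass,
2 s recording interval, per-liver flux distributions lognormal around the
published cohort medians with spreads matched to the printed IQRs, and
efficiency distributions beta around the published means. Identical seeds
give bit-identical output; per-liver streams are spawned deterministically
from the root seed so single livers can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SimulationError
from .outcome_model import time_auc
from .perfusate_viability import PerfusateSeries
from .protocols import SuitProtocol, get_protocol
from .trace_analysis import RespiroTrace, TitrationEvent

# Coupling-control truth used when no fluxes are supplied: the four states at
# the end of cold storage (pmol O2 s-1 mg-1), with the uncoupler optimum in
# the middle CCCP step and a slight overshoot decline after it.
DEFAULT_SUIT02_FLUXES: dict[str, float] = {
    "LEAK": 8.21,
    "OXPHOS": 40.49,
    "OXPHOS_cytc": 43.48,
    "CCCP1": 65.0,
    "CCCP2": 70.33,
    "CCCP3": 68.0,
}

DEFAULT_SUIT01_FLUXES: dict[str, float] = {
    "F_P": 12.54,
    "FN_P": 17.35,   # F + N increment
    "FNS_P": 40.23,  # all substrates: internal reference
    "S_P": 40.23,
}

_DEFAULT_FLUXES = {"SUIT02": DEFAULT_SUIT02_FLUXES, "SUIT01": DEFAULT_SUIT01_FLUXES}


def _lognormal_sigma_from_iqr(q25: float, q75: float) -> float:
    """Lognormal shape parameter matching a printed interquartile range."""
    z = 2.0 * 0.6744897501960817  # z_.75 - z_.25
    return math.log(q75 / q25) / z


@dataclass
class TraceSimParams:
    """Settings of one simulated oxygraph run.

    ``true_fluxes`` maps step name to the mass-specific plateau flux
    (pmol O₂ s⁻¹ mg⁻¹); ``step_durations`` is either one duration for every
    step or a per-step mapping (seconds). ``equilibration_tau`` is the time
    constant of the first-order post-titration transient, ``noise_sd`` the
    additive concentration noise (µM) on the recorded signal, and
    ``background_a``/``background_b`` the instrumental background flux
    intercept (pmol s⁻¹ mL⁻¹) and O₂ slope (pmol s⁻¹ mL⁻¹ µM⁻¹).
    """

    protocol_id: str = "SUIT02"
    true_fluxes: Mapping[str, float] | None = None
    chamber_volume: float = 2.0
    mass_density: float = 1.0
    o2_start: float = 250.0
    sample_interval: float = 2.0
    equilibration_tau: float = 20.0
    noise_sd: float = 0.5
    background_a: float = 0.0
    background_b: float = 0.0
    step_durations: float | Mapping[str, float] = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chamber_volume <= 0 or self.mass_density <= 0:
            raise SimulationError("chamber_volume and mass_density must be positive")
        if self.o2_start <= 0:
            raise SimulationError("o2_start must be positive")
        if self.sample_interval <= 0:
            raise SimulationError("sample_interval must be positive")
        if self.noise_sd < 0 or self.equilibration_tau < 0:
            raise SimulationError("noise_sd and equilibration_tau must be >= 0")
        if self.true_fluxes is None:
            self.true_fluxes = dict(_DEFAULT_FLUXES[self.protocol_id])

    def duration_of(self, step_name: str) -> float:
        if isinstance(self.step_durations, Mapping):
            return float(self.step_durations[step_name])
        return float(self.step_durations)


def simulate_trace(params: TraceSimParams) -> RespiroTrace:
    """Simulate an oxygen trace for a SUIT protocol run.

    Within each step the concentration declines at
    (flux·mass_density + background)/1000 µM s⁻¹, approached from the
    previous step's rate through an exponential transient of time constant
    ``equilibration_tau``; the underlying concentration is continuous at every
    titration. Raises if a flux would exhaust chamber oxygen before the
    protocol ends, naming the offending step.
    """
    protocol = get_protocol(params.protocol_id)
    missing = [s.name for s in protocol.steps if s.name not in params.true_fluxes]
    if missing:
        raise SimulationError(f"true_fluxes missing protocol steps: {missing}")

    dt = params.sample_interval
    starts: list[float] = []
    t_cursor = 0.0
    for step in protocol.steps:
        starts.append(t_cursor)
        t_cursor += params.duration_of(step.name)
    total = t_cursor
    n = int(math.floor(total / dt)) + 1
    time = np.arange(n) * dt

    step_idx = np.searchsorted(np.asarray(starts), time, side="right") - 1
    fluxes = np.array([params.true_fluxes[s.name] for s in protocol.steps])
    prev_fluxes = np.concatenate([[0.0], fluxes[:-1]])  # before any titrant: no flux
    j_target = fluxes[step_idx]
    if params.equilibration_tau > 0:
        elapsed = time - np.asarray(starts)[step_idx]
        blend = np.exp(-elapsed / params.equilibration_tau)
        j_inst = j_target + (prev_fluxes[step_idx] - j_target) * blend
    else:
        j_inst = j_target

    o2 = np.empty(n)
    o2[0] = params.o2_start
    rho = params.mass_density
    a, b = params.background_a, params.background_b
    for i in range(n - 1):
        rate = -(j_inst[i] * rho + a + b * o2[i]) / 1000.0
        o2[i + 1] = o2[i] + rate * dt
        if o2[i + 1] <= 0.0:
            step = protocol.steps[int(step_idx[i])]
            raise SimulationError(
                f"chamber oxygen exhausted during step {step.name!r} "
                f"at t = {time[i + 1]:.0f} s; lower fluxes, shorten steps or "
                f"raise o2_start"
            )

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        o2 = o2 + rng.normal(0.0, params.noise_sd, size=n)

    events = tuple(
        TitrationEvent(start, step.name, step.titrant, step.concentration)
        for start, step in zip(starts, protocol.steps)
    )
    return RespiroTrace(
        time=time,
        o2=o2,
        events=events,
        chamber_volume=params.chamber_volume,
        mass_density=params.mass_density,
        chamber_id=f"{params.protocol_id}-sim",
    )


@dataclass(frozen=True)
class OutcomeCoefs:
    """Linear link from AUC biomarkers to the outcome score.

    Signs follow the published multivariate model: higher ATP-production
    efficiency (P-L) and lower outer-membrane damage/LEAK predict a better
    (lower) score; magnitudes are scaled so that each term contributes
    comparable variance under the default cohort distributions.
    """

    intercept: float = -0.8
    pl_eff_auc: float = -3.1
    cytc_eff_auc: float = 2.5
    leak_auc: float = -0.047
    interaction: float = -0.125  # cytc_eff_auc x leak_auc product term

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class CohortSimParams:
    """Settings of a simulated NMP cohort.

    Per-liver flux draws are lognormal with medians ``flux_location`` and
    shapes ``flux_scale`` (defaults match the published cohort medians and
    IQRs at the end of cold storage); efficiency draws are beta with means
    ``eff_mean`` and common concentration ``eff_concentration``. Each
    biomarker follows a liver-specific linear trend over NMP hours (slope
    s.d. ``drift_sd``, relative per hour) plus measurement noise of
    coefficient of variation ``meas_cv``. The outcome is
    ``outcome_coefs`` applied to the realized AUC terms plus Gaussian noise.
    """

    n_livers: int = 50
    sampling_times: tuple[float, ...] = (0.0, 1.0, 6.0, 12.0, 20.0)
    flux_location: Mapping[str, float] = field(
        default_factory=lambda: {"oxphos": 40.23, "f_pathway": 12.54, "n_pathway": 4.81}
    )
    flux_scale: Mapping[str, float] = field(
        default_factory=lambda: {
            "oxphos": _lognormal_sigma_from_iqr(33.57, 52.15),
            "f_pathway": _lognormal_sigma_from_iqr(8.88, 14.82),
            "n_pathway": _lognormal_sigma_from_iqr(2.99, 6.67),
        }
    )
    eff_mean: Mapping[str, float] = field(
        default_factory=lambda: {"pl_eff": 0.8, "cytc_eff": 0.06, "ep_eff": 0.40}
    )
    eff_concentration: float = 60.0
    drift_sd: float = 0.01
    meas_cv: float = 0.05
    outcome_coefs: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    outcome_noise_sd: float = 2.0
    transplant_fraction: float = 0.7
    auc_window: tuple[float, float] = (0.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_livers < 2:
            raise SimulationError("n_livers must be >= 2")
        times = np.asarray(self.sampling_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise SimulationError("sampling_times must be non-empty, strictly increasing")
        if self.outcome_noise_sd < 0 or self.drift_sd < 0 or self.meas_cv < 0:
            raise SimulationError("noise parameters must be >= 0")
        if not 0.0 < self.transplant_fraction <= 1.0:
            raise SimulationError("transplant_fraction must be in (0, 1]")


BIOMARKER_PARAMETERS = ("leak", "oxphos", "oxphos_cytc", "et", "pl_eff", "cytc_eff")

PERFUSATE_TIMES_H = (0.25, 1.0, 2.0, 6.0, 12.0, 20.0)


@dataclass
class LiverRecord:
    """One synthetic liver: longitudinal biomarkers, adenylates, perfusate."""

    liver_id: str
    transplanted: bool
    truth: dict[str, float]
    biomarkers: pd.DataFrame      # columns: time_h, parameter, value
    adenylates: pd.DataFrame      # columns: time_h, amp, adp, atp
    perfusate: PerfusateSeries
    outcome: dict[str, float] | None = None

    def biomarker(self, parameter: str) -> pd.DataFrame:
        sub = self.biomarkers[self.biomarkers["parameter"] == parameter]
        return sub.sort_values("time_h").reset_index(drop=True)

    def biomarker_auc(
        self, parameter: str, window: tuple[float, float] = (0.0, 6.0)
    ) -> float:
        sub = self.biomarker(parameter)
        return time_auc(sub["time_h"].to_numpy(), sub["value"].to_numpy(), window)


def _liver_rng(root_seed: int, index: int) -> np.random.Generator:
    # child streams are a pure function of (root seed, liver index) so single
    # livers can be regenerated without generating the whole cohort
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), int(index)]))


def _trajectory(
    rng: np.random.Generator,
    base: float,
    times: np.ndarray,
    drift_sd: float,
    meas_cv: float,
) -> np.ndarray:
    slope = rng.normal(0.0, drift_sd)
    noise = rng.normal(0.0, meas_cv * abs(base), size=times.size) if meas_cv > 0 else 0.0
    return base * (1.0 + slope * times) + noise


def simulate_liver(
    params: CohortSimParams, index: int, seed: int | None = None
) -> LiverRecord:
    """Simulate one liver of the cohort.

    The coupling states L, P, Pc, E share one set of liver-level draws
    (OXPHOS capacity lognormal; P-L, cytochrome-c and E-P efficiencies beta),
    each following its own linear drift over NMP with measurement noise, so
    the per-time-point efficiencies computed downstream scatter around the
    liver's true values. ATP rises after the start of perfusion; lactate
    clears promptly for transplant-quality livers and slowly for poor ones.
    """
    root = params.seed if seed is None else seed
    rng = _liver_rng(root, index)
    times = np.asarray(params.sampling_times, dtype=float)

    kappa = params.eff_concentration
    P0 = rng.lognormal(math.log(params.flux_location["oxphos"]), params.flux_scale["oxphos"])
    pl0 = rng.beta(params.eff_mean["pl_eff"] * kappa, (1 - params.eff_mean["pl_eff"]) * kappa)
    cc0 = rng.beta(params.eff_mean["cytc_eff"] * kappa, (1 - params.eff_mean["cytc_eff"]) * kappa)
    ep0 = rng.beta(params.eff_mean["ep_eff"] * kappa, (1 - params.eff_mean["ep_eff"]) * kappa)
    L0 = P0 * (1.0 - pl0)
    Pc0 = P0 / (1.0 - cc0)
    E0 = Pc0 / (1.0 - ep0)
    F0 = rng.lognormal(math.log(params.flux_location["f_pathway"]), params.flux_scale["f_pathway"])
    N0 = rng.lognormal(math.log(params.flux_location["n_pathway"]), params.flux_scale["n_pathway"])
    transplanted = bool(rng.uniform() < params.transplant_fraction)

    truth = {
        "oxphos": P0, "leak": L0, "oxphos_cytc": Pc0, "et": E0,
        "pl_eff": pl0, "cytc_eff": cc0, "ep_eff": ep0,
        "f_pathway": F0, "n_pathway": N0,
    }

    states = {
        name: _trajectory(rng, truth[name], times, params.drift_sd, params.meas_cv)
        for name in ("leak", "oxphos", "oxphos_cytc", "et")
    }
    rows: list[tuple[float, str, float]] = []
    for i, t in enumerate(times):
        L, P, Pc, E = (states[k][i] for k in ("leak", "oxphos", "oxphos_cytc", "et"))
        rows.extend(
            [
                (t, "leak", L),
                (t, "oxphos", P),
                (t, "oxphos_cytc", Pc),
                (t, "et", E),
                (t, "pl_eff", 1.0 - L / P),
                (t, "cytc_eff", 1.0 - P / Pc),
            ]
        )
    biomarkers = pd.DataFrame(rows, columns=["time_h", "parameter", "value"])

    # adenylates: ATP recovers after the start of perfusion, AMP declines
    atp0 = rng.lognormal(math.log(1.2), 0.35)
    adp0 = rng.lognormal(math.log(0.9), 0.25)
    amp0 = rng.lognormal(math.log(0.5), 0.30)
    gain = rng.lognormal(math.log(0.8), 0.30)
    cv = params.meas_cv
    atp = atp0 * (1.0 + gain * (1.0 - np.exp(-times / 3.0)))
    adp = np.full_like(times, adp0)
    amp = amp0 * (0.55 + 0.45 * np.exp(-times / 4.0))
    if cv > 0:
        atp = atp * (1.0 + rng.normal(0.0, cv, times.size))
        adp = adp * (1.0 + rng.normal(0.0, cv, times.size))
        amp = amp * (1.0 + rng.normal(0.0, cv, times.size))
    adenylates = pd.DataFrame(
        {"time_h": times, "amp": np.abs(amp), "adp": np.abs(adp), "atp": np.abs(atp)}
    )

    perfusate = _simulate_perfusate(rng, f"L{index:03d}", transplanted, cv)

    return LiverRecord(
        liver_id=f"L{index:03d}",
        transplanted=transplanted,
        truth=truth,
        biomarkers=biomarkers,
        adenylates=adenylates,
        perfusate=perfusate,
    )


def _simulate_perfusate(
    rng: np.random.Generator, liver_id: str, good: bool, cv: float
) -> PerfusateSeries:
    t = np.asarray(PERFUSATE_TIMES_H)
    if good:
        l0 = rng.lognormal(math.log(5.5), 0.35)
        lactate = 0.8 + (l0 - 0.8) * np.exp(-t / 0.45)
        ph = rng.normal(7.375, 0.015, t.size)
        bicarb = np.zeros(t.size, dtype=bool)
        ast0, growth = rng.lognormal(math.log(1250.0), 0.6), 0.17
    else:
        l0 = rng.lognormal(math.log(7.7), 0.30)
        lactate = 2.2 + (l0 - 2.2) * np.exp(-t / 1.2)
        ph = rng.normal(7.33, 0.025, t.size)
        bicarb = np.zeros(t.size, dtype=bool)
        if rng.uniform() < 0.6:
            bicarb[:2] = True  # repeated early correction
        ast0, growth = rng.lognormal(math.log(6000.0), 0.6), 0.09
    trend = 1.0 + growth * t
    noise = lambda: 1.0 + rng.normal(0.0, cv, t.size) if cv > 0 else 1.0  # noqa: E731
    ast = ast0 * trend * noise()
    alt = 0.8 * ast0 * trend * noise()
    ldh = 2.0 * ast0 * trend * noise()
    il6 = rng.lognormal(math.log(800.0 if good else 4000.0), 0.5) * trend * noise()
    gldh = rng.lognormal(math.log(300.0 if good else 1500.0), 0.5) * trend * noise()
    samples = pd.DataFrame(
        {
            "time_h": t,
            "lactate": np.maximum(lactate * noise(), 0.0),
            "ph": np.clip(ph, 6.8, 7.8),
            "ast": np.abs(ast),
            "alt": np.abs(alt),
            "ldh": np.abs(ldh),
            "il6": np.abs(il6),
            "gldh": np.abs(gldh),
            "bicarbonate_given": bicarb,
        }
    )
    return PerfusateSeries(liver_id=liver_id, samples=samples)


N_OUTCOME_TERMS = 4  # three AUC main effects + one product interaction


@dataclass
class CohortBundle:
    """A simulated cohort plus its generating truth.

    ``true_outcome_terms`` holds, per liver, the realized AUC predictor values
    and the noiseless linear predictor of the outcome.
    """

    livers: list[LiverRecord]
    truth: CohortSimParams
    true_outcome_terms: pd.DataFrame

    def biomarker_frame(self) -> pd.DataFrame:
        frames = []
        for liver in self.livers:
            f = liver.biomarkers.copy()
            f.insert(0, "liver_id", liver.liver_id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "liver_id": liver.liver_id,
                    "lgraft": liver.outcome["lgraft"],
                    "meaf": liver.outcome["meaf"],
                    "ead_flag": int(liver.outcome["ead_flag"]),
                    "transplanted": int(liver.transplanted),
                }
                for liver in self.livers
            ]
        )

    def adenylate_frame(self) -> pd.DataFrame:
        frames = []
        for liver in self.livers:
            f = liver.adenylates.copy()
            f.insert(0, "liver_id", liver.liver_id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def perfusate_series(self) -> list[PerfusateSeries]:
        return [liver.perfusate for liver in self.livers]

    def model_frame(self) -> pd.DataFrame:
        """AUC predictors joined with the outcome, ready for regression."""
        out = self.true_outcome_terms.merge(self.outcomes_frame(), on="liver_id")
        return out


def simulate_cohort(params: CohortSimParams) -> CohortBundle:
    """Simulate a full cohort with a linear AUC-to-outcome link.

    The linear predictor uses the same trapezoidal ``time_auc`` as the
    analysis modules (self-consistency by construction): outcome =
    intercept + b_pl·AUC(1-L/P) + b_cc·AUC(cyt-c eff) + b_leak·AUC(LEAK)
    + b_int·AUC(cyt-c eff)·AUC(LEAK) + Gaussian noise.
    """
    if params.n_livers <= N_OUTCOME_TERMS + 1:
        raise SimulationError(
            f"n_livers = {params.n_livers} cannot identify "
            f"{N_OUTCOME_TERMS} model terms plus intercept"
        )
    livers = [simulate_liver(params, i) for i in range(params.n_livers)]
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 2**20])
    )
    coefs = params.outcome_coefs
    rows = []
    for liver in livers:
        pl_auc = liver.biomarker_auc("pl_eff", params.auc_window)
        cc_auc = liver.biomarker_auc("cytc_eff", params.auc_window)
        leak_auc = liver.biomarker_auc("leak", params.auc_window)
        lp = (
            coefs.intercept
            + coefs.pl_eff_auc * pl_auc
            + coefs.cytc_eff_auc * cc_auc
            + coefs.leak_auc * leak_auc
            + coefs.interaction * cc_auc * leak_auc
        )
        lgraft = lp + (
            noise_rng.normal(0.0, params.outcome_noise_sd)
            if params.outcome_noise_sd > 0
            else 0.0
        )
        liver.outcome = {
            "lgraft": float(lgraft),
            # companion scores: monotone recodings of the same latent outcome
            "meaf": float(np.clip(4.67 + 1.3 * (lgraft - coefs.intercept), 0.5, 14.0)),
            "ead_flag": bool(lgraft > coefs.intercept),
        }
        rows.append(
            {
                "liver_id": liver.liver_id,
                "pl_eff_auc": pl_auc,
                "cytc_eff_auc": cc_auc,
                "leak_auc": leak_auc,
                "cytc_eff_auc:leak_auc": cc_auc * leak_auc,
                "linear_predictor": float(lp),
            }
        )
    terms = pd.DataFrame(rows)
    return CohortBundle(livers=livers, truth=params, true_outcome_terms=terms)
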