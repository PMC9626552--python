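"""Coupling states, control efficiencies and flux control ratios.

From a coupling-control SUIT run the four respiratory states of the succinate
pathway are

    L   LEAK respiration (substrates, no ADP) — dissipative proton leak,
    P   OXPHOS capacity (saturating ADP),
    Pc  OXPHOS capacity after exogenous cytochrome c,
    E   ET capacity (maximum over the stepwise uncoupler titration).

Derived control efficiencies, each a dimensionless fraction:

    P-L control efficiency   1 - L/P    ATP-production efficiency,
    cyt-c control efficiency 1 - P/Pc   outer-membrane damage,
    E-P control efficiency   1 - P/E    (variant A) or 1 - Pc/E (variant B)
                                        control of the phosphorylation system.

Both E-P variants circulate in the field; this module computes both and lets
the caller pick which one is *the* E-P efficiency. Values outside [0, 1]
diagnose titration problems (e.g. an uncoupler overshoot drives E below P);
they are flagged, never clipped, because silent clipping would hide exactly
the problem the flag is for.

Pathway control (from a substrate-titration run) is expressed as flux control
ratios: each pathway's OXPHOS-state flux divided by the maximal OXPHOS
capacity with all substrates (the internal reference of the measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ProtocolError, UndefinedValueError
from .protocols import CYTC, LEAK, OXPHOS, PATHWAY, REFERENCE, UNCOUPLER, get_protocol
from .trace_analysis import StepFluxTable

FLAG_NEGATIVE_PL = "negative_pl_eff"
FLAG_NEGATIVE_CYTC = "negative_cytc_eff"
FLAG_NEGATIVE_EP = "negative_ep_eff"


@dataclass(frozen=True)
class CouplingProfile:
    """The four coupling-state fluxes, pmol O₂ s⁻¹ mg⁻¹ wet mass."""

    L: float
    P: float
    Pc: float
    E: float
    pathway: str = "S"

    def __post_init__(self) -> None:
        for name in ("L", "P", "Pc", "E"):
            if getattr(self, name) < 0:
                raise UndefinedValueError(f"coupling state {name} must be >= 0")


@dataclass(frozen=True)
class PathwayFluxes:
    """OXPHOS-state pathway fluxes and the all-substrate reference capacity."""

    F_P: float
    N_P: float
    S_P: float
    ref_max: float

    def __post_init__(self) -> None:
        for name in ("F_P", "N_P", "S_P"):
            if getattr(self, name) < 0:
                raise UndefinedValueError(f"pathway flux {name} must be >= 0")
        if self.ref_max <= 0:
            raise UndefinedValueError("ref_max must be positive")


@dataclass(frozen=True)
class EfficiencyPanel:
    """Control efficiencies of one measurement, with QC flags.

    ``ep_eff`` reports the variant selected by ``variant`` ("A": 1-P/E,
    "B": 1-Pc/E); both underlying values are kept.
    """

    pl_eff: float
    cytc_eff: float
    ep_eff_a: float
    ep_eff_b: float
    variant: str = "A"
    flags: tuple[str, ...] = field(default=())

    @property
    def ep_eff(self) -> float:
        return self.ep_eff_a if self.variant == "A" else self.ep_eff_b


def coupling_states(
    table: StepFluxTable, protocol=None
) -> CouplingProfile:
    """Read the L, P, Pc, E states off a coupling-control step-flux table.

    E is the maximum over the recorded uncoupler steps, so a final-step CCCP
    overshoot (declining flux past the optimum) never lowers the reported ET
    capacity.
    """
    protocol = protocol or get_protocol(table.protocol_id)
    kinds = {LEAK: None, OXPHOS: None, CYTC: None}
    uncoupler_fluxes = []
    available = set(table.step_names)
    for step in protocol.steps:
        if step.name not in available:
            raise ProtocolError(f"table is missing protocol step {step.name!r}")
        f = table.flux(step.name)
        if step.kind in kinds:
            kinds[step.kind] = f
        elif step.kind == UNCOUPLER:
            uncoupler_fluxes.append(f)
    for kind, value in kinds.items():
        if value is None:
            raise ProtocolError(f"protocol has no {kind!r} step")
    if not uncoupler_fluxes:
        raise ProtocolError("protocol has no uncoupler step")
    return CouplingProfile(
        L=kinds[LEAK], P=kinds[OXPHOS], Pc=kinds[CYTC], E=max(uncoupler_fluxes)
    )


def pl_control_efficiency(L: float, P: float) -> float:
    """P-L control efficiency 1 - L/P (ATP-production efficiency proxy)."""
    if P <= 0:
        raise UndefinedValueError("P-L control efficiency needs P > 0")
    return 1.0 - L / P


def cytc_control_efficiency(P: float, Pc: float) -> float:
    """Cytochrome c control efficiency 1 - P/Pc (outer-membrane damage proxy)."""
    if Pc <= 0:
        raise UndefinedValueError("cytochrome c control efficiency needs Pc > 0")
    return 1.0 - P / Pc


def ep_control_efficiency(profile: CouplingProfile, variant: str = "A") -> float:
    """E-P control efficiency: 1 - P/E (variant A) or 1 - Pc/E (variant B)."""
    if variant not in ("A", "B"):
        raise UndefinedValueError(f"unknown E-P variant {variant!r}")
    if profile.E <= 0:
        raise UndefinedValueError("E-P control efficiency needs E > 0")
    num = profile.P if variant == "A" else profile.Pc
    return 1.0 - num / profile.E


def efficiency_panel(profile: CouplingProfile, variant: str = "A") -> EfficiencyPanel:
    """All control efficiencies of a profile, with negative values flagged."""
    pl = pl_control_efficiency(profile.L, profile.P)
    cc = cytc_control_efficiency(profile.P, profile.Pc)
    ep_a = ep_control_efficiency(profile, "A")
    ep_b = ep_control_efficiency(profile, "B")
    flags = []
    if pl < 0:
        flags.append(FLAG_NEGATIVE_PL)
    if cc < 0:
        flags.append(FLAG_NEGATIVE_CYTC)
    if (ep_a if variant == "A" else ep_b) < 0:
        flags.append(FLAG_NEGATIVE_EP)
    return EfficiencyPanel(pl, cc, ep_a, ep_b, variant=variant, flags=tuple(flags))


def flux_control_ratios(pf: PathwayFluxes) -> dict[str, float]:
    """FCR of each pathway relative to the all-substrate OXPHOS reference."""
    return {
        "F_P": pf.F_P / pf.ref_max,
        "N_P": pf.N_P / pf.ref_max,
        "S_P": pf.S_P / pf.ref_max,
    }


def pathway_fluxes(table: StepFluxTable, protocol=None) -> PathwayFluxes:
    """Decompose a serial substrate-titration table into pathway fluxes.

    The titration is cumulative (F, then F+N, then all substrates, then
    rotenone isolating S), so the NADH-linked pathway flux is read as the
    increment over the fatty-acid step, and the all-substrate step is the
    internal reference capacity.
    """
    protocol = protocol or get_protocol(table.protocol_id)
    path_steps = protocol.steps_of_kind(PATHWAY)
    ref_step = protocol.single_step_of_kind(REFERENCE)
    if len(path_steps) != 3:
        raise ProtocolError("pathway protocol needs F, FN and S steps")
    f_step, fn_step, s_step = path_steps
    f = table.flux(f_step.name)
    fn = table.flux(fn_step.name)
    s = table.flux(s_step.name)
    ref = table.flux(ref_step.name)
    return PathwayFluxes(F_P=f, N_P=max(fn - f, 0.0), S_P=s, ref_max=ref)


def summarize_efficiencies(panels: pd.DataFrame, by: str = "timepoint") -> pd.DataFrame:
    """Cohort summary as summary-of-ratios: per-liver efficiencies are computed
    first, then averaged — the mean of per-liver ratios, not the ratio of mean
    fluxes (the two differ whenever fluxes vary between livers)."""
    value_cols = [c for c in ("pl_eff", "cytc_eff", "ep_eff") if c in panels.columns]
    if not value_cols:
        raise UndefinedValueError("no efficiency columns to summarize")
    long = panels.melt(id_vars=[by], value_vars=value_cols,
                       var_name="efficiency", value_name="value")
    out = long.groupby([by, "efficiency"])["value"].agg(
        mean="mean",
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    return out.reset_index()
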