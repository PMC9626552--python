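"""Transplantability decision rules and perfusate trajectory summaries.

During normothermic machine perfusion the perfusate is sampled repeatedly and
the decision to transplant rests on three criteria:

1. prompt lactate clearance — any sample at or below the lactate threshold
   (2.5 mmol L⁻¹) no later than the clearance deadline (2 h of NMP);
2. stable physiological pH (7.30–7.45) without repeated sodium bicarbonate
   supplementation ("repeated" operationalized as two or more additions);
3. no excessive enzyme release — AST, ALT and LDH each stay at or below
   20,000 U L⁻¹ throughout.

IL-6 carries no accept/reject threshold; very high levels only raise a
warning. All thresholds are configurable via :class:`ViabilityCriteria`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedValueError

REQUIRED_COLUMNS = ("time_h", "lactate", "ph", "ast", "alt", "ldh")
ANALYTE_COLUMNS = ("lactate", "ph", "ast", "alt", "ldh", "il6", "gldh")


@dataclass
class PerfusateSeries:
    """Per-liver perfusate trajectory.

    ``samples`` is a DataFrame with columns ``time_h``, ``lactate`` (mmol/L),
    ``ph``, ``ast``/``alt``/``ldh`` (U/L) and optionally ``il6``, ``gldh`` and
    the boolean ``bicarbonate_given``.
    """

    liver_id: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.samples.columns]
        if missing:
            raise UndefinedValueError(f"perfusate series missing columns {missing}")
        s = self.samples.sort_values("time_h").reset_index(drop=True)
        if "bicarbonate_given" not in s.columns:
            s["bicarbonate_given"] = False
        for col in ("lactate", "ast", "alt", "ldh"):
            if (s[col].dropna() < 0).any():
                raise UndefinedValueError(f"negative {col} in perfusate series")
        ph = s["ph"].dropna()
        if ((ph <= 6.0) | (ph >= 8.0)).any():
            raise UndefinedValueError("pH outside the plausible range (6, 8)")
        self.samples = s


@dataclass(frozen=True)
class ViabilityCriteria:
    lactate_threshold: float = 2.5      # mmol/L
    lactate_deadline_h: float = 2.0
    ph_range: tuple[float, float] = (7.30, 7.45)
    max_bicarbonate_additions: int = 1  # "repeated" means >= 2
    enzyme_threshold: float = 20_000.0  # U/L, each of AST/ALT/LDH
    il6_warn_threshold: float | None = None


@dataclass(frozen=True)
class ViabilityDecision:
    liver_id: str
    lactate_cleared: bool
    ph_stable: bool
    enzymes_ok: bool
    overall: str
    reasons: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        all_ok = self.lactate_cleared and self.ph_stable and self.enzymes_ok
        if (self.overall == "accept") != all_ok:
            raise UndefinedValueError(
                "overall must be 'accept' exactly when every criterion holds"
            )


def assess_viability(
    series: PerfusateSeries, criteria: ViabilityCriteria | None = None
) -> ViabilityDecision:
    """Apply the transplantability criteria to one perfusate series."""
    criteria = criteria or ViabilityCriteria()
    s = series.samples
    if s.empty:
        raise UndefinedValueError("empty perfusate series")
    early = s[s["time_h"] <= criteria.lactate_deadline_h]
    if early.empty:
        raise UndefinedValueError(
            f"no perfusate sample at or before the lactate deadline "
            f"({criteria.lactate_deadline_h} h)"
        )

    lactate_cleared = bool(
        (early["lactate"] <= criteria.lactate_threshold).any()
    )
    lo, hi = criteria.ph_range
    ph = s["ph"].dropna()
    n_bicarb = int(s["bicarbonate_given"].fillna(False).sum())
    ph_stable = bool(((ph >= lo) & (ph <= hi)).all()) and (
        n_bicarb <= criteria.max_bicarbonate_additions
    )
    enzyme_max = {c: float(s[c].max()) for c in ("ast", "alt", "ldh")}
    enzymes_ok = all(v <= criteria.enzyme_threshold for v in enzyme_max.values())

    reasons = []
    if not lactate_cleared:
        reasons.append(
            f"lactate_cleared: no sample <= {criteria.lactate_threshold} mmol/L "
            f"within {criteria.lactate_deadline_h} h"
        )
    if not ph_stable:
        reasons.append(
            f"ph_stable: pH outside [{lo}, {hi}] or bicarbonate given "
            f"{n_bicarb} times"
        )
    if not enzymes_ok:
        high = {k: v for k, v in enzyme_max.items() if v > criteria.enzyme_threshold}
        reasons.append(f"enzymes_ok: {high} exceed {criteria.enzyme_threshold} U/L")

    warnings = []
    if (
        criteria.il6_warn_threshold is not None
        and "il6" in s.columns
        and (s["il6"].dropna() > criteria.il6_warn_threshold).any()
    ):
        warnings.append(f"il6 above {criteria.il6_warn_threshold}")

    return ViabilityDecision(
        liver_id=series.liver_id,
        lactate_cleared=lactate_cleared,
        ph_stable=ph_stable,
        enzymes_ok=enzymes_ok,
        overall="accept" if (lactate_cleared and ph_stable and enzymes_ok) else "reject",
        reasons=tuple(reasons),
        warnings=tuple(warnings),
    )


def summarize_trajectories(
    cohort: list[PerfusateSeries],
    grouping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Median/IQR per analyte, observed time point and group.

    No interpolation is performed — only observed sampling times appear.
    ``grouping`` maps liver_id to a group label (default: one group "all").
    """
    if not cohort:
        raise UndefinedValueError("empty cohort")
    frames = []
    for series in cohort:
        f = series.samples.copy()
        f["liver_id"] = series.liver_id
        f["group"] = (grouping or {}).get(series.liver_id, "all")
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    analytes = [c for c in ANALYTE_COLUMNS if c in long.columns]
    long = long.melt(
        id_vars=["group", "time_h", "liver_id"], value_vars=analytes,
        var_name="analyte", value_name="value",
    ).dropna(subset=["value"])
    out = long.groupby(["group", "analyte", "time_h"])["value"].agg(
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
        n="count",
    )
    return out.reset_index()
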