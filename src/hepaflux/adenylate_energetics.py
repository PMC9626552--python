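"""Adenylate-derived energetic indices.

Tissue AMP/ADP/ATP amounts (any consistent per-wet-mass unit) give two scale-
invariant indices of the cellular energy state:

    energy charge = (ATP + 0.5*ADP) / (ATP + ADP + AMP)   in [0, 1]
    ATP:ADP ratio = ATP / ADP

The energy charge weighs ADP at one half because each ADP carries one of the
two transferable phosphoanhydride bonds of ATP.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import UndefinedValueError


@dataclass(frozen=True)
class AdenylatePanel:
    """AMP/ADP/ATP amounts of one biopsy (units consistent within a panel)."""

    amp: float
    adp: float
    atp: float
    liver_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        for name in ("amp", "adp", "atp"):
            if getattr(self, name) < 0:
                raise UndefinedValueError(f"{name} must be >= 0")


def energy_charge(panel: AdenylatePanel) -> float:
    total = panel.amp + panel.adp + panel.atp
    if total <= 0:
        raise UndefinedValueError("energy charge undefined for an all-zero panel")
    return (panel.atp + 0.5 * panel.adp) / total


def atp_adp_ratio(panel: AdenylatePanel) -> float:
    if panel.adp <= 0:
        raise UndefinedValueError("ATP:ADP ratio undefined for ADP = 0")
    return panel.atp / panel.adp


def adenylate_indices(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized indices for a table with columns amp, adp, atp.

    Returns a copy with ``energy_charge`` and ``atp_adp`` columns; rows where
    an index is undefined get NaN rather than raising.
    """
    out = frame.copy()
    total = out["amp"] + out["adp"] + out["atp"]
    ec = (out["atp"] + 0.5 * out["adp"]) / total
    out["energy_charge"] = ec.where(total > 0)
    out["atp_adp"] = (out["atp"] / out["adp"]).where(out["adp"] > 0)
    return out
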