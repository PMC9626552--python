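"""SUIT protocol definitions.

A Substrate-Uncoupler-Inhibitor Titration (SUIT) protocol is an ordered
sequence of chamber additions, each driving the tissue homogenate into a new
respiratory state. Two protocols are registered by default:

``SUIT02``
    Coupling-control protocol for the succinate pathway: succinate + rotenone
    without ADP gives LEAK respiration (*L*), ADP gives OXPHOS capacity (*P*),
    exogenous cytochrome c gives *Pc* (outer-membrane integrity check), and
    stepwise CCCP titration up to maximal respiration gives ET capacity (*E*).

``SUIT01``
    Pathway-control protocol in the OXPHOS state: fatty-acid-oxidation
    substrates first (F), then NADH-linked substrates (FN), then succinate
    (FNS, the internal reference with all substrates), then rotenone to leave
    the succinate pathway alone (S).

The registry is open: analyses accept any :class:`SuitProtocol`, so site-
specific titration orders can be added without touching the analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ProtocolError

# step kinds
LEAK = "leak"
OXPHOS = "oxphos"
CYTC = "cytc"
UNCOUPLER = "uncoupler"
PATHWAY = "pathway"
REFERENCE = "reference"


@dataclass(frozen=True)
class ProtocolStep:
    """One titration step: the state it establishes and what is added."""

    name: str
    kind: str
    titrant: str
    concentration: str


@dataclass(frozen=True)
class SuitProtocol:
    protocol_id: str
    steps: tuple[ProtocolStep, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.steps]
        if len(set(names)) != len(names):
            raise ProtocolError(
                f"protocol {self.protocol_id!r} has duplicate step names"
            )

    @property
    def step_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.steps)

    def steps_of_kind(self, kind: str) -> tuple[ProtocolStep, ...]:
        return tuple(s for s in self.steps if s.kind == kind)

    def single_step_of_kind(self, kind: str) -> ProtocolStep:
        matches = self.steps_of_kind(kind)
        if len(matches) != 1:
            raise ProtocolError(
                f"protocol {self.protocol_id!r} needs exactly one {kind!r} step, "
                f"found {len(matches)}"
            )
        return matches[0]


SUIT02 = SuitProtocol(
    "SUIT02",
    (
        ProtocolStep("LEAK", LEAK, "succinate+rotenone", "10 mM / 0.5 uM"),
        ProtocolStep("OXPHOS", OXPHOS, "ADP", "5 mM"),
        ProtocolStep("OXPHOS_cytc", CYTC, "cytochrome c", "10 uM"),
        ProtocolStep("CCCP1", UNCOUPLER, "CCCP", "step 1"),
        ProtocolStep("CCCP2", UNCOUPLER, "CCCP", "step 2"),
        ProtocolStep("CCCP3", UNCOUPLER, "CCCP", "step 3"),
    ),
)

SUIT01 = SuitProtocol(
    "SUIT01",
    (
        ProtocolStep("F_P", PATHWAY, "octanoylcarnitine+malate+ADP", "0.5 mM / 0.1 mM / 5 mM"),
        ProtocolStep("FN_P", PATHWAY, "pyruvate+malate+glutamate", "5 mM / 2 mM / 10 mM"),
        ProtocolStep("FNS_P", REFERENCE, "succinate", "10 mM"),
        ProtocolStep("S_P", PATHWAY, "rotenone", "0.5 uM"),
    ),
)

PROTOCOLS: dict[str, SuitProtocol] = {p.protocol_id: p for p in (SUIT01, SUIT02)}


def get_protocol(protocol_id: str) -> SuitProtocol:
    try:
        return PROTOCOLS[protocol_id]
    except KeyError:
        raise ProtocolError(
            f"unknown protocol {protocol_id!r}; registered: {sorted(PROTOCOLS)}"
        ) from None


def register_protocol(protocol: SuitProtocol) -> None:
    PROTOCOLS[protocol.protocol_id] = protocol
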