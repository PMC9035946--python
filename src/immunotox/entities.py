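"""Cell-agent and molecular-entity catalogue.

Cell agents carry a type, a lattice position, an internal state drawn from
the type's allowed set, an optional clonotypic receptor (lymphocytes only),
MHC haplotype strings, a half-life and a duplication counter bounded by the
Hayflick limit.  Molecular entities are cytokine fields, clonotyped
immunoglobulins and antigens with explicit epitope/peptide bit-strings.
The simulation space is split into three anatomical compartments: bone
marrow (haematopoiesis), thymus (T-cell education) and a generic secondary
lymphoid organ where challenges and vaccines are injected.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np

from .shape_space import BitString

__all__ = [
    "CellType",
    "CellState",
    "Isotype",
    "CompartmentId",
    "CellAgent",
    "Antigen",
    "CYTOKINES",
    "LYMPHOCYTE_TYPES",
    "APC_TYPES",
    "TRANSITION_TABLE",
    "step_lifecycle",
    "isotype_switch",
    "removal_probability",
]


class CellType(enum.Enum):
    B = "B"
    PLB = "PLB"  # plasma B
    TH1 = "TH1"
    TH2 = "TH2"
    TC = "TC"
    TREG = "TREG"
    NK = "NK"
    MONO = "MONO"
    MAC = "MAC"
    DC = "DC"
    MAST = "MAST"
    NEU = "NEU"


class CellState(enum.Enum):
    RESTING = "RESTING"
    ACTIVE = "ACTIVE"
    PRESENTING_II = "PRESENTING_II"
    PRESENTING_I = "PRESENTING_I"
    DUPLICATING = "DUPLICATING"
    ANERGIC = "ANERGIC"
    MEMORY = "MEMORY"


class Isotype(enum.Enum):
    IgM = "IgM"
    IgG = "IgG"
    IgA = "IgA"


class CompartmentId(enum.Enum):
    BONE_MARROW = "BONE_MARROW"
    THYMUS = "THYMUS"
    SECONDARY_ORGAN = "SECONDARY_ORGAN"


#: Cytokine species tracked as molecular fields.
CYTOKINES = (
    "IL1", "IL2", "IL4", "IL6", "IL8", "IL10", "IL12", "IL17", "IL18",
    "IL23", "IFNG", "IFNA1", "IFNB1", "TNFA", "TGFB",
)

LYMPHOCYTE_TYPES = frozenset(
    {CellType.B, CellType.PLB, CellType.TH1, CellType.TH2, CellType.TC}
)
APC_TYPES = frozenset({CellType.MAC, CellType.DC, CellType.MONO, CellType.B})

#: Allowed state transitions per type; the engine only ever applies these.
TRANSITION_TABLE: dict[CellType, frozenset[tuple[CellState, CellState]]] = {
    CellType.B: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.RESTING, CellState.ANERGIC),
        (CellState.ACTIVE, CellState.PRESENTING_II),
        (CellState.PRESENTING_II, CellState.DUPLICATING),
        (CellState.DUPLICATING, CellState.DUPLICATING),
        (CellState.DUPLICATING, CellState.MEMORY),
        (CellState.DUPLICATING, CellState.RESTING),
        (CellState.MEMORY, CellState.DUPLICATING),
    }),
    CellType.PLB: frozenset({(CellState.ACTIVE, CellState.ACTIVE)}),
    CellType.TH1: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.RESTING, CellState.ANERGIC),
        (CellState.ACTIVE, CellState.DUPLICATING),
        (CellState.DUPLICATING, CellState.DUPLICATING),
        (CellState.DUPLICATING, CellState.ACTIVE),
        (CellState.DUPLICATING, CellState.MEMORY),
        (CellState.ACTIVE, CellState.RESTING),
        (CellState.MEMORY, CellState.ACTIVE),
    }),
    CellType.TC: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.RESTING, CellState.ANERGIC),
        (CellState.ACTIVE, CellState.DUPLICATING),
        (CellState.DUPLICATING, CellState.DUPLICATING),
        (CellState.DUPLICATING, CellState.ACTIVE),
        (CellState.ACTIVE, CellState.RESTING),
    }),
    CellType.TREG: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.ACTIVE, CellState.RESTING),
    }),
    CellType.NK: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.ACTIVE, CellState.RESTING),
    }),
    CellType.MONO: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.ACTIVE, CellState.RESTING),
    }),
    CellType.MAC: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.RESTING, CellState.PRESENTING_II),
        (CellState.ACTIVE, CellState.PRESENTING_II),
        (CellState.PRESENTING_II, CellState.RESTING),
        (CellState.ACTIVE, CellState.RESTING),
    }),
    CellType.DC: frozenset({
        (CellState.RESTING, CellState.PRESENTING_II),
        (CellState.RESTING, CellState.PRESENTING_I),
        (CellState.PRESENTING_II, CellState.RESTING),
        (CellState.PRESENTING_I, CellState.RESTING),
    }),
    CellType.MAST: frozenset({
        (CellState.RESTING, CellState.DUPLICATING),
        (CellState.DUPLICATING, CellState.RESTING),
    }),
    CellType.NEU: frozenset({
        (CellState.RESTING, CellState.ACTIVE),
        (CellState.ACTIVE, CellState.RESTING),
    }),
}

TRANSITION_TABLE[CellType.TH2] = TRANSITION_TABLE[CellType.TH1]

_agent_ids = itertools.count()


@dataclass
class CellAgent:
    """One immune cell."""

    cell_type: CellType
    position: int
    state: CellState = CellState.RESTING
    receptor: BitString | None = None
    mhc_I: tuple[BitString, ...] = ()
    mhc_II: tuple[BitString, ...] = ()
    age: int = 0
    half_life: float = 30.0
    duplication_count: int = 0
    isotype: Isotype | None = None
    # transient response bookkeeping
    complex: BitString | None = None   # presented MHC-peptide complex
    antigen_id: str | None = None      # antigen the cell responded to
    divisions_remaining: int = 0
    uid: int = field(default_factory=lambda: next(_agent_ids))

    def __post_init__(self) -> None:
        is_lymph = self.cell_type in LYMPHOCYTE_TYPES
        if is_lymph and self.receptor is None:
            raise ValueError(f"{self.cell_type.value} agent requires a receptor")
        if not is_lymph and self.receptor is not None:
            raise ValueError(f"{self.cell_type.value} agent must not carry a receptor")
        if self.cell_type in (CellType.B, CellType.PLB) and self.isotype is None:
            self.isotype = Isotype.IgM

    def set_state(self, new: CellState) -> None:
        """Apply a transition, enforcing the per-type transition table."""
        if (self.state, new) not in TRANSITION_TABLE[self.cell_type]:
            raise ValueError(
                f"illegal transition {self.state.value} -> {new.value} "
                f"for {self.cell_type.value}"
            )
        self.state = new


@dataclass
class Antigen:
    """A molecular antigen species with explicit epitope/peptide strings."""

    antigen_id: str
    b_epitope: BitString
    peptides: tuple[BitString, ...]
    pamp: bool = True

    def __post_init__(self) -> None:
        if len(self.peptides) < 1:
            raise ValueError("antigen requires at least one peptide")


def removal_probability(half_life: float) -> float:
    """Per-step death probability of the geometric survival model."""
    if half_life <= 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return 1.0 - 2.0 ** (-1.0 / half_life)


def step_lifecycle(agent: CellAgent, rng: np.random.Generator) -> bool:
    """Advance one step of the memoryless survival clock.

    Returns True if the agent survives (its age is incremented), False if it
    is removed.  The per-step removal probability ``1 - 2**(-1/half_life)``
    makes the population half-life equal to ``half_life`` steps.
    """
    if rng.random() < removal_probability(agent.half_life):
        return False
    agent.age += 1
    return True


def isotype_switch(cell: CellAgent, il4_local: float, threshold: float) -> CellAgent:
    """IgM -> IgG class switch driven by local IL-4 at activation.

    Switched cells never revert (IgG/IgA are absorbing); the IgG -> IgA late
    switch is a separate low-rate event handled by the engine.
    """
    if cell.cell_type not in (CellType.B, CellType.PLB):
        raise ValueError("isotype switch applies to B-lineage cells only")
    if cell.isotype is Isotype.IgM and il4_local >= threshold:
        cell.isotype = Isotype.IgG
    return cell
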