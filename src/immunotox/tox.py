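"""Chemical exposure and mechanism-of-action (MoA) layer.

A chemical acts on the immune engine through a target map: each entry names
one engine rate (a cytokine's secretion, the spleen B-cell homeostatic mean,
the thymic export rate, or mast-cell growth) and a Hill-type suppression
curve.  Serum concentration is an exogenous step-constant time course in
ng/ml — no pharmacokinetics.  For PFOA/PFOS the default map suppresses
IL-6, TNF-alpha, IL-4, IL-8, IL-18, IFN-gamma and IL-10 secretion, the
spleen B-cell pool, thymic output (gland atrophy) and IL-4-driven mast-cell
growth; PFOS differs from PFOA only by a potency multiplier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "MoATarget",
    "MoAEntry",
    "MoAMap",
    "ExposureProfile",
    "serum_concentration",
    "suppression_factor",
    "apply_exposure",
    "default_moa_map",
    "PFAS_CYTOKINE_TARGETS",
]

#: Cytokines whose secretion PFAS suppress.
PFAS_CYTOKINE_TARGETS = ("IL6", "TNFA", "IL4", "IL8", "IL18", "IFNG", "IL10")


class MoATarget(enum.Enum):
    CYTOKINE_SECRETION = "CYTOKINE_SECRETION"
    B_POOL_MU = "B_POOL_MU"            # spleen B-cell OU mean
    THYMIC_OUTPUT = "THYMIC_OUTPUT"    # thymic emigration rate
    MAST_GROWTH = "MAST_GROWTH"


@dataclass(frozen=True)
class MoAEntry:
    """One suppressed rate with its Hill dose-response parameters."""

    target: MoATarget
    species: str | None = None  # cytokine id for CYTOKINE_SECRETION targets
    imax: float = 1.0           # maximal fractional suppression, in [0, 1]
    ec50: float = 10.0          # ng/ml at half-maximal suppression
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.imax <= 1.0):
            raise ValueError(f"imax must be in [0, 1], got {self.imax}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if self.hill <= 0:
            raise ValueError(f"hill must be positive, got {self.hill}")
        if (self.target is MoATarget.CYTOKINE_SECRETION) != (self.species is not None):
            raise ValueError("species must be given exactly for cytokine targets")

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.target.value, self.species)


@dataclass
class MoAMap:
    """Chemical id -> target entries, plus per-chemical potency scaling."""

    entries: dict[str, tuple[MoAEntry, ...]]
    potency: dict[str, float] = field(default_factory=dict)

    def for_chemical(self, chemical: str) -> tuple[MoAEntry, ...]:
        if chemical not in self.entries:
            raise KeyError(f"no mechanism-of-action map for chemical {chemical!r}")
        return self.entries[chemical]

    def potency_of(self, chemical: str) -> float:
        return self.potency.get(chemical, 1.0)

    def with_shared_imax(self, imax: float) -> "MoAMap":
        """Copy with one shared maximal suppression on every entry."""
        new = {
            chem: tuple(
                MoAEntry(e.target, e.species, imax, e.ec50, e.hill) for e in ents
            )
            for chem, ents in self.entries.items()
        }
        return MoAMap(new, dict(self.potency))


@dataclass(frozen=True)
class ExposureProfile:
    """Step-constant serum concentration time course (ng/ml)."""

    chemical: str = "PFOA"
    points: tuple[tuple[int, float], ...] = ()  # (step, ng/ml), step-ascending

    def __post_init__(self) -> None:
        steps = [s for s, _ in self.points]
        if steps != sorted(set(steps)):
            raise ValueError("profile steps must be strictly increasing")
        if any(c < 0 for _, c in self.points):
            raise ValueError("serum concentrations must be non-negative")

    @classmethod
    def constant(cls, conc: float, chemical: str = "PFOA", start: int = 0) -> "ExposureProfile":
        return cls(chemical=chemical, points=((start, conc),))

    @classmethod
    def none(cls, chemical: str = "PFOA") -> "ExposureProfile":
        return cls(chemical=chemical, points=())


def serum_concentration(profile: ExposureProfile, t: int) -> float:
    """Step-constant lookup; 0 before the first defined point."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    conc = 0.0
    for step, c in profile.points:
        if step <= t:
            conc = c
        else:
            break
    return conc


def suppression_factor(conc: float, entry: MoAEntry) -> float:
    """Multiplicative rate factor ``1 - Imax * C^h / (C^h + EC50^h)``.

    Continuous and non-increasing in ``conc``; 1 at zero exposure and
    ``1 - Imax`` in the high-dose limit.
    """
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    if conc == 0.0:
        return 1.0
    ch = conc**entry.hill
    return 1.0 - entry.imax * ch / (ch + entry.ec50**entry.hill)


def apply_exposure(
    profile: ExposureProfile, moa_map: MoAMap, t: int
) -> dict[tuple[str, str | None], float]:
    """Rate multipliers for every MoA target at step ``t``.

    Returns a dict keyed by ``(target, species)``; untargeted rates are
    simply absent (multiplier 1).  At zero serum concentration all
    multipliers are exactly 1, so an exposed run with C=0 is bit-identical
    to an unexposed run.
    """
    entries = moa_map.for_chemical(profile.chemical)
    conc = serum_concentration(profile, t) * moa_map.potency_of(profile.chemical)
    return {e.key: suppression_factor(conc, e) for e in entries}


def default_moa_map(
    imax: float, ec50: float = 10.0, hill: float = 1.0,
    potency: dict[str, float] | None = None,
) -> MoAMap:
    """The shipped PFOA/PFOS target map (equal parameters on every target)."""
    entries = tuple(
        MoAEntry(MoATarget.CYTOKINE_SECRETION, sp, imax, ec50, hill)
        for sp in PFAS_CYTOKINE_TARGETS
    ) + (
        MoAEntry(MoATarget.B_POOL_MU, None, imax, ec50, hill),
        MoAEntry(MoATarget.THYMIC_OUTPUT, None, imax, ec50, hill),
        MoAEntry(MoATarget.MAST_GROWTH, None, imax, ec50, hill),
    )
    potency = potency or {"PFOA": 1.0, "PFOS": 2.0}
    return MoAMap({"PFOA": entries, "PFOS": entries}, potency)


def moa_map_from_config(cfg) -> MoAMap:
    """Build the default map from the shipped parameter file."""
    d = cfg["exposure"]["moa_defaults"]
    return default_moa_map(
        imax=d["imax"], ec50=d["ec50"], hill=d["hill"],
        potency=dict(cfg["exposure"]["potency"]),
    )
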