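"""The simulation loop.

One step advances the world through a fixed, documented phase order:

1. exposure update (serum concentration -> rate multipliers),
2. haematopoiesis (Ornstein-Uhlenbeck homeostasis of naive pools, new cells
   created in the bone marrow) and compartment emigration,
3. thymic education of newly arrived T cells (positive then negative
   selection against the patient's MHC strings and self complexes),
4. per-site interactions under a per-site randomized Bernoulli schedule,
   followed by field-driven state changes and clonal expansion,
5. cytokine and immunoglobulin secretion, antibody-mediated antigen
   neutralisation,
6. molecular-field diffusion and decay, antigen unit diffusion,
7. agent Brownian diffusion,
8. lifecycle (geometric survival by half-life).

Interactions only couple entities co-located on one lattice site within one
step, and the whole run is a pure function of (config, patient parameters,
seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import SimConfig
from .entities import (
    APC_TYPES,
    Antigen,
    CYTOKINES,
    CellAgent,
    CellState,
    CellType,
    CompartmentId,
    Isotype,
    isotype_switch,
    removal_probability,
)
from .lattice import (
    Boundary,
    Geometry,
    Lattice,
    MolecularField,
    decay_field,
    diffuse_agents,
    diffuse_field,
)
from .shape_space import (
    AffinityParams,
    BitString,
    binding_probability,
    hamming_distance,
    mutate_receptor,
    sample_repertoire,
)
from .tox import ExposureProfile, MoAMap, apply_exposure

__all__ = [
    "OUParams",
    "ThymusThresholds",
    "InteractionRule",
    "SimulationState",
    "ou_step",
    "haematopoiesis",
    "thymus_positive",
    "thymus_negative",
    "thymus_education",
    "build_site_schedule",
    "execute_site_interactions",
    "process_and_present",
    "clonal_expansion",
    "secrete",
    "initialize_state",
    "step_world",
    "T_LINEAGES",
]

#: Receptor-bearing lineages routed through the thymus (regulatory T cells
#: are tracked without an explicit clonotypic receptor and traffic directly).
T_LINEAGES = (CellType.TH1, CellType.TH2, CellType.TC)
#: Lineages replenished by haematopoiesis (PLB and memory arise peripherally).
HAEMATOPOIETIC = (
    CellType.B, CellType.TH1, CellType.TH2, CellType.TC, CellType.TREG,
    CellType.NK, CellType.MONO, CellType.MAC, CellType.DC, CellType.MAST,
    CellType.NEU,
)
_PROFESSIONAL_APC = (CellType.MAC, CellType.DC, CellType.MONO)


@dataclass(frozen=True)
class OUParams:
    """Mean-reverting homeostasis of one lineage's naive pool."""

    mu: float
    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.sigma < 0 or self.mu < 0:
            raise ValueError("sigma and mu must be non-negative")

    def stationary_std(self) -> float:
        return self.sigma / math.sqrt(2.0 * self.theta)


@dataclass(frozen=True)
class ThymusThresholds:
    theta_pos: int
    theta_neg: int
    self_peptides: tuple[BitString, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.theta_pos <= self.theta_neg):
            raise ValueError(
                f"need 0 <= theta_pos <= theta_neg, got "
                f"({self.theta_pos}, {self.theta_neg})"
            )


# --------------------------------------------------------------------------
# Ornstein-Uhlenbeck homeostasis
# --------------------------------------------------------------------------

def ou_step(
    x: float, params: OUParams, dt: float, rng: np.random.Generator,
    *, integer: bool = True,
) -> float:
    """Exact one-step update of the mean-reverting process.

    ``x' = mu + (x - mu) e^{-theta dt} + sigma sqrt((1 - e^{-2 theta dt}) /
    (2 theta)) eps`` with standard-normal ``eps``; the result is clamped at
    zero and (by default) rounded to an integer cell count.
    """
    e = math.exp(-params.theta * dt)
    sd = params.sigma * math.sqrt((1.0 - e * e) / (2.0 * params.theta))
    new = params.mu + (x - params.mu) * e + sd * rng.standard_normal()
    new = max(0.0, new)
    return round(new) if integer else new


# --------------------------------------------------------------------------
# Thymic education
# --------------------------------------------------------------------------

def thymus_positive(
    receptor: BitString, mhc_set: tuple[BitString, ...], thresholds: ThymusThresholds
) -> bool:
    """Positive selection: keep iff some MHC string is complementary enough."""
    if not mhc_set:
        raise ValueError("positive selection requires a non-empty MHC set")
    return max(hamming_distance(receptor, m) for m in mhc_set) >= thresholds.theta_pos


def thymus_negative(
    receptor: BitString,
    self_complexes: tuple[BitString, ...],
    thresholds: ThymusThresholds,
) -> bool:
    """Negative selection: remove iff too complementary to a self complex."""
    if not self_complexes:
        return True
    return max(
        hamming_distance(receptor, c) for c in self_complexes
    ) < thresholds.theta_neg


def thymus_education(
    repertoire: list[BitString],
    mhc_set: tuple[BitString, ...],
    self_complexes: tuple[BitString, ...],
    thresholds: ThymusThresholds,
) -> list[BitString]:
    """Positive then negative selection, in that order."""
    survivors = [r for r in repertoire if thymus_positive(r, mhc_set, thresholds)]
    return [r for r in survivors if thymus_negative(r, self_complexes, thresholds)]


def mhc_peptide_complex(mhc: BitString, peptide: BitString) -> BitString:
    """Deterministic, length-preserving combiner (bitwise XOR)."""
    if mhc.length != peptide.length:
        raise ValueError("MHC and peptide strings must share one length")
    return BitString(mhc.length, mhc.value ^ peptide.value)


# --------------------------------------------------------------------------
# Antigen processing and presentation
# --------------------------------------------------------------------------

def process_and_present(
    apc: CellAgent,
    antigen: Antigen,
    pathway: str,
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> BitString | None:
    """Load one antigen peptide onto one of the APC's MHC strings.

    ``pathway`` is ``"ENDOCYTIC"`` (class II) or ``"CYTOSOLIC"`` (class I).
    Every peptide is tested against every MHC string of the pathway's class
    with the binding rule; the first success returns the MHC-peptide complex
    string and the caller moves the APC into the matching PRESENTING state.
    """
    if pathway == "ENDOCYTIC":
        mhc_strings = apc.mhc_II
    elif pathway == "CYTOSOLIC":
        mhc_strings = apc.mhc_I
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    if not mhc_strings:
        raise ValueError(
            f"{apc.cell_type.value} agent has no MHC strings for {pathway}"
        )
    for peptide in antigen.peptides:
        for mhc in mhc_strings:
            p = binding_probability(peptide, mhc, affinity)
            if p > 0 and rng.random() < p:
                return mhc_peptide_complex(mhc, peptide)
    return None


# --------------------------------------------------------------------------
# Clonal expansion
# --------------------------------------------------------------------------

def clonal_expansion(
    cell: CellAgent,
    hayflick_limit: int,
    rng: np.random.Generator,
    *,
    hypermutation_prob: float = 0.0,
) -> list[CellAgent]:
    """One division of a DUPLICATING cell: two daughters, or none at the
    Hayflick limit.  Daughters inherit the receptor (B daughters may receive
    one-bit hypermutation) and carry ``duplication_count = parent + 1``.
    """
    if cell.state is not CellState.DUPLICATING:
        raise ValueError("clonal expansion requires a DUPLICATING cell")
    if cell.duplication_count >= hayflick_limit:
        return []
    daughters = []
    for _ in range(2):
        receptor = cell.receptor
        if (
            receptor is not None
            and cell.cell_type is CellType.B
            and hypermutation_prob > 0
            and rng.random() < hypermutation_prob
        ):
            receptor = mutate_receptor(receptor, 1, rng)
        daughters.append(
            CellAgent(
                cell_type=cell.cell_type,
                position=cell.position,
                state=CellState.DUPLICATING,
                receptor=receptor,
                mhc_I=cell.mhc_I,
                mhc_II=cell.mhc_II,
                half_life=cell.half_life,
                duplication_count=cell.duplication_count + 1,
                isotype=cell.isotype,
                antigen_id=cell.antigen_id,
                divisions_remaining=max(0, cell.divisions_remaining - 1),
            )
        )
    return daughters


# --------------------------------------------------------------------------
# Interaction rules and the per-site randomized schedule
# --------------------------------------------------------------------------

@dataclass
class InteractionRule:
    """One Bernoulli interaction between an actor type and a partner.

    ``kind`` is SPECIFIC (probability computed from receptor
    complementarity) or ASPECIFIC (fixed probability, e.g. the TLR-PAMP
    coupling p').  ``partner_kind`` is ``"cell"`` or ``"antigen"``.
    """

    name: str
    kind: str                       # "SPECIFIC" | "ASPECIFIC"
    partner_kind: str               # "cell" | "antigen"
    actors: Callable                # (site_agents) -> list[CellAgent]
    partners: Callable              # (state, site) -> list
    probability: Callable           # (actor, partner, state, site) -> float
    effects: Callable               # (actor, partner, state, site, rng) -> None
    consumes_partner: bool = False


def build_site_schedule(
    rules: list[InteractionRule],
    agents_at_site: list[CellAgent],
    rng: np.random.Generator,
) -> list[tuple[InteractionRule, CellAgent]]:
    """Randomized attempt plan for one site.

    The rule order is permuted uniformly, and within each rule the actor
    list is permuted uniformly; the plan is deterministic under a fixed
    seed.  This per-site randomization is what removes scheduling bias from
    the serialized execution of nominally simultaneous interactions.
    """
    plan: list[tuple[InteractionRule, CellAgent]] = []
    rule_order = rng.permutation(len(rules))
    for ri in rule_order:
        rule = rules[ri]
        actors = rule.actors(agents_at_site)
        if not actors:
            continue
        for ai in rng.permutation(len(actors)):
            plan.append((rule, actors[ai]))
    return plan


def execute_site_interactions(
    site: int,
    rules: list[InteractionRule],
    state: "SimulationState",
    rng: np.random.Generator,
) -> list[tuple[str, CellAgent, object]]:
    """Run the randomized schedule at one site.

    Per rule, each actor is compared to the partners in turn until one
    Bernoulli attempt succeeds (at most one success per actor per rule);
    consumed partners are unavailable to later attempts.  Returns the event
    list in application order.
    """
    agents_here = state.site_agents(CompartmentId.SECONDARY_ORGAN, site)
    events: list[tuple[str, CellAgent, object]] = []
    consumed: set[int] = set()
    for rule, actor in build_site_schedule(rules, agents_here, rng):
        if actor.state is CellState.ANERGIC:
            continue
        for partner in rule.partners(state, site):
            if isinstance(partner, CellAgent) and (
                partner.uid in consumed or partner is actor
            ):
                continue
            p = rule.probability(actor, partner, state, site)
            if p <= 0.0:
                continue
            if rng.random() < p:
                rule.effects(actor, partner, state, site, rng)
                if rule.consumes_partner:
                    if isinstance(partner, CellAgent):
                        consumed.add(partner.uid)
                        state.remove_agent(CompartmentId.SECONDARY_ORGAN, partner)
                    else:  # antigen unit
                        state.consume_antigen(partner, site)
                events.append((rule.name, actor, partner))
                break
    return events


# --------------------------------------------------------------------------
# Simulation state
# --------------------------------------------------------------------------

class _AntigenUnit:
    """Lightweight partner token for one antigen unit at a site."""

    __slots__ = ("antigen",)

    def __init__(self, antigen: Antigen):
        self.antigen = antigen


@dataclass
class SimulationState:
    config: SimConfig
    lattice: Lattice
    rng: np.random.Generator
    mhc_I: tuple[BitString, ...]
    mhc_II: tuple[BitString, ...]
    self_complexes: tuple[BitString, ...]
    thresholds: ThymusThresholds
    lineage_params: dict[CellType, OUParams]
    exposure: ExposureProfile
    moa_map: MoAMap | None

    t: int = 0
    initialized: bool = False
    compartments: dict[CompartmentId, list[CellAgent]] = field(default_factory=dict)
    fields: dict[str, MolecularField] = field(default_factory=dict)
    antigens: dict[str, Antigen] = field(default_factory=dict)
    antigen_counts: dict[str, np.ndarray] = field(default_factory=dict)
    ig_pools: dict[tuple[int | None, Isotype], np.ndarray] = field(default_factory=dict)
    ou_targets: dict[CellType, float] = field(default_factory=dict)
    multipliers: dict[tuple[str, str | None], float] = field(default_factory=dict)
    rules: list[InteractionRule] = field(default_factory=list)
    secretion_table: dict = field(default_factory=dict)
    thymic_output_scale: float = 1.0
    _site_map: dict[int, list[CellAgent]] | None = None

    # ---- bookkeeping helpers ---------------------------------------------
    def agents(self, comp: CompartmentId) -> list[CellAgent]:
        return self.compartments[comp]

    def site_agents(self, comp: CompartmentId, site: int) -> list[CellAgent]:
        if self._site_map is None:
            self._rebuild_site_map()
        return self._site_map.get(site, [])

    def _rebuild_site_map(self) -> None:
        m: dict[int, list[CellAgent]] = {}
        for a in self.compartments[CompartmentId.SECONDARY_ORGAN]:
            m.setdefault(a.position, []).append(a)
        self._site_map = m

    def invalidate_site_map(self) -> None:
        self._site_map = None

    def remove_agent(self, comp: CompartmentId, agent: CellAgent) -> None:
        self.compartments[comp].remove(agent)
        if self._site_map is not None and comp is CompartmentId.SECONDARY_ORGAN:
            lst = self._site_map.get(agent.position)
            if lst and agent in lst:
                lst.remove(agent)

    def add_agent(self, comp: CompartmentId, agent: CellAgent) -> None:
        self.compartments[comp].append(agent)
        if self._site_map is not None and comp is CompartmentId.SECONDARY_ORGAN:
            self._site_map.setdefault(agent.position, []).append(agent)

    def consume_antigen(self, unit: _AntigenUnit, site: int) -> None:
        counts = self.antigen_counts[unit.antigen.antigen_id]
        if counts[site] > 0:
            counts[site] -= 1

    def multiplier(self, target: str, species: str | None = None) -> float:
        return self.multipliers.get((target, species), 1.0)

    def inject_antigen(self, antigen: Antigen, dose: int) -> None:
        """Spread ``dose`` units uniformly over the secondary-organ lattice."""
        if antigen.antigen_id not in self.antigens:
            self.antigens[antigen.antigen_id] = antigen
            self.antigen_counts[antigen.antigen_id] = np.zeros(
                self.lattice.n_sites, dtype=np.int64
            )
        counts = self.antigen_counts[antigen.antigen_id]
        n = self.lattice.n_sites
        counts += dose // n
        counts[: dose % n] += 1

    # ---- observables ------------------------------------------------------
    def count_by_type(self) -> dict[CellType, int]:
        out = {ct: 0 for ct in CellType}
        for a in self.compartments[CompartmentId.SECONDARY_ORGAN]:
            out[a.cell_type] += 1
        return out

    def specific_ig_total(self, antigen_id: str, isotype: Isotype) -> float:
        """Total immunoglobulin able to bind the antigen's B epitope.

        Counted at the loosest engagement threshold in the model
        (``d_min`` relaxed by the memory allowance), so antibody secreted
        by memory-derived clones is included.
        """
        antigen = self.antigens.get(antigen_id)
        if antigen is None:
            return 0.0
        aff = self.config.affinity
        relax = self.config["expansion"]["memory_dmin_relax"]
        threshold = max(0, aff.d_min - relax)
        total = 0.0
        for (paratope, iso), conc in self.ig_pools.items():
            if iso is not isotype or paratope is None:
                continue
            d = (paratope ^ antigen.b_epitope.value).bit_count()
            if d >= threshold:
                total += float(conc.sum())
        return total

    def snapshot(self) -> dict:
        """JSON-serializable dump of the full dynamical state.

        Two runs with the same config and seed produce identical snapshots
        at every step; the dump is also convenient for inspection.
        """
        agents = []
        for comp in CompartmentId:
            for a in self.compartments[comp]:
                agents.append([
                    comp.value, a.cell_type.value, int(a.position),
                    a.state.value,
                    a.receptor.value if a.receptor is not None else None,
                    int(a.age), int(a.duplication_count),
                    a.isotype.value if a.isotype is not None else None,
                    int(a.divisions_remaining),
                ])
        return {
            "t": int(self.t),
            "agents": agents,
            "fields": {sp: f.conc.tolist() for sp, f in self.fields.items()},
            "ig_pools": {
                f"{p if p is not None else 'bulk'}:{iso.value}": c.tolist()
                for (p, iso), c in self.ig_pools.items()
            },
            "antigens": {
                aid: c.tolist() for aid, c in self.antigen_counts.items()
            },
            "ou_targets": {
                ct.value: float(x) for ct, x in self.ou_targets.items()
            },
        }

    def ig_summary(
        self, antigen_ids: list[str]
    ) -> tuple[dict[Isotype, float], dict[tuple[str, Isotype], float]]:
        """One-pass totals and antigen-specific totals of the Ig pools."""
        aff = self.config.affinity
        relax = self.config["expansion"]["memory_dmin_relax"]
        threshold = max(0, aff.d_min - relax)
        epitopes = {
            aid: self.antigens[aid].b_epitope.value
            for aid in antigen_ids if aid in self.antigens
        }
        totals = {iso: 0.0 for iso in Isotype}
        specific = {
            (aid, iso): 0.0 for aid in antigen_ids for iso in Isotype
        }
        for (paratope, iso), conc in self.ig_pools.items():
            mass = float(conc.sum())
            totals[iso] += mass
            if paratope is None:
                continue
            for aid, epi in epitopes.items():
                if (paratope ^ epi).bit_count() >= threshold:
                    specific[(aid, iso)] += mass
        return totals, specific

    def total_ig(self, isotype: Isotype) -> float:
        return float(
            sum(c.sum() for (p, iso), c in self.ig_pools.items() if iso is isotype)
        )


# --------------------------------------------------------------------------
# Secretion
# --------------------------------------------------------------------------

def secrete(
    cell: CellAgent,
    state: SimulationState,
    secretion_table: dict[tuple[CellType, CellState], dict[str, float]],
) -> None:
    """Deposit the cell's cytokine output at its site.

    The base rate of every species is multiplied by the chemical suppression
    factor for that species (1 when unexposed).  Plasma cells are handled
    separately (they feed the clonotyped immunoglobulin pools).
    """
    entry = secretion_table.get((cell.cell_type, cell.state))
    if not entry:
        return
    for species, rate in entry.items():
        f = state.multiplier("CYTOKINE_SECRETION", species)
        if rate * f > 0.0:
            state.fields[species].conc[cell.position] += rate * f


def _secrete_immunoglobulin(state: SimulationState, cfg: SimConfig) -> None:
    rate = cfg["immunoglobulin"]["secretion_rate"]
    cap = cfg["immunoglobulin"]["clonotype_cap"]
    n = state.lattice.n_sites
    for cell in state.compartments[CompartmentId.SECONDARY_ORGAN]:
        if cell.cell_type is not CellType.PLB:
            continue
        key = (cell.receptor.value, cell.isotype)
        pool = state.ig_pools.get(key)
        if pool is None:
            pool = state.ig_pools[key] = np.zeros(n)
        pool[cell.position] += rate
    # clonotype cap: aggregate the least-abundant specific pools into bulk
    specific = [k for k in state.ig_pools if k[0] is not None]
    if len(specific) > cap:
        specific.sort(key=lambda k: (float(state.ig_pools[k].sum()), k[0]))
        for key in specific[: len(specific) - cap]:
            bulk = state.ig_pools.setdefault((None, key[1]), np.zeros(n))
            bulk += state.ig_pools.pop(key)


# --------------------------------------------------------------------------
# Default interaction rules
# --------------------------------------------------------------------------

def _antigen_partners(state: SimulationState, site: int) -> list[_AntigenUnit]:
    out = []
    for aid, counts in state.antigen_counts.items():
        c = int(counts[site])
        if c > 0:
            ag = state.antigens[aid]
            out.extend(_AntigenUnit(ag) for _ in range(c))
    return out


def _has_costim(state: SimulationState, site: int) -> bool:
    for a in state.site_agents(CompartmentId.SECONDARY_ORGAN, site):
        if a.cell_type in _PROFESSIONAL_APC and a.state is not CellState.RESTING:
            return True
    return False


def default_rules(cfg: SimConfig) -> list[InteractionRule]:
    aff = cfg.affinity
    aff_memory = AffinityParams(
        aff.l,
        max(0, aff.d_min - cfg["expansion"]["memory_dmin_relax"]),
        aff.alpha,
        aff.p_max,
    )
    # MHC grooves bind peptides promiscuously: lower loading threshold
    aff_mhc = AffinityParams(
        aff.l, cfg["shape_space"].get("d_min_mhc", aff.d_min), aff.alpha, aff.p_max
    )
    p_prime = cfg["p_prime"]
    pamp_free = cfg["pamp_free_uptake_factor"]
    il10_k = cfg["il10_inhibition"]
    inter = cfg["interaction"]
    expan = cfg["expansion"]

    # --- rule 1: aspecific APC uptake of antigen (TLR-PAMP coupling) ------
    def uptake_actors(agents):
        return [
            a for a in agents
            if a.cell_type in _PROFESSIONAL_APC
            and a.state in (CellState.RESTING, CellState.ACTIVE)
        ]

    def uptake_p(actor, unit, state, site):
        p = p_prime if unit.antigen.pamp else p_prime * pamp_free
        if actor.cell_type is CellType.MAC:
            il10 = state.fields["IL10"].conc[site]
            p /= 1.0 + il10_k * il10  # IL-10 inhibits macrophages
        return p

    def uptake_effects(actor, unit, state, site, rng):
        ag = unit.antigen
        if actor.cell_type is CellType.MONO:
            if actor.state is CellState.RESTING:
                actor.set_state(CellState.ACTIVE)
            return
        complex_ii = process_and_present(actor, ag, "ENDOCYTIC", aff_mhc, rng)
        if complex_ii is not None:
            actor.complex = complex_ii
            actor.antigen_id = ag.antigen_id
            actor.set_state(CellState.PRESENTING_II)
            return
        if (
            actor.cell_type is CellType.DC
            and rng.random() < inter["cross_present_p"]
        ):
            complex_i = process_and_present(actor, ag, "CYTOSOLIC", aff_mhc, rng)
            if complex_i is not None:
                actor.complex = complex_i
                actor.antigen_id = ag.antigen_id
                actor.set_state(CellState.PRESENTING_I)
                return
        if actor.cell_type is CellType.MAC and actor.state is CellState.RESTING:
            actor.set_state(CellState.ACTIVE)

    # --- rule 2: specific T-helper priming by presenting APCs -------------
    def th_actors(agents):
        return [
            a for a in agents
            if a.cell_type in (CellType.TH1, CellType.TH2)
            and a.state in (CellState.RESTING, CellState.MEMORY)
        ]

    def presenting_partners(state, site):
        return [
            a for a in state.site_agents(CompartmentId.SECONDARY_ORGAN, site)
            if a.state is CellState.PRESENTING_II and a.complex is not None
        ]

    def _bystander_bonus(state, site):
        # optional activation bonus near clusters of ACTIVE cells (default 0)
        bonus = inter["bystander_bonus"]
        if bonus <= 0:
            return 0.0
        n_active = sum(
            1 for a in state.site_agents(CompartmentId.SECONDARY_ORGAN, site)
            if a.state is CellState.ACTIVE
        )
        return bonus if n_active >= inter["bystander_k"] else 0.0

    def th_prime_p(actor, partner, state, site):
        params = aff_memory if actor.state is CellState.MEMORY else aff
        p = binding_probability(actor.receptor, partner.complex, params)
        if p > 0:
            p = min(1.0, p + _bystander_bonus(state, site))
        return p

    def th_prime_effects(actor, partner, state, site, rng):
        actor.antigen_id = partner.antigen_id
        actor.divisions_remaining = expan["t_divisions"]
        actor.set_state(CellState.ACTIVE)

    # --- rule 3: specific B-cell recognition of antigen -------------------
    def b_actors(agents):
        # naive cells (never divided) start a response; ACTIVE cells that
        # failed to form a complex retry while antigen lasts; recall goes
        # through MEMORY cells only -- spent post-burst cells stay out
        return [
            a for a in agents
            if a.cell_type is CellType.B
            and (
                (a.state in (CellState.RESTING, CellState.ACTIVE)
                 and a.duplication_count == 0)
                or a.state is CellState.MEMORY
            )
        ]

    def b_bind_p(actor, unit, state, site):
        params = aff_memory if actor.state is CellState.MEMORY else aff
        p = binding_probability(actor.receptor, unit.antigen.b_epitope, params)
        if p > 0:
            p = min(1.0, p + _bystander_bonus(state, site))
        return p

    def b_bind_effects(actor, unit, state, site, rng):
        ag = unit.antigen
        actor.antigen_id = ag.antigen_id
        if actor.state is CellState.MEMORY:
            # recall needs an inflamed context (an engaged professional APC
            # at the site) but no fresh cognate licensing; otherwise the
            # cell stays memory and can retry while antigen persists
            if _has_costim(state, site):
                actor.divisions_remaining = expan["b_divisions"]
                actor.set_state(CellState.DUPLICATING)
            return
        if actor.state is CellState.RESTING:
            if not ag.pamp and not _has_costim(state, site):
                # self-like antigen signal without danger or co-stimulation
                actor.set_state(CellState.ANERGIC)
                return
            actor.set_state(CellState.ACTIVE)
        complex_ii = process_and_present(actor, ag, "ENDOCYTIC", aff_mhc, rng)
        if complex_ii is not None:
            actor.complex = complex_ii
            actor.set_state(CellState.PRESENTING_II)

    # --- rule 4: cognate T help licenses B-cell expansion -----------------
    def b_presenting_actors(agents):
        return [
            a for a in agents
            if a.cell_type is CellType.B and a.state is CellState.PRESENTING_II
        ]

    def active_th_partners(state, site):
        return [
            a for a in state.site_agents(CompartmentId.SECONDARY_ORGAN, site)
            if a.cell_type in (CellType.TH1, CellType.TH2)
            and a.state in (CellState.ACTIVE, CellState.DUPLICATING)
        ]

    def help_p(actor, partner, state, site):
        # linked recognition: help requires matched antigen identity
        if partner.antigen_id != actor.antigen_id:
            return 0.0
        return inter["th_help_p"]

    def help_effects(actor, partner, state, site, rng):
        actor.divisions_remaining = expan["b_divisions"]
        actor.set_state(CellState.DUPLICATING)
        il4 = state.fields["IL4"].conc[site]
        isotype_switch(actor, il4, inter["il4_switch_threshold"])

    # --- rule 5: specific cytotoxic T priming (cytosolic pathway) ---------
    def tc_actors(agents):
        return [
            a for a in agents
            if a.cell_type is CellType.TC and a.state is CellState.RESTING
        ]

    def presenting_i_partners(state, site):
        return [
            a for a in state.site_agents(CompartmentId.SECONDARY_ORGAN, site)
            if a.state is CellState.PRESENTING_I and a.complex is not None
        ]

    def tc_prime_p(actor, partner, state, site):
        return binding_probability(actor.receptor, partner.complex, aff)

    def tc_prime_effects(actor, partner, state, site, rng):
        actor.antigen_id = partner.antigen_id
        actor.divisions_remaining = expan["t_divisions"]
        actor.set_state(CellState.ACTIVE)

    return [
        InteractionRule(
            "apc_uptake", "ASPECIFIC", "antigen", uptake_actors,
            _antigen_partners, uptake_p, uptake_effects, consumes_partner=True,
        ),
        InteractionRule(
            "th_priming", "SPECIFIC", "cell", th_actors,
            presenting_partners, th_prime_p, th_prime_effects,
        ),
        InteractionRule(
            "b_recognition", "SPECIFIC", "antigen", b_actors,
            _antigen_partners, b_bind_p, b_bind_effects, consumes_partner=True,
        ),
        InteractionRule(
            "t_help", "ASPECIFIC", "cell", b_presenting_actors,
            active_th_partners, help_p, help_effects,
        ),
        InteractionRule(
            "tc_priming", "SPECIFIC", "cell", tc_actors,
            presenting_i_partners, tc_prime_p, tc_prime_effects,
        ),
    ]


# --------------------------------------------------------------------------
# Cell creation
# --------------------------------------------------------------------------

def _new_naive(
    cell_type: CellType,
    position: int,
    cfg: SimConfig,
    state: SimulationState,
    receptor: BitString | None,
) -> CellAgent:
    return CellAgent(
        cell_type=cell_type,
        position=position,
        state=CellState.RESTING,
        receptor=receptor,
        mhc_I=state.mhc_I,
        mhc_II=state.mhc_II if cell_type in APC_TYPES else (),
        half_life=cfg["half_lives"][cell_type.value],
        isotype=Isotype.IgM if cell_type is CellType.B else None,
    )


def haematopoiesis(state: SimulationState, cfg: SimConfig, rng: np.random.Generator) -> int:
    """Ornstein-Uhlenbeck homeostasis of every naive lineage.

    The OU target of each lineage is advanced one step; deficits are filled
    with fresh naive cells (new uniformly sampled receptors for
    lymphocytes) created in the bone marrow, surpluses remove the oldest
    naive cells first.  The spleen B-cell OU mean and, indirectly, thymic
    supply are the chemical's cellular targets.  Returns the number of cells
    created.
    """
    created = 0
    lymph = {CellType.B, CellType.TH1, CellType.TH2, CellType.TC}
    naive: dict[CellType, list[tuple[CompartmentId, CellAgent]]] = {
        ct: [] for ct in HAEMATOPOIETIC
    }
    totals: dict[CellType, int] = {ct: 0 for ct in HAEMATOPOIETIC}
    for comp in CompartmentId:
        for a in state.compartments[comp]:
            if a.cell_type not in naive:
                continue
            # homeostasis senses naive plus transient effectors (so responses
            # displace production instead of triggering runaway replacement)
            # but not the long-lived memory compartment
            if a.state is not CellState.MEMORY:
                totals[a.cell_type] += 1
            if a.state is CellState.RESTING and a.duplication_count == 0:
                naive[a.cell_type].append((comp, a))
    for ct in HAEMATOPOIETIC:
        params = state.lineage_params[ct]
        if ct is CellType.B:
            f = state.multiplier("B_POOL_MU")
            params = OUParams(params.mu * f, params.theta, params.sigma)
        target = ou_step(state.ou_targets.get(ct, params.mu), params, 1.0, rng)
        state.ou_targets[ct] = target
        current = totals[ct]
        if target > current:
            for _ in range(int(target - current)):
                receptor = (
                    sample_repertoire(1, cfg.l, rng)[0] if ct in lymph else None
                )
                state.add_agent(
                    CompartmentId.BONE_MARROW,
                    _new_naive(ct, 0, cfg, state, receptor),
                )
                created += 1
        elif target < current:
            doomed = sorted(naive[ct], key=lambda ca: (-ca[1].age, ca[1].uid))
            n_cull = min(int(current - target), len(doomed))
            for comp, a in doomed[:n_cull]:
                state.remove_agent(comp, a)
    return created


def _emigration(state: SimulationState, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Bone-marrow export and thymic education/export.

    New T-lineage cells go to the thymus, are educated on arrival (positive
    then negative selection; failures are deleted), and surviving thymocytes
    emigrate to the secondary organ at a rate the chemical can suppress
    (thymic atrophy).  Other lineages emigrate directly.
    """
    p_marrow = cfg["marrow"]["emigration_prob"]
    p_thymus = cfg["thymus"]["emigration_prob"] * state.multiplier("THYMIC_OUTPUT")
    n_sites = state.lattice.n_sites

    marrow = state.compartments[CompartmentId.BONE_MARROW]
    for a in list(marrow):
        if rng.random() >= p_marrow:
            continue
        state.remove_agent(CompartmentId.BONE_MARROW, a)
        if a.cell_type in T_LINEAGES:
            survivors = thymus_education(
                [a.receptor], state.mhc_II if a.cell_type is not CellType.TC
                else state.mhc_I,
                state.self_complexes, state.thresholds,
            )
            if survivors:
                state.add_agent(CompartmentId.THYMUS, a)
            # failed selection: deleted
        else:
            a.position = int(rng.integers(0, n_sites))
            state.add_agent(CompartmentId.SECONDARY_ORGAN, a)

    thymus = state.compartments[CompartmentId.THYMUS]
    for a in list(thymus):
        if rng.random() < p_thymus:
            state.remove_agent(CompartmentId.THYMUS, a)
            a.position = int(rng.integers(0, n_sites))
            state.add_agent(CompartmentId.SECONDARY_ORGAN, a)


# --------------------------------------------------------------------------
# Phases of one step
# --------------------------------------------------------------------------

def _update_exposure(state: SimulationState) -> None:
    if state.moa_map is None or not state.exposure.points:
        state.multipliers = {}
        return
    state.multipliers = apply_exposure(state.exposure, state.moa_map, state.t)


def _hot_sites(state: SimulationState) -> list[int]:
    sites: set[int] = set()
    for counts in state.antigen_counts.values():
        sites.update(np.flatnonzero(counts).tolist())
    for a in state.compartments[CompartmentId.SECONDARY_ORGAN]:
        if a.state not in (CellState.RESTING, CellState.MEMORY, CellState.ANERGIC):
            sites.add(a.position)
    return sorted(sites)


def _site_interactions(state, cfg, rng) -> None:
    state.invalidate_site_map()
    for site in _hot_sites(state):
        execute_site_interactions(site, state.rules, state, rng)


def _field_transitions(state, cfg, rng) -> None:
    """Cytokine-driven state changes outside the pairwise rule set."""
    inter = cfg["interaction"]
    antigen_present = any(int(c.sum()) > 0 for c in state.antigen_counts.values())
    il18 = state.fields["IL18"].conc
    il2 = state.fields["IL2"].conc
    il8 = state.fields["IL8"].conc
    il4 = state.fields["IL4"].conc
    mast_f = state.multiplier("MAST_GROWTH")
    for a in state.compartments[CompartmentId.SECONDARY_ORGAN]:
        ct, st = a.cell_type, a.state
        if ct is CellType.NK:
            if st is CellState.RESTING and il18[a.position] >= inter["il18_nk_threshold"]:
                a.set_state(CellState.ACTIVE)
            elif st is CellState.ACTIVE and il18[a.position] < inter["il18_nk_threshold"]:
                a.set_state(CellState.RESTING)
        elif ct is CellType.TREG:
            if st is CellState.RESTING and il2[a.position] >= inter["il2_treg_threshold"]:
                a.set_state(CellState.ACTIVE)
            elif st is CellState.ACTIVE and il2[a.position] < inter["il2_treg_threshold"]:
                a.set_state(CellState.RESTING)
        elif ct is CellType.NEU:
            if st is CellState.RESTING and il8[a.position] >= inter["il8_neu_threshold"]:
                a.set_state(CellState.ACTIVE)
            elif st is CellState.ACTIVE and il8[a.position] < inter["il8_neu_threshold"]:
                a.set_state(CellState.RESTING)
        elif ct is CellType.MAST:
            if st is CellState.RESTING:
                p = min(1.0, inter["mast_growth_rate"] * il4[a.position]) * mast_f
                if p > 0 and rng.random() < p:
                    a.divisions_remaining = 1
                    a.set_state(CellState.DUPLICATING)
        elif ct in (CellType.MAC, CellType.DC) and st in (
            CellState.PRESENTING_II, CellState.PRESENTING_I
        ):
            if rng.random() < inter["presentation_stop_p"]:
                a.complex = None
                a.set_state(CellState.RESTING)
        elif (
            ct in (CellType.TH1, CellType.TH2, CellType.TC, CellType.MAC,
                   CellType.MONO)
            and st is CellState.ACTIVE
            and not antigen_present
        ):
            if rng.random() < inter["effector_rest_p"]:
                a.set_state(CellState.RESTING)


def _clonal_expansion_phase(state, cfg, rng) -> None:
    expan = cfg["expansion"]
    hayflick = cfg["hayflick_limit"]
    il4_thr = cfg["interaction"]["il4_switch_threshold"]
    il4 = state.fields["IL4"].conc
    comp = state.compartments[CompartmentId.SECONDARY_ORGAN]
    duplicating = [a for a in comp if a.state is CellState.DUPLICATING]
    if not duplicating:
        return
    divided: set[int] = set()
    born: list[CellAgent] = []
    for cell in duplicating:
        if cell.divisions_remaining > 0 and cell.duplication_count < hayflick:
            daughters = clonal_expansion(
                cell, hayflick, rng,
                hypermutation_prob=expan["hypermutation_prob"]
                if cell.cell_type is CellType.B else 0.0,
            )
            divided.add(cell.uid)
            for d in daughters:
                if d.cell_type is CellType.B:
                    isotype_switch(d, il4[d.position], il4_thr)
                if d.divisions_remaining == 0:
                    _differentiate(d, state, cfg, rng)
                born.append(d)
        else:
            _differentiate(cell, state, cfg, rng)
    if divided:
        comp[:] = [a for a in comp if a.uid not in divided]
    comp.extend(born)
    state.invalidate_site_map()


def _differentiate(cell: CellAgent, state, cfg, rng) -> None:
    """Exit from the DUPLICATING state at the end of an expansion burst."""
    expan = cfg["expansion"]
    if cell.cell_type is CellType.B:
        u = rng.random()
        if u < expan["plb_fraction"]:
            cell.cell_type = CellType.PLB
            cell.state = CellState.ACTIVE
            cell.half_life = cfg["half_lives"]["PLB"]
        elif u < expan["plb_fraction"] + expan["b_memory_fraction"]:
            cell.set_state(CellState.MEMORY)
            cell.half_life = (
                cfg["half_lives"]["B"] * expan["memory_half_life_mult"]
            )
        else:
            cell.set_state(CellState.RESTING)
    elif cell.cell_type is CellType.MAST:
        cell.set_state(CellState.RESTING)
    elif cell.cell_type in (CellType.TH1, CellType.TH2):
        if rng.random() < expan["t_memory_fraction"]:
            cell.set_state(CellState.MEMORY)
            cell.half_life = (
                cfg["half_lives"][cell.cell_type.value]
                * expan["memory_half_life_mult"]
            )
        else:
            cell.set_state(CellState.ACTIVE)
    else:  # TC
        cell.set_state(CellState.ACTIVE)


def _secretion_phase(state, cfg, rng) -> None:
    table = state.secretion_table
    for cell in state.compartments[CompartmentId.SECONDARY_ORGAN]:
        secrete(cell, state, table)
    _secrete_immunoglobulin(state, cfg)
    _neutralize_antigen(state, cfg, rng)
    # late IgG -> IgA switch in plasma cells
    rate = cfg["expansion"]["iga_switch_rate"]
    for cell in state.compartments[CompartmentId.SECONDARY_ORGAN]:
        if (
            cell.cell_type is CellType.PLB
            and cell.isotype is Isotype.IgG
            and rng.random() < rate
        ):
            cell.isotype = Isotype.IgA


def _neutralize_antigen(state, cfg, rng) -> None:
    """Antibody-mediated clearance: per-unit removal ``1 - exp(-k S)`` with
    ``S`` the binding-weighted specific immunoglobulin at the site."""
    k = cfg["antigen"]["clearance_rate"]
    aff = cfg.affinity
    for aid, counts in state.antigen_counts.items():
        total = int(counts.sum())
        if total == 0:
            continue
        epitope = state.antigens[aid].b_epitope
        S = np.zeros(state.lattice.n_sites)
        for (paratope, iso), conc in state.ig_pools.items():
            if paratope is None:
                continue
            p = binding_probability(
                BitString(aff.l, paratope), epitope, aff
            )
            if p > 0:
                S += p * conc
        if not S.any():
            continue
        p_clear = 1.0 - np.exp(-k * S)
        removed = rng.binomial(counts, p_clear)
        counts -= removed


def _batch_diffuse(columns: np.ndarray, lattice: Lattice, D: float) -> np.ndarray:
    """Vectorized conservative diffusion of many fields at once.

    ``columns`` has shape (n_sites, n_fields); equivalent to applying
    :func:`immunotox.lattice.diffuse_field` to each column.
    """
    if D == 0.0:
        return columns
    k = lattice.valid_counts[:, None]
    out = columns * (D / k)
    new = columns * (1.0 - D)
    table = lattice.neighbor_table
    for j in range(6):
        col = table[:, j]
        mask = col >= 0
        np.add.at(new, col[mask], out[mask])
    return new


def _fields_phase(state, cfg, rng) -> None:
    lat = state.lattice
    fld_cfg = cfg["fields"]
    species = list(state.fields)
    stack = np.column_stack([state.fields[sp].conc for sp in species])
    stack = _batch_diffuse(stack, lat, fld_cfg["diffusion"])
    stack *= 2.0 ** (-1.0 / fld_cfg["half_life"])
    for i, sp in enumerate(species):
        state.fields[sp].conc = stack[:, i]
    ig_cfg = cfg["immunoglobulin"]
    if state.ig_pools:
        keys = list(state.ig_pools)
        pools = np.column_stack([state.ig_pools[k] for k in keys])
        pools = _batch_diffuse(pools, lat, ig_cfg["diffusion"])
        pools *= 2.0 ** (-1.0 / ig_cfg["half_life"])
        for i, k in enumerate(keys):
            state.ig_pools[k] = pools[:, i]
    # antigen units: binomial thinning (decay) then per-unit random moves
    ag_cfg = cfg["antigen"]
    p_die = removal_probability(ag_cfg["half_life"])
    D = ag_cfg["diffusion"]
    for aid, counts in state.antigen_counts.items():
        if not counts.any():
            continue
        counts -= rng.binomial(counts, p_die)
        movers = rng.binomial(counts, D)
        if movers.any():
            counts -= movers
            for site in np.flatnonzero(movers):
                dest = rng.multinomial(movers[site], np.full(6, 1 / 6))
                row = lat.neighbor_table[site]
                for j in range(6):
                    if dest[j] and row[j] >= 0:
                        counts[row[j]] += dest[j]
                    elif dest[j]:  # hard wall: stay
                        counts[site] += dest[j]


def _agent_diffusion(state, cfg, rng) -> None:
    agents = state.compartments[CompartmentId.SECONDARY_ORGAN]
    if not agents:
        return
    positions = np.fromiter(
        (a.position for a in agents), dtype=np.int64, count=len(agents)
    )
    new = diffuse_agents(positions, state.lattice, rng)
    for a, p in zip(agents, new):
        a.position = int(p)
    state.invalidate_site_map()


def _lifecycle_phase(state, cfg, rng) -> None:
    for comp in CompartmentId:
        agents = state.compartments[comp]
        if not agents:
            continue
        hl = np.fromiter((a.half_life for a in agents), dtype=float, count=len(agents))
        die = rng.random(len(agents)) < (1.0 - 2.0 ** (-1.0 / hl))
        survivors = []
        for a, d in zip(agents, die):
            if d:
                continue
            a.age += 1
            survivors.append(a)
        state.compartments[comp] = survivors
    state.invalidate_site_map()


# --------------------------------------------------------------------------
# Initialization and the step function
# --------------------------------------------------------------------------

def initialize_state(
    config: SimConfig,
    rng: np.random.Generator,
    *,
    lineage_mus: dict[str, float] | None = None,
    thymic_output_scale: float = 1.0,
    cytokine_baselines: dict[str, float] | None = None,
    initial_igg: float = 0.0,
    exposure: ExposureProfile | None = None,
    moa_map: MoAMap | None = None,
) -> SimulationState:
    """Build and fill a simulation state before t = 0.

    Compartments are filled to the lineage OU means with naive cells
    (T cells are pre-educated against the drawn MHC strings and self
    peptides), cytokine fields start at the supplied baselines spread
    uniformly, and an optional pre-existing bulk IgG pool seeds the
    humoral compartment.
    """
    lat_cfg = config["lattice"]
    lattice = Lattice(
        Geometry(lat_cfg["geometry"]), lat_cfg["side"], Boundary(lat_cfg["boundary"])
    )
    l = config.l
    mhc_I = tuple(sample_repertoire(2, l, rng))
    mhc_II = tuple(sample_repertoire(2, l, rng))
    self_peptides = tuple(
        sample_repertoire(config["thymus"]["n_self_peptides"], l, rng)
    )
    self_complexes = tuple(
        mhc_peptide_complex(m, p)
        for m in (mhc_I + mhc_II)
        for p in self_peptides
    )
    thresholds = ThymusThresholds(
        config["thymus"]["theta_pos"], config["thymus"]["theta_neg"], self_peptides
    )
    lineage_params = {}
    for ct in HAEMATOPOIETIC:
        base = config["lineages"][ct.value]
        mu = float(lineage_mus.get(ct.value, base["mu"])) if lineage_mus else base["mu"]
        lineage_params[ct] = OUParams(mu, base["theta"], base["sigma"])

    state = SimulationState(
        config=config,
        lattice=lattice,
        rng=rng,
        mhc_I=mhc_I,
        mhc_II=mhc_II,
        self_complexes=self_complexes,
        thresholds=thresholds,
        lineage_params=lineage_params,
        exposure=exposure or ExposureProfile.none(),
        moa_map=moa_map,
        compartments={comp: [] for comp in CompartmentId},
    )
    state.thymic_output_scale = thymic_output_scale
    fld = config["fields"]
    n = lattice.n_sites
    baselines = cytokine_baselines or {}
    for sp in CYTOKINES:
        conc = np.full(n, baselines.get(sp, 0.0) / n)
        state.fields[sp] = MolecularField(
            sp, conc, fld["diffusion"], fld["half_life"]
        )
    if initial_igg > 0:
        state.ig_pools[(None, Isotype.IgG)] = np.full(n, initial_igg / n)

    # secretion lookup table
    table: dict[tuple[CellType, CellState], dict[str, float]] = {}
    for key, rates in config["secretion"].items():
        tname, sname = key.split(".")
        table[(CellType[tname], CellState[sname])] = dict(rates)
    state.secretion_table = table
    state.rules = default_rules(config)

    # fill compartments to the OU means
    lymph_t = set(T_LINEAGES)
    for ct, params in lineage_params.items():
        want = int(round(params.mu))
        placed = 0
        attempts = 0
        while placed < want and attempts < 20 * max(want, 1):
            attempts += 1
            receptor = None
            if ct in (CellType.B, *T_LINEAGES):
                receptor = sample_repertoire(1, l, rng)[0]
            if ct in lymph_t:
                mhc_set = mhc_I if ct is CellType.TC else mhc_II
                if not thymus_education(
                    [receptor], mhc_set, self_complexes, thresholds
                ):
                    continue
            agent = _new_naive(ct, int(rng.integers(0, n)), config, state, receptor)
            state.add_agent(CompartmentId.SECONDARY_ORGAN, agent)
            placed += 1
        state.ou_targets[ct] = float(want)

    state.initialized = True
    return state


def step_world(
    state: SimulationState, config: SimConfig, rng: np.random.Generator
) -> SimulationState:
    """Advance the world by one time step (see module docstring for the
    frozen phase order).  Mutates and returns ``state``."""
    if not state.initialized:
        raise RuntimeError("step_world called on an uninitialized state")
    _update_exposure(state)
    # patient-level thymic scaling combines with chemical suppression
    scale = state.thymic_output_scale
    if scale != 1.0:
        key = ("THYMIC_OUTPUT", None)
        state.multipliers[key] = state.multipliers.get(key, 1.0) * scale
    haematopoiesis(state, config, rng)
    _emigration(state, config, rng)
    _site_interactions(state, config, rng)
    _field_transitions(state, config, rng)
    _clonal_expansion_phase(state, config, rng)
    _secretion_phase(state, config, rng)
    _fields_phase(state, config, rng)
    _agent_diffusion(state, config, rng)
    _lifecycle_phase(state, config, rng)
    state.t += 1
    return state
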