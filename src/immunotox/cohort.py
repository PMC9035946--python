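"""Virtual-patient synthesis.

A virtual patient is the 26-entry personalization vector (exposure level,
baseline cell pools, baseline cytokine levels, demographics, and the
disease-model / vaccination / mechanism-of-action references) plus two HLA
haplotype pairs and a private random seed.  Cohorts are generated from a
population spec: per-feature marginals with bounds, and an acyclic set of
dependency rules so that biologically linked features (e.g. BMI given age,
naive T-cell pools declining with age) remain jointly plausible.

The printed feature list carries IL10 twice; the schema keeps both entries
(``IL10`` and ``IL10_b``) aliased to one underlying value.  The first entry
names the serum PFAS level and accepts either chemical id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .shape_space import BitString, sample_repertoire

__all__ = [
    "FEATURE_SCHEMA",
    "Marginal",
    "Dependency",
    "PopulationSpec",
    "VirtualPatient",
    "adult_population_spec",
    "child_population_spec",
    "default_hla_pool",
    "sample_hla",
    "sample_patient",
    "generate_cohort",
    "validate_patient",
]

#: The 26 personalization-vector entries, in printed order.  ``IL10_b``
#: aliases ``IL10``; ``DiseaseModel``, ``VC`` and ``MoA`` are categorical
#: configuration references, not sampled numerics.
FEATURE_SCHEMA: tuple[str, ...] = (
    "PFOA", "Th1", "Th2", "M", "DC", "IgG", "TC",
    "IL1", "IL2", "IL10", "IL12", "IL17A", "IL23",
    "IFN1A", "IFN1B", "IFNG", "TNF", "VitaminD", "Treg",
    "IL10_b", "TGFB", "Age", "BMI", "DiseaseModel", "VC", "MoA",
)

CATEGORICAL_FEATURES = frozenset({"DiseaseModel", "VC", "MoA"})

#: Population-typical values used to scale engine parameters per patient.
TYPICAL = {
    "Th1": 60.0, "Th2": 60.0, "M": 40.0, "DC": 30.0, "TC": 60.0,
    "Treg": 20.0, "IgG": 50.0,
}


@dataclass(frozen=True)
class Marginal:
    """One feature's marginal: family, location, scale and hard bounds."""

    dist: str  # "truncnorm" | "lognorm" | "uniform" | "const"
    loc: float = 0.0
    scale: float = 0.0
    low: float = -math.inf
    high: float = math.inf

    def sample(self, rng: np.random.Generator, loc_shift: float = 0.0) -> float:
        loc = self.loc + loc_shift
        if self.dist == "const":
            return loc
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        for _ in range(100):
            if self.dist == "truncnorm":
                x = loc + self.scale * rng.standard_normal()
            elif self.dist == "lognorm":
                x = math.exp(math.log(max(loc, 1e-12)) + self.scale * rng.standard_normal())
            else:
                raise ValueError(f"unknown distribution family {self.dist!r}")
            if self.low <= x <= self.high:
                return float(x)
        raise RuntimeError(
            f"could not sample within bounds [{self.low}, {self.high}] "
            f"after 100 attempts ({self.dist}, loc={loc}, scale={self.scale})"
        )


@dataclass(frozen=True)
class Dependency:
    """Linear location shift: feature's loc moves by slope*(parent - ref)."""

    feature: str
    parent: str
    slope: float
    ref: float = 0.0


@dataclass
class PopulationSpec:
    """Marginals plus dependency rules for one population."""

    name: str
    marginals: dict[str, Marginal]
    dependencies: tuple[Dependency, ...] = ()
    categorical: dict[str, str] = field(default_factory=dict)
    hla_pool: tuple[BitString, ...] = ()
    age_range: tuple[float, float] = (18.0, 60.0)
    thymic_age_slope: float = 0.015  # thymic output ~ 1.6 - slope * age

    def __post_init__(self) -> None:
        numeric = [f for f in FEATURE_SCHEMA if f not in CATEGORICAL_FEATURES]
        missing = [f for f in numeric if f != "IL10_b" and f not in self.marginals]
        if missing:
            raise ValueError(f"population spec lacks marginals for {missing}")
        # dependency graph must be acyclic (parents sampled first)
        order = self.sampling_order()
        if len(order) != len(self.marginals):
            raise ValueError("dependency graph has a cycle")

    def sampling_order(self) -> list[str]:
        deps = {d.feature: d.parent for d in self.dependencies}
        order: list[str] = []
        seen: set[str] = set()

        def visit(f: str, stack: set[str]) -> None:
            if f in seen:
                return
            if f in stack:
                raise ValueError(f"dependency cycle at {f}")
            if f in deps:
                visit(deps[f], stack | {f})
            seen.add(f)
            order.append(f)

        for f in self.marginals:
            visit(f, set())
        return order

    def thymic_output_scale(self, age: float) -> float:
        return float(np.clip(1.6 - self.thymic_age_slope * age, 0.5, 2.0))


@dataclass
class VirtualPatient:
    """One digital twin: the feature vector, HLA haplotypes and a seed."""

    features: dict[str, float | str]
    hla_I: tuple[BitString, BitString]
    hla_II: tuple[BitString, BitString]
    seed: int
    population: str = "adult"

    def __getitem__(self, key: str):
        return self.features[key]

    def to_row(self) -> dict:
        row = dict(self.features)
        row["seed"] = self.seed
        row["hla_I"] = ";".join(str(h) for h in self.hla_I)
        row["hla_II"] = ";".join(str(h) for h in self.hla_II)
        return row


def _base_marginals() -> dict[str, Marginal]:
    cyto = Marginal("truncnorm", 1.0, 0.3, 0.0, 5.0)
    m = {
        "PFOA": Marginal("lognorm", 2.0, 0.6, 0.05, 50.0),
        "Th1": Marginal("truncnorm", 60.0, 10.0, 20.0, 120.0),
        "Th2": Marginal("truncnorm", 60.0, 10.0, 20.0, 120.0),
        "M": Marginal("truncnorm", 40.0, 8.0, 10.0, 80.0),
        "DC": Marginal("truncnorm", 30.0, 6.0, 10.0, 60.0),
        "IgG": Marginal("truncnorm", 50.0, 15.0, 0.0, 200.0),
        "TC": Marginal("truncnorm", 60.0, 10.0, 20.0, 120.0),
        "VitaminD": Marginal("truncnorm", 30.0, 8.0, 10.0, 60.0),
        "Treg": Marginal("truncnorm", 20.0, 4.0, 5.0, 40.0),
    }
    for sp in ("IL1", "IL2", "IL10", "IL12", "IL17A", "IL23",
               "IFN1A", "IFN1B", "IFNG", "TNF", "TGFB"):
        m[sp] = cyto
    return m


def adult_population_spec() -> PopulationSpec:
    """Healthy adults, ages 18-60."""
    marginals = _base_marginals()
    marginals["Age"] = Marginal("uniform", low=18.0, high=60.0)
    marginals["BMI"] = Marginal("truncnorm", 25.0, 4.0, 16.0, 45.0)
    return PopulationSpec(
        name="adult",
        marginals=marginals,
        dependencies=(
            Dependency("BMI", "Age", slope=0.08, ref=40.0),
            Dependency("Th1", "Age", slope=-0.25, ref=40.0),
            Dependency("Th2", "Age", slope=-0.25, ref=40.0),
            Dependency("TC", "Age", slope=-0.25, ref=40.0),
        ),
        categorical={"DiseaseModel": "generic-pathogen", "VC": "two-dose",
                     "MoA": "PFAS-default"},
        hla_pool=default_hla_pool(),
        age_range=(18.0, 60.0),
    )


def child_population_spec() -> PopulationSpec:
    """Children around age 5 (routine-immunization cohort).

    Naive pools are slightly larger and thymic output higher than in
    adults, reflecting age-dependent involution; everything else matches
    the adult spec.
    """
    marginals = _base_marginals()
    marginals["Age"] = Marginal("truncnorm", 5.0, 0.3, 4.0, 6.0)
    marginals["BMI"] = Marginal("truncnorm", 15.5, 1.5, 11.0, 22.0)
    marginals["IgG"] = Marginal("truncnorm", 35.0, 10.0, 0.0, 150.0)
    return PopulationSpec(
        name="child",
        marginals=marginals,
        dependencies=(
            Dependency("Th1", "Age", slope=-0.25, ref=40.0),
            Dependency("Th2", "Age", slope=-0.25, ref=40.0),
            Dependency("TC", "Age", slope=-0.25, ref=40.0),
        ),
        categorical={"DiseaseModel": "generic-pathogen", "VC": "two-dose",
                     "MoA": "PFAS-default"},
        hla_pool=default_hla_pool(),
        age_range=(4.0, 6.0),
    )


def default_hla_pool(l: int = 12, size: int = 16) -> tuple[BitString, ...]:
    """A fixed pool of synthetic HLA haplotype bit-strings.

    These are stand-ins drawn once from a frozen seed; no real allele
    identities or population frequencies are claimed.
    """
    rng = np.random.default_rng(190711)
    return tuple(sample_repertoire(size, l, rng))


def sample_hla(
    pool: tuple[BitString, ...], rng: np.random.Generator
) -> tuple[tuple[BitString, BitString], tuple[BitString, BitString]]:
    """Draw class-I and class-II haplotype pairs uniformly with replacement."""
    if not pool:
        raise ValueError("HLA allele pool is empty")
    idx = rng.integers(0, len(pool), size=4)
    return (pool[idx[0]], pool[idx[1]]), (pool[idx[2]], pool[idx[3]])


def sample_patient(
    spec: PopulationSpec, rng: np.random.Generator, seed: int | None = None
) -> VirtualPatient:
    """Draw one virtual patient: features in dependency order, then HLA."""
    dep_by_feature = {d.feature: d for d in spec.dependencies}
    values: dict[str, float | str] = {}
    for feature in spec.sampling_order():
        marg = spec.marginals[feature]
        shift = 0.0
        if feature in dep_by_feature:
            d = dep_by_feature[feature]
            shift = d.slope * (float(values[d.parent]) - d.ref)
        values[feature] = marg.sample(rng, shift)
    values["IL10_b"] = values["IL10"]  # printed twice; one underlying value
    for feature in CATEGORICAL_FEATURES:
        values[feature] = spec.categorical.get(feature, "default")
    hla_I, hla_II = sample_hla(spec.hla_pool, rng)
    if seed is None:
        seed = int(rng.integers(0, 2**31))
    ordered = {f: values[f] for f in FEATURE_SCHEMA}
    return VirtualPatient(ordered, hla_I, hla_II, seed, spec.name)


def generate_cohort(
    n: int, spec: PopulationSpec, master_seed: int
) -> list[VirtualPatient]:
    """``n`` mutually independent patients, reproducible from one seed.

    Per-patient seeds are split off the master seed with a dedicated
    generator, so two calls with the same master seed produce byte-identical
    cohorts and patients can be simulated independently (common random
    numbers across paired arms come from re-using the same cohort).
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31, size=n) if n else []
    return [sample_patient(spec, rng, seed=int(s)) for s in seeds]


def validate_patient(p: VirtualPatient, spec: PopulationSpec) -> list[str]:
    """Schema and bound violations; an empty list means the patient is valid."""
    violations: list[str] = []
    for feature in FEATURE_SCHEMA:
        if feature not in p.features:
            violations.append(f"missing feature {feature}")
    extra = set(p.features) - set(FEATURE_SCHEMA)
    for feature in sorted(extra):
        violations.append(f"unknown feature {feature}")
    for feature, marg in spec.marginals.items():
        if feature not in p.features:
            continue
        v = p.features[feature]
        if not isinstance(v, (int, float)):
            violations.append(f"{feature}: non-numeric value {v!r}")
        elif not (marg.low <= v <= marg.high):
            violations.append(
                f"{feature}: value {v} outside [{marg.low}, {marg.high}]"
            )
    if "Age" in p.features and isinstance(p.features["Age"], (int, float)):
        lo, hi = spec.age_range
        if not (lo <= p.features["Age"] <= hi):
            violations.append(f"Age: value {p.features['Age']} outside [{lo}, {hi}]")
    if "IL10" in p.features and p.features.get("IL10_b") != p.features["IL10"]:
        violations.append("IL10_b: does not alias IL10")
    return violations
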