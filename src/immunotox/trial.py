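"""In silico trial orchestration and analytics.

A trial runs a schedule of antigen injections (bacterial challenges or
vaccine doses, injected into the secondary lymphoid organ) over every
patient of a cohort, applying a serum-exposure profile each step, and
collects per-patient time series plus an endpoint table of antigen-specific
antibody titers.  Analytics cover population averages, quartile splits by
exposure, rank exposure-response correlation, the percent effect of a
2-fold exposure difference, calibration of the shared maximal suppression
against a target effect size, and benchmark-dose search.

Exposed-vs-unexposed contrasts re-use one cohort (identical per-patient
seeds), so arms differ only through the chemical's effect (common random
numbers).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine as eng
from .cohort import TYPICAL, VirtualPatient
from .config import SimConfig, default_config
from .entities import Antigen, CellType, CompartmentId, CYTOKINES, Isotype
from .shape_space import sample_repertoire
from .tox import ExposureProfile, MoAMap, moa_map_from_config

__all__ = [
    "ScheduleEvent",
    "Schedule",
    "TimeSeries",
    "TrialResult",
    "antigen_from_id",
    "run_simulation",
    "run_trial",
    "population_average",
    "quartile_split",
    "exposure_response_correlation",
    "fold_change_effect",
    "calibrate_moa",
    "CalibrationReport",
    "benchmark_dose",
    "load_study",
    "write_trial_outputs",
]

EVENT_TYPES = ("BACTERIAL_CHALLENGE", "VACCINE_DOSE")


@dataclass(frozen=True)
class ScheduleEvent:
    day: float
    event_type: str
    antigen_id: str
    dose: int = 2000
    pamp: bool = True

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class Schedule:
    events: tuple[ScheduleEvent, ...]
    duration_days: float
    sampling_day: float | None = None
    endpoint_antigen: str | None = None

    def __post_init__(self) -> None:
        for ev in self.events:
            if not (0 <= ev.day <= self.duration_days):
                raise ValueError(
                    f"event at day {ev.day} outside duration {self.duration_days}"
                )
        if self.sampling_day is not None and self.sampling_day > self.duration_days:
            raise ValueError("sampling day beyond trial duration")

    def antigen_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ev in self.events:
            if ev.antigen_id not in seen:
                seen.append(ev.antigen_id)
        return tuple(seen)

    def endpoint_id(self) -> str:
        if self.endpoint_antigen is not None:
            return self.endpoint_antigen
        if not self.events:
            raise ValueError("schedule has no events and no endpoint antigen")
        return self.events[-1].antigen_id


@dataclass
class TimeSeries:
    """Per-step records of one patient's run."""

    data: dict[str, np.ndarray]
    steps_per_day: int
    seed: int
    patient_id: str

    def __len__(self) -> int:
        return len(next(iter(self.data.values())))

    def days(self) -> np.ndarray:
        return np.arange(len(self)) / self.steps_per_day


@dataclass
class TrialResult:
    series: list[TimeSeries]
    endpoints: pd.DataFrame
    manifest: dict


def antigen_from_id(antigen_id: str, l: int, pamp: bool = True) -> Antigen:
    """Deterministic antigen bit-strings for a named antigen.

    The epitope and three peptides are drawn from a generator seeded by a
    CRC of the antigen id, so 'diphtheria' is the same molecule in every
    run and distinct ids give distinct specificities.
    """
    rng = np.random.default_rng(zlib.crc32(antigen_id.encode()))
    strings = sample_repertoire(4, l, rng)
    return Antigen(antigen_id, strings[0], tuple(strings[1:]), pamp=pamp)


def _patient_engine_kwargs(patient: VirtualPatient, cfg: SimConfig) -> dict:
    """Map the personalization vector onto engine parameters."""
    mus: dict[str, float] = {}
    base = cfg["lineages"]
    feature_to_lineage = {
        "Th1": "TH1", "Th2": "TH2", "M": "MAC", "DC": "DC",
        "TC": "TC", "Treg": "TREG",
    }
    for feat, lineage in feature_to_lineage.items():
        ratio = float(patient[feat]) / TYPICAL[feat]
        mus[lineage] = base[lineage]["mu"] * float(np.clip(ratio, 0.25, 2.5))
    baselines = {}
    feature_to_species = {
        "IL1": "IL1", "IL2": "IL2", "IL10": "IL10", "IL12": "IL12",
        "IL17A": "IL17", "IL23": "IL23", "IFN1A": "IFNA1", "IFN1B": "IFNB1",
        "IFNG": "IFNG", "TNF": "TNFA", "TGFB": "TGFB",
    }
    for feat, sp in feature_to_species.items():
        baselines[sp] = 10.0 * float(patient[feat])
    age = float(patient["Age"])
    scale = float(np.clip(1.6 - 0.015 * age, 0.5, 2.0))
    return {
        "lineage_mus": mus,
        "cytokine_baselines": baselines,
        "initial_igg": float(patient["IgG"]),
        "thymic_output_scale": scale,
    }


def run_simulation(
    patient: VirtualPatient,
    schedule: Schedule,
    exposure: ExposureProfile | None,
    config: SimConfig | None = None,
    moa_map: MoAMap | None = None,
) -> TimeSeries:
    """Simulate one patient through a schedule under an exposure profile.

    ``exposure=None`` uses a constant profile at the patient's own serum
    PFAS feature.  The run is a deterministic function of the patient (its
    seed included), the schedule, the exposure and the config.
    """
    cfg = config or default_config()
    if exposure is None:
        exposure = ExposureProfile.constant(float(patient["PFOA"]))
    if moa_map is None:
        moa_map = moa_map_from_config(cfg)
    rng = np.random.default_rng(patient.seed)
    state = eng.initialize_state(
        cfg, rng, exposure=exposure, moa_map=moa_map,
        **_patient_engine_kwargs(patient, cfg),
    )
    antigens = {
        aid: antigen_from_id(aid, cfg.l) for aid in schedule.antigen_ids()
    }
    inject_at: dict[int, list[ScheduleEvent]] = {}
    for ev in schedule.events:
        inject_at.setdefault(cfg.day_to_step(ev.day), []).append(ev)
    n_steps = cfg.day_to_step(schedule.duration_days)

    records: dict[str, list[float]] = {}

    def record() -> None:
        counts = state.count_by_type()
        for ct in CellType:
            records.setdefault(f"count_{ct.value}", []).append(counts[ct])
        for sp in CYTOKINES:
            records.setdefault(f"cytokine_{sp}", []).append(
                state.fields[sp].total()
            )
        totals, specific = state.ig_summary(list(antigens))
        for aid in antigens:
            arr = state.antigen_counts.get(aid)
            records.setdefault(f"antigen_{aid}", []).append(
                float(arr.sum()) if arr is not None else 0.0
            )
            for iso in Isotype:
                records.setdefault(f"ig_{iso.value}_{aid}", []).append(
                    specific[(aid, iso)]
                )
        for iso in Isotype:
            records.setdefault(f"ig_{iso.value}_total", []).append(totals[iso])

    def inject(step: int) -> None:
        for ev in inject_at.get(step, ()):
            ag = replace(antigens[ev.antigen_id], pamp=ev.pamp)
            antigens[ev.antigen_id] = ag
            state.inject_antigen(ag, ev.dose)

    # an event scheduled at step s is visible in the records at index s
    inject(0)
    record()
    for t in range(1, n_steps + 1):
        inject(t)
        eng.step_world(state, cfg, rng)
        record()

    data = {k: np.asarray(v) for k, v in records.items()}
    pid = f"{patient.population}-{patient.seed}"
    return TimeSeries(data, cfg.steps_per_day, patient.seed, pid)


def _endpoint_row(
    patient: VirtualPatient,
    ts: TimeSeries,
    schedule: Schedule,
    exposure: ExposureProfile | None,
    cfg: SimConfig,
) -> dict:
    aid = schedule.endpoint_id()
    if exposure is None:
        exp_level = float(patient["PFOA"])
    else:
        from .tox import serum_concentration

        t_ref = (
            cfg.day_to_step(schedule.sampling_day)
            if schedule.sampling_day is not None
            else cfg.day_to_step(schedule.duration_days)
        )
        exp_level = serum_concentration(exposure, t_ref)
    row = {"patient_id": ts.patient_id, "seed": ts.seed, "exposure": exp_level}
    for iso in Isotype:
        series = ts.data[f"ig_{iso.value}_{aid}"]
        row[f"peak_{iso.value}"] = float(series.max())
        if schedule.sampling_day is not None:
            row[f"endpoint_{iso.value}"] = float(
                series[cfg.day_to_step(schedule.sampling_day)]
            )
        else:
            row[f"endpoint_{iso.value}"] = float(series.max())
    return row


def run_trial(
    cohort: list[VirtualPatient],
    schedule: Schedule,
    exposure: ExposureProfile | None,
    config: SimConfig | None = None,
    moa_map: MoAMap | None = None,
    keep_series: bool = True,
) -> TrialResult:
    """Run every patient of a cohort and collect the endpoint table.

    The endpoint is the antigen-specific IgG (plus IgM/IgA) at the
    schedule's sampling day, or the peak when no sampling day is set.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    cfg = config or default_config()
    series: list[TimeSeries] = []
    rows: list[dict] = []
    for patient in cohort:
        ts = run_simulation(patient, schedule, exposure, cfg, moa_map)
        rows.append(_endpoint_row(patient, ts, schedule, exposure, cfg))
        if keep_series:
            series.append(ts)
    endpoints = pd.DataFrame(rows)
    manifest = {
        "n_patients": len(cohort),
        "config_hash": config_hash(cfg),
        "endpoint_antigen": schedule.endpoint_id(),
        "version": 1,
    }
    return TrialResult(series, endpoints, manifest)


def config_hash(cfg: SimConfig) -> str:
    blob = yaml.safe_dump(cfg.raw, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# Analytics
# --------------------------------------------------------------------------

def population_average(
    series: list[TimeSeries],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and standard deviation per tracked quantity."""
    if not series:
        raise ValueError("no series given")
    n = len(series[0])
    if any(len(s) != n for s in series):
        raise ValueError("series have unequal lengths")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for key in series[0].data:
        stack = np.stack([s.data[key] for s in series])
        out[key] = (stack.mean(axis=0), stack.std(axis=0))
    return out


def quartile_split(
    endpoints: pd.DataFrame, by: str = "exposure"
) -> list[pd.DataFrame]:
    """Sort by exposure and split into 4 contiguous groups.

    Group sizes are as equal as possible with the remainder assigned to the
    lowest quartiles; ties in exposure are broken by patient id.
    """
    n = len(endpoints)
    if n < 4:
        raise ValueError(f"need at least 4 patients for quartiles, got {n}")
    ordered = endpoints.sort_values(
        [by, "patient_id"], kind="mergesort"
    ).reset_index(drop=True)
    base, rem = divmod(n, 4)
    sizes = [base + 1 if i < rem else base for i in range(4)]
    groups, start = [], 0
    for s in sizes:
        groups.append(ordered.iloc[start : start + s])
        start += s
    return groups


def exposure_response_correlation(
    exposures: np.ndarray,
    titers: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float], bool]:
    """Spearman rank correlation with a seeded bootstrap percentile CI.

    Constant titers make the statistic degenerate; then (0.0, (0, 0), True)
    is returned with the degeneracy flagged.
    """
    from scipy import stats

    exposures = np.asarray(exposures, dtype=float)
    titers = np.asarray(titers, dtype=float)
    n = exposures.size
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    if np.ptp(exposures) == 0:
        raise ValueError("exposures are constant")
    if np.ptp(titers) == 0:
        return 0.0, (0.0, 0.0), True
    rho = float(stats.spearmanr(exposures, titers).statistic)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(titers[idx]) == 0 or np.ptp(exposures[idx]) == 0:
            boot[i] = 0.0
        else:
            boot[i] = stats.spearmanr(exposures[idx], titers[idx]).statistic
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return rho, (float(lo), float(hi)), False


def fold_change_effect(
    endpoints_ref: np.ndarray,
    endpoints_2x: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Percent difference of means, higher-exposure arm vs reference.

    ``100 * (mean(2x) - mean(ref)) / mean(ref)`` with a seeded BCa bootstrap
    CI; paired resampling when the arms share patients (equal length),
    otherwise independent two-sample resampling.
    """
    from scipy import stats

    ref = np.asarray(endpoints_ref, dtype=float)
    x2 = np.asarray(endpoints_2x, dtype=float)
    if ref.size == 0 or x2.size == 0:
        raise ValueError("endpoint sets must be non-empty")
    m_ref = ref.mean()
    if m_ref == 0:
        raise ZeroDivisionError("reference mean endpoint is zero; effect undefined")
    point = 100.0 * (x2.mean() - m_ref) / m_ref

    def effect(r, x):
        mr = r.mean()
        return 100.0 * (x.mean() - mr) / mr if mr else np.nan

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate resamples handled below
        res = stats.bootstrap(
            (ref, x2), effect,
            paired=ref.size == x2.size,
            vectorized=False,
            n_resamples=n_boot,
            method="BCa",
            rng=np.random.default_rng(seed),
        )
    ci = res.confidence_interval
    lo, hi = float(ci.low), float(ci.high)
    if not (np.isfinite(lo) and np.isfinite(hi)):  # e.g. identical arms
        lo = hi = point
    return float(point), (lo, hi)


# --------------------------------------------------------------------------
# Calibration and benchmark dose
# --------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    imax: float
    achieved_effect: float
    target_effect: float
    converged: bool
    iterations: int
    history: list[tuple[float, float]] = field(default_factory=list)


def calibrate_moa(
    target_effect: float,
    effect_fn,
    tol: float = 3.0,
    max_iter: int = 20,
) -> CalibrationReport:
    """Bisection on a shared maximal suppression Imax in [0, 1].

    ``effect_fn(imax)`` must return the simulated percent effect (<= 0,
    monotone non-increasing in Imax); the search stops when the effect is
    within ``tol`` percentage points of ``target_effect``.  A target more
    negative than the effect at Imax = 1 is reported as unconverged.
    """
    if target_effect > 0:
        raise ValueError("target effect must be <= 0 (suppression)")
    history: list[tuple[float, float]] = []
    if target_effect == 0.0:
        return CalibrationReport(0.0, 0.0, 0.0, True, 0, history)
    lo, hi = 0.0, 1.0
    f_hi = effect_fn(hi)
    history.append((hi, f_hi))
    if abs(f_hi - target_effect) <= tol:
        return CalibrationReport(hi, f_hi, target_effect, True, 1, history)
    if f_hi > target_effect:
        return CalibrationReport(hi, f_hi, target_effect, False, 1, history)
    mid, f_mid = hi, f_hi
    for it in range(2, max_iter + 1):
        mid = 0.5 * (lo + hi)
        f_mid = effect_fn(mid)
        history.append((mid, f_mid))
        if abs(f_mid - target_effect) <= tol:
            return CalibrationReport(mid, f_mid, target_effect, True, it, history)
        if f_mid > target_effect:  # too weak: need more suppression
            lo = mid
        else:
            hi = mid
    return CalibrationReport(mid, f_mid, target_effect, False, max_iter, history)


def make_fold_change_objective(
    cohort: list[VirtualPatient],
    schedule: Schedule,
    c0: float,
    config: SimConfig,
    chemical: str = "PFOA",
    isotype: str = "IgG",
):
    """Objective for calibration: the percent effect of doubling exposure.

    Runs paired-seed trials of one cohort at C0 and 2*C0 with a shared-Imax
    target map and returns the fold-change point estimate.
    """
    base_map = moa_map_from_config(config)

    def effect(imax: float) -> float:
        moa = base_map.with_shared_imax(imax)
        ref = run_trial(
            cohort, schedule, ExposureProfile.constant(c0, chemical),
            config, moa, keep_series=False,
        )
        hi = run_trial(
            cohort, schedule, ExposureProfile.constant(2 * c0, chemical),
            config, moa, keep_series=False,
        )
        point, _ = fold_change_effect(
            ref.endpoints[f"endpoint_{isotype}"].to_numpy(),
            hi.endpoints[f"endpoint_{isotype}"].to_numpy(),
            n_boot=200,
        )
        return point

    return effect


def benchmark_dose(
    target_reduction: float,
    reduction_fn,
    c_max: float = 1000.0,
    tol: float = 1.0,
    max_iter: int = 30,
) -> float:
    """Bisection for the serum concentration producing a target reduction.

    ``reduction_fn(C)`` returns the percent reduction (>= 0, monotone
    non-decreasing in C) of the endpoint versus unexposed.  Raises
    ``RuntimeError`` with diagnostics when the target is unreachable below
    ``c_max``.
    """
    if target_reduction == 0:
        return 0.0
    if target_reduction < 0 or target_reduction >= 100:
        raise ValueError("target reduction must be in [0, 100)")
    r_max = reduction_fn(c_max)
    if r_max < target_reduction - tol:
        raise RuntimeError(
            f"target reduction {target_reduction}% unreachable: "
            f"only {r_max:.2f}% at {c_max} ng/ml"
        )
    lo, hi = 0.0, c_max
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = reduction_fn(mid)
        if abs(r - target_reduction) <= tol:
            return mid
        if r < target_reduction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Shipped study designs and file output
# --------------------------------------------------------------------------

def load_study(name_or_path: str | Path) -> dict:
    """Load a shipped study design by name or a YAML file by path."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        with open(p) as fh:
            return yaml.safe_load(fh)
    from importlib import resources

    ref = resources.files("immunotox").joinpath(f"studies/{name_or_path}.yaml")
    if not ref.is_file():
        raise FileNotFoundError(f"no shipped study named {name_or_path!r}")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def schedule_from_study(study: dict) -> Schedule:
    events = tuple(
        ScheduleEvent(
            day=ev["day"],
            event_type=ev["type"],
            antigen_id=ev["antigen"],
            dose=ev.get("dose", 2000),
            pamp=ev.get("pamp", True),
        )
        for ev in study["schedule"]["events"]
    )
    return Schedule(
        events=events,
        duration_days=study["schedule"]["duration_days"],
        sampling_day=study["schedule"].get("sampling_day"),
        endpoint_antigen=study["schedule"].get("endpoint_antigen"),
    )


def write_trial_outputs(result: TrialResult, out_dir: str | Path) -> None:
    """Write timeseries.csv, endpoints.csv and manifest.json.

    Floats are written at 17 significant digits so outputs are reproducible
    bit-for-bit across runs with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in result.series:
        days = ts.days()
        for quantity, values in ts.data.items():
            for step, v in enumerate(values):
                rows.append(
                    (step, days[step], quantity, v, ts.patient_id)
                )
    if rows:
        df = pd.DataFrame(
            rows, columns=["step", "day", "quantity", "value", "patient_id"]
        )
        df.to_csv(out / "timeseries.csv", index=False, float_format="%.17g")
    result.endpoints.to_csv(out / "endpoints.csv", index=False, float_format="%.17g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
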