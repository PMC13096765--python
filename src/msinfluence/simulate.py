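"""Synthetic clock-reset multistate cohorts with known truth.

Patients start in state 1 and move through the transition graph under
proportional-hazards intensities

    lambda_g(t) = lambda_g0(t) * exp(beta_true' Z_g),

sampled as competing independent latent clocks per occupied state (minimum
taken, clock reset on every entry).  Baselines are constant (exponential)
by default, with a per-transition Weibull shape available.  Right
censoring combines an administrative horizon with an independent
exponential censoring time, both on the study clock.  Contamination
operators inject the influential-case patterns the diagnostics are meant
to find: extreme covariate values, implausibly fast transitions, and
inflated post-relapse survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .data import LONG_COLUMNS, MultistateDataset
from .graph import CovariateMapping, MappingTerm, TransitionGraph, figure1_breast5

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "Contamination",
    "default_config",
    "simulate_cohort",
    "inject_outliers",
    "write_truth",
]

#: Baseline monthly rates for the 9 breast-cancer transitions, tuned so a
#: typical patient's first event lands a few years after surgery and a
#: 15-year horizon censors roughly a third of the cohort.
DEFAULT_RATES = {1: 0.002, 2: 0.003, 3: 0.0005, 4: 0.001,
                 5: 0.010, 6: 0.005, 7: 0.002,
                 8: 0.020, 9: 0.003}

#: Tumor-size-like covariate (mm): Gamma with mean 25 mm, sd 12.5 mm;
#: grade-like binary marker with prevalence 1/2.
DEFAULT_COVARIATES = {
    "size": ("gamma", {"shape": 4.0, "scale": 6.25}),
    "grade": ("bernoulli", {"p": 0.5}),
}

DEFAULT_BETA = {"size": 0.03, "grade": 0.4}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``beta_true`` is keyed by expanded design column; ``rates`` by
    transition id (months^-1).  ``horizon`` is the administrative
    censoring time and ``censoring_rate`` the rate of an additional
    exponential censoring clock, both in months on the study clock.
    """

    n: int = 300
    graph: TransitionGraph = field(default_factory=figure1_breast5)
    mapping: CovariateMapping | None = None
    covariate_specs: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    beta_true: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    weibull_shapes: dict | None = None
    horizon: float = 180.0
    censoring_rate: float = 1.0 / 360.0
    seed: int = 0

    def resolved_mapping(self) -> CovariateMapping:
        if self.mapping is not None:
            return self.mapping
        return CovariateMapping.shared(list(self.covariate_specs), self.graph)

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size n must be >= 2")
        if self.horizon <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring rate must be non-negative")
        mapping = self.resolved_mapping()
        mapping.validate(self.graph)
        for g in range(1, self.graph.n_transitions + 1):
            if self.rates.get(g, 0.0) <= 0:
                raise ValueError(f"transition {g} needs a positive baseline rate")
        missing = [c for c in mapping.columns if c not in self.beta_true]
        if missing:
            raise ValueError(f"beta_true missing design column(s) {missing}")
        for t in mapping.terms:
            if t.covariate not in self.covariate_specs:
                raise ValueError(f"no sampler for covariate {t.covariate!r}")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated cohort."""

    beta_true: np.ndarray
    columns: list[str]
    trajectories: dict          # id -> [(state, study-clock entry time), ...]
    seed: int
    config: SimulationConfig
    contaminated_ids: list[str] = field(default_factory=list)


def default_config(**overrides) -> SimulationConfig:
    """The standard breast-cancer-like study conditions (5 states, p = 2)."""
    return replace(SimulationConfig(), **overrides)


def _sample_covariates(rng: np.random.Generator, specs: dict) -> dict:
    out = {}
    for name, (dist, params) in specs.items():
        if dist == "gamma":
            out[name] = float(rng.gamma(params["shape"], params["scale"]))
        elif dist == "bernoulli":
            out[name] = float(rng.random() < params["p"])
        elif dist == "normal":
            out[name] = float(rng.normal(params.get("loc", 0.0), params.get("scale", 1.0)))
        elif dist == "uniform":
            out[name] = float(rng.uniform(params.get("low", 0.0), params.get("high", 1.0)))
        else:
            raise ValueError(f"unknown covariate distribution {dist!r}")
    return out


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> tuple[MultistateDataset, SimulationTruth]:
    """Simulate a cohort; deterministic given the seed.

    Emits the long format: whenever a patient occupies a non-absorbing
    state, one row per outgoing transition, all sharing the sojourn
    interval on the study clock; the transition taken gets status 1.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    graph = config.graph
    mapping = config.resolved_mapping()
    columns = mapping.columns
    beta = np.array([config.beta_true[c] for c in columns])
    shapes = config.weibull_shapes or {}
    rng = np.random.default_rng(config.seed)

    rows: list[list] = []
    trajectories: dict[str, list] = {}
    width = len(str(config.n))
    for k in range(config.n):
        pid = f"P{k + 1:0{width}d}"
        base = _sample_covariates(rng, config.covariate_specs)
        if config.censoring_rate > 0:
            censor = min(config.horizon, rng.exponential(1.0 / config.censoring_rate))
        else:
            censor = config.horizon
        state, gtime = 1, 0.0
        trajectories[pid] = [(1, 0.0)]
        while state not in graph.absorbing_states:
            outs = graph.out_transitions(state)
            designs = {g: mapping.design_row(base, g) for g in outs}
            times = {}
            for g in outs:
                theta = config.rates[g] * float(np.exp(designs[g] @ beta))
                shape = float(shapes.get(g, 1.0))
                e = rng.exponential(1.0)
                times[g] = (e / theta) ** (1.0 / shape)
            g_win = min(times, key=lambda g: (times[g], g))
            t_win = times[g_win]
            remaining = censor - gtime
            if remaining <= 0:
                break
            if t_win >= remaining:
                for g in outs:
                    i, j = graph.transitions[g - 1]
                    rows.append([pid, i, j, g, gtime, gtime + remaining, 0,
                                 *designs[g]])
                break
            for g in outs:
                i, j = graph.transitions[g - 1]
                rows.append([pid, i, j, g, gtime, gtime + t_win,
                             int(g == g_win), *designs[g]])
            gtime += t_win
            state = graph.target(g_win)
            trajectories[pid].append((state, gtime))

    table = pd.DataFrame(rows, columns=LONG_COLUMNS + columns)
    data = MultistateDataset(graph, table, columns)
    truth = SimulationTruth(beta_true=beta, columns=list(columns),
                            trajectories=trajectories, seed=config.seed,
                            config=config)
    return data, truth


@dataclass(frozen=True)
class Contamination:
    """How many patients to contaminate and with which mechanisms.

    ``extreme_covariate`` multiplies one covariate column by
    ``covariate_factor`` for the chosen patients (the >100 mm tumor
    pattern); ``fast_transition`` shrinks the sojourn ending in the
    patient's first event by ``time_factor``; ``slow_survival`` inflates
    the patient's post-relapse sojourns (origin state > 1) by
    ``survival_factor``.
    """

    n_patients: int = 2
    mechanisms: tuple[str, ...] = ("extreme_covariate", "fast_transition")
    covariate: str = "size"
    covariate_factor: float = 6.0
    time_factor: float = 0.05
    survival_factor: float = 5.0

    _KNOWN = ("extreme_covariate", "fast_transition", "slow_survival")

    def __post_init__(self) -> None:
        bad = [m for m in self.mechanisms if m not in self._KNOWN]
        if bad:
            raise ValueError(f"unknown contamination mechanism(s) {bad}")


def _patient_blocks(table: pd.DataFrame, pid: str) -> list[np.ndarray]:
    """Row-index blocks of one patient, one block per occupied state,
    ordered by study-clock entry time (rows in a block share the sojourn)."""
    rows = table.index[table["id"] == pid]
    starts = table.loc[rows, "Tstart"]
    blocks = []
    for t in sorted(starts.unique()):
        blocks.append(rows[(starts == t).to_numpy()].to_numpy())
    return blocks


def _rescale_patient(table: pd.DataFrame, pid: str, scale_idx: set[int],
                     factor: float) -> None:
    """Scale selected sojourns by ``factor``, rebuilding the patient's study
    clock so later blocks shift consistently."""
    blocks = _patient_blocks(table, pid)
    new_start = 0.0
    for b_idx, rows in enumerate(blocks):
        dur = float(table.loc[rows[0], "Tstop"] - table.loc[rows[0], "Tstart"])
        if b_idx in scale_idx:
            dur *= factor
        table.loc[rows, "Tstart"] = new_start
        table.loc[rows, "Tstop"] = new_start + dur
        new_start += dur


def inject_outliers(data: MultistateDataset, contamination: Contamination | None = None,
                    seed: int = 0) -> tuple[MultistateDataset, list[str]]:
    """Contaminate a copy of the dataset; returns it with the ground-truth ids.

    Patients are drawn among those with at least one event record: a fully
    censored patient has a zero score contribution and cannot register in
    any case-weight diagnostic, and the influential-case patterns being
    emulated are patients who progressed.
    """
    contamination = contamination or Contamination()
    if data.n_records == 0:
        raise ValueError("cannot contaminate an empty dataset")
    if contamination.n_patients >= data.n_patients:
        raise ValueError("contamination count must be below the cohort size")
    rng = np.random.default_rng(seed)
    with_event = sorted(set(data.table.loc[data.table["status"] == 1, "id"]))
    if len(with_event) < contamination.n_patients:
        raise ValueError("not enough patients with events to contaminate")
    chosen = sorted(rng.choice(with_event, size=contamination.n_patients,
                               replace=False).tolist())
    table = data.table.copy()
    for pid in chosen:
        if "extreme_covariate" in contamination.mechanisms:
            col = contamination.covariate
            if col not in data.covariates:
                raise KeyError(f"unknown covariate {col!r}")
            mask = table["id"] == pid
            table.loc[mask, col] = table.loc[mask, col] * contamination.covariate_factor
        if "fast_transition" in contamination.mechanisms:
            blocks = _patient_blocks(table, pid)
            target = next((b for b, rows in enumerate(blocks)
                           if (table.loc[rows, "status"] == 1).any()), None)
            if target is not None:
                _rescale_patient(table, pid, {target}, contamination.time_factor)
        if "slow_survival" in contamination.mechanisms:
            blocks = _patient_blocks(table, pid)
            late = {b for b, rows in enumerate(blocks)
                    if int(table.loc[rows[0], "from"]) > 1}
            if late:
                _rescale_patient(table, pid, late, contamination.survival_factor)
    return MultistateDataset(data.graph, table, list(data.covariates)), chosen


def write_truth(truth: SimulationTruth, path) -> None:
    """Write the truth sidecar (structured text) next to a simulated cohort."""
    cfg = truth.config
    doc = {
        "seed": int(truth.seed),
        "beta_true": {c: float(b) for c, b in zip(truth.columns, truth.beta_true)},
        "design_columns": list(truth.columns),
        "contaminated_ids": list(truth.contaminated_ids),
        "config": {
            "n": int(cfg.n),
            "horizon_months": float(cfg.horizon),
            "censoring_rate": float(cfg.censoring_rate),
            "rates": {int(g): float(r) for g, r in cfg.rates.items()},
            "n_states": int(cfg.graph.n_states),
            "transitions": [list(t) for t in cfg.graph.transitions],
            "absorbing_states": sorted(cfg.graph.absorbing_states),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
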