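"""Generalized Cox partial likelihood for clock-reset multistate models.

The model places a proportional-hazards intensity on each transition g,

    lambda_g(t) = lambda_g0(t) * exp(beta' Z_g),

with t the time since entering the origin state.  Under the clock-reset
convention each transition contributes Cox-type factors to a single pooled
partial likelihood: for every event record (g, k)

    L_gk(beta) = Z_gk' beta - log sum_{l in R(t_gk)} exp(Z_gl' beta),

where the risk set R(t) holds all records of transition g with
entry < t <= exit (Breslow tie handling: tied events share the full
risk-set denominator).  Coefficients shared across transitions are encoded
in the expanded design, so a single coefficient vector beta of length p
covers all transitions.

This module evaluates the log partial likelihood, its analytic score and
Hessian, fits beta by Newton-Raphson with step-halving, and estimates the
per-transition cumulative baseline hazards by Nelson-Aalen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultistateDataset

__all__ = [
    "ConvergenceError",
    "TransitionDesign",
    "ModelDesign",
    "EventContributions",
    "FittedModel",
    "build_design",
    "risk_set",
    "log_partial_likelihood",
    "score",
    "hessian",
    "fit",
    "nelson_aalen_baseline",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed (singular Hessian or no convergence)."""


@dataclass
class TransitionDesign:
    """Arrays for one transition: at-risk intervals, events, design."""

    g: int
    patient_idx: np.ndarray      # dense patient index per record
    patient_ids: np.ndarray      # string ids per record
    entry: np.ndarray            # clock-reset entry times (0 in practice)
    exit: np.ndarray             # clock-reset exit times t_gk
    status: np.ndarray           # bool, event indicator d_gk
    Z: np.ndarray                # (n_g, p) expanded design
    event_rows: np.ndarray = field(init=False)  # indices of event records
    risk_mask: np.ndarray = field(init=False)   # (n_events, n_g) bool

    def __post_init__(self) -> None:
        self.event_rows = np.flatnonzero(self.status)
        t = self.exit[self.event_rows]
        # member l at risk at event time t: entry_l < t <= exit_l
        self.risk_mask = (self.entry[None, :] < t[:, None]) & (t[:, None] <= self.exit[None, :])

    @property
    def n_events(self) -> int:
        return len(self.event_rows)


class ModelDesign:
    """Per-transition arrays plus the dense patient index for a dataset."""

    def __init__(self, dataset: MultistateDataset, covariates: list[str] | None = None):
        self.dataset = dataset
        self.covariates = list(dataset.covariates if covariates is None else covariates)
        self.p = len(self.covariates)
        ids = dataset.patient_ids
        self.patient_ids = list(ids)
        index = {pid: k for k, pid in enumerate(ids)}
        tab = dataset.table
        dur = (tab["Tstop"] - tab["Tstart"]).to_numpy(dtype=float)
        pidx = np.array([index[i] for i in tab["id"]], dtype=int)
        Z = tab[self.covariates].to_numpy(dtype=float) if self.p else np.empty((len(tab), 0))
        self.transitions: list[TransitionDesign] = []
        for g in range(1, dataset.graph.n_transitions + 1):
            rows = np.flatnonzero((tab["trans"] == g).to_numpy())
            self.transitions.append(TransitionDesign(
                g=g,
                patient_idx=pidx[rows],
                patient_ids=tab["id"].to_numpy()[rows],
                entry=np.zeros(len(rows)),
                exit=dur[rows],
                status=tab["status"].to_numpy()[rows].astype(bool),
                Z=Z[rows],
            ))
        empty = [td.g for td in self.transitions
                 if td.n_events and not td.risk_mask.any(axis=1).all()]
        if empty:
            raise ValueError(f"event with empty risk set in transition(s) {empty}")

    @property
    def n_events(self) -> int:
        return sum(td.n_events for td in self.transitions)


def build_design(dataset: MultistateDataset,
                 covariates: list[str] | None = None) -> ModelDesign:
    """Build (and cache on the dataset) the per-transition design arrays."""
    key = tuple(covariates) if covariates is not None else None
    cache = getattr(dataset, "_design_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    design = ModelDesign(dataset, covariates)
    dataset._design_cache = (key, design)
    return design


def risk_set(data: MultistateDataset, g: int, t: float) -> list[str]:
    """Patient ids of records of transition ``g`` at risk at time ``t``.

    A record is at risk when ``entry < t <= exit``; records exiting exactly
    at ``t`` are included regardless of status (Breslow convention).
    """
    if t <= 0:
        raise ValueError("risk sets are defined for t > 0")
    data.graph._check(g)
    td = build_design(data).transitions[g - 1]
    mask = (td.entry < t) & (t <= td.exit)
    return list(td.patient_ids[mask])


def _per_transition(td: TransitionDesign, beta: np.ndarray):
    """Risk-set aggregates for one transition at beta.

    Returns (lp, Q, C, S1, eventZ): linear predictors, exp weights, the
    risk-set sums C_gk, weighted covariate sums S1_gk and the event design
    rows, all per event record.
    """
    lp = td.Z @ beta if beta.size else np.zeros(len(td.Z))
    Q = np.exp(lp)
    C = td.risk_mask @ Q
    S1 = (td.risk_mask * Q[None, :]) @ td.Z          # (e, p)
    return lp, Q, C, S1, td.Z[td.event_rows]


def log_partial_likelihood(beta: np.ndarray, data: MultistateDataset,
                           covariates: list[str] | None = None) -> float:
    """Pooled log partial likelihood sum_g sum_{events} L_gk(beta)."""
    design = build_design(data, covariates)
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for td in design.transitions:
        if not td.n_events:
            continue
        lp, Q, C, _, _ = _per_transition(td, beta)
        total += float(np.sum(lp[td.event_rows] - np.log(C)))
    return total


def score(beta: np.ndarray, data: MultistateDataset,
          covariates: list[str] | None = None):
    """Analytic score U_P(beta) and per-event contributions.

    Each event record (g, k) contributes

        U_gk = Z_gk - sum_{l in R} Q_gl Z_gl / C_gk,

    its covariate value minus the risk-set exp(beta'Z)-weighted mean.

    Returns
    -------
    total : (p,) ndarray
    per_event : list of (g, event_rows, U) with U of shape (n_events_g, p)
    """
    design = build_design(data, covariates)
    beta = np.asarray(beta, dtype=float)
    total = np.zeros(design.p)
    per_event = []
    for td in design.transitions:
        if not td.n_events:
            per_event.append((td.g, td.event_rows, np.empty((0, design.p))))
            continue
        _, Q, C, S1, Zev = _per_transition(td, beta)
        U = Zev - S1 / C[:, None]
        total += U.sum(axis=0)
        per_event.append((td.g, td.event_rows, U))
    return total, per_event


def hessian(beta: np.ndarray, data: MultistateDataset,
            covariates: list[str] | None = None) -> np.ndarray:
    """Analytic Hessian of the log partial likelihood.

    Each event contributes minus the exp(beta'Z)-weighted covariate
    covariance over its risk set; the total is symmetric negative
    semidefinite.
    """
    design = build_design(data, covariates)
    beta = np.asarray(beta, dtype=float)
    p = design.p
    H = np.zeros((p, p))
    for td in design.transitions:
        if not td.n_events:
            continue
        _, Q, C, S1, _ = _per_transition(td, beta)
        W = td.risk_mask * Q[None, :]                    # (e, n_g)
        ZZ = np.einsum("li,lj->lij", td.Z, td.Z).reshape(len(td.Z), p * p)
        M2 = (W @ ZZ).reshape(-1, p, p)                  # sum_l Q_l Z_l Z_l'
        outer = np.einsum("ki,kj->kij", S1, S1)
        H += np.einsum("kij->ij", outer / (C ** 2)[:, None, None]
                       - M2 / C[:, None, None])
    return (H + H.T) / 2.0


@dataclass
class EventContributions:
    """Per-event quantities at the fitted beta, one block per transition.

    For each event record (g, k): the score contribution U_gk, the
    case-weight factor v_gk = 1 - exp(Z_gk' beta) / C_gk, the risk-set sum
    C_gk, the event time, the patient's dense index and id.
    """

    g: int
    event_rows: np.ndarray
    times: np.ndarray
    patient_idx: np.ndarray
    patient_ids: np.ndarray
    U: np.ndarray        # (n_events, p)
    v: np.ndarray        # (n_events,)
    C: np.ndarray


@dataclass
class FittedModel:
    """A converged multistate Cox fit.

    ``variance`` is V = -(Hessian)^{-1}, the usual large-sample covariance
    of beta_hat; ``events`` holds the per-event score contributions that
    every influence diagnostic is built from.
    """

    dataset: MultistateDataset
    covariates: list[str]
    beta: np.ndarray
    loglik: float
    score_vec: np.ndarray
    hessian: np.ndarray
    variance: np.ndarray
    events: list[EventContributions]
    n_iter: int
    converged: bool
    final_score_norm: float

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def patient_ids(self) -> list[str]:
        return self.dataset.patient_ids

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.variance)) if self.p else np.empty(0)

    def summary_frame(self) -> pd.DataFrame:
        from scipy import stats
        se = self.standard_errors
        z = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        return pd.DataFrame({
            "coef": self.beta,
            "se": se,
            "z": z,
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        }, index=self.covariates)


def _event_contributions(design: ModelDesign, beta: np.ndarray) -> list[EventContributions]:
    out = []
    for td in design.transitions:
        if not td.n_events:
            out.append(EventContributions(
                g=td.g, event_rows=td.event_rows, times=np.empty(0),
                patient_idx=np.empty(0, dtype=int), patient_ids=np.empty(0, dtype=object),
                U=np.empty((0, design.p)), v=np.empty(0), C=np.empty(0)))
            continue
        lp, Q, C, S1, Zev = _per_transition(td, beta)
        U = Zev - S1 / C[:, None]
        v = 1.0 - Q[td.event_rows] / C
        out.append(EventContributions(
            g=td.g,
            event_rows=td.event_rows,
            times=td.exit[td.event_rows],
            patient_idx=td.patient_idx[td.event_rows],
            patient_ids=td.patient_ids[td.event_rows],
            U=U, v=v, C=C))
    return out


def _null_loglik(design: ModelDesign) -> float:
    total = 0.0
    for td in design.transitions:
        if td.n_events:
            total -= float(np.sum(np.log(td.risk_mask.sum(axis=1))))
    return total


def fit(data: MultistateDataset, covariates: list[str] | None = None,
        init: np.ndarray | None = None, tol: float = 1e-8,
        max_iter: int = 50) -> FittedModel:
    """Maximize the pooled partial likelihood by Newton-Raphson.

    Starts at ``init`` (zeros by default), iterates full Newton steps with
    step-halving whenever the log likelihood would decrease, and declares
    convergence when the max-abs score component drops below ``tol``.

    Raises
    ------
    ConvergenceError
        On a singular Hessian (collinear design within the risk-set
        structure), persistent likelihood decrease, or ``max_iter``
        exhausted.
    """
    design = build_design(data, covariates)
    p = design.p
    if p == 0:
        ll = _null_loglik(design)
        return FittedModel(
            dataset=data, covariates=[], beta=np.empty(0), loglik=ll,
            score_vec=np.empty(0), hessian=np.empty((0, 0)),
            variance=np.empty((0, 0)), events=_event_contributions(design, np.empty(0)),
            n_iter=0, converged=True, final_score_norm=0.0)

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll = log_partial_likelihood(beta, data, covariates)
    for it in range(1, max_iter + 1):
        U, _ = score(beta, data, covariates)
        norm = float(np.max(np.abs(U))) if p else 0.0
        if norm <= tol:
            return _finalize(design, data, beta, ll, U, it - 1)
        H = hessian(beta, data, covariates)
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                "singular Hessian: collinear design within the risk-set structure"
            ) from None
        # Newton direction: beta - H^{-1} U increases the concave objective
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            ll_new = log_partial_likelihood(cand, data, covariates)
            if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            scale /= 2.0
        else:
            raise ConvergenceError("step-halving failed to increase the likelihood")
        beta, ll = cand, ll_new
    U, _ = score(beta, data, covariates)
    if float(np.max(np.abs(U))) <= tol:
        return _finalize(design, data, beta, ll, U, max_iter)
    raise ConvergenceError(f"no convergence after {max_iter} iterations "
                           f"(|score|_inf = {np.max(np.abs(U)):.3e})")


def _finalize(design: ModelDesign, data: MultistateDataset, beta: np.ndarray,
              ll: float, U: np.ndarray, n_iter: int) -> FittedModel:
    H = hessian(beta, data, design.covariates)
    Hs = (H + H.T) / 2.0
    try:
        V = np.linalg.solve(-Hs, np.eye(len(beta)))
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular Hessian at the optimum") from None
    V = (V + V.T) / 2.0
    return FittedModel(
        dataset=data, covariates=list(design.covariates), beta=beta,
        loglik=ll, score_vec=U, hessian=Hs, variance=V,
        events=_event_contributions(design, beta),
        n_iter=n_iter, converged=True,
        final_score_norm=float(np.max(np.abs(U))) if len(beta) else 0.0)


def nelson_aalen_baseline(fitted: FittedModel, g: int) -> pd.DataFrame:
    """Nelson-Aalen cumulative baseline hazard for transition ``g``.

    A right-continuous step function jumping d_gk / sum_{l in R} exp(beta'
    Z_gl) at each event time of transition ``g``; identically zero when the
    transition has no events.  Returned as a two-column frame (time,
    cumulative hazard), one row per distinct event time.
    """
    fitted.dataset.graph._check(g)
    ev = fitted.events[g - 1]
    if not len(ev.times):
        return pd.DataFrame({"time": [], "cum_hazard": []})
    order = np.argsort(ev.times, kind="stable")
    times = ev.times[order]
    jumps = 1.0 / ev.C[order]
    frame = pd.DataFrame({"time": times, "jump": jumps})
    out = frame.groupby("time", as_index=False)["jump"].sum()
    out["cum_hazard"] = out["jump"].cumsum()
    return out[["time", "cum_hazard"]]
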