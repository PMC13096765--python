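"""Case-weight local influence via conformal normal curvature.

Each component of the log partial likelihood is given a weight; the
sensitivity of the estimating equations to infinitesimal weight changes
around the null perturbation is summarized by the curvature matrix

    B = Delta' Hessian^{-1} Delta,

with Delta the p x r mixed second derivative of the perturbed
log-likelihood in (beta, omega) at (beta_hat, omega_0).  The conformal
normal curvature in a unit direction h is B_h = |h' B h| / |tr(B)|, bounded
in [0, 1]; the index curvatures B_i = |b_ii / tr(B)| sum to one, and a unit
is flagged as potentially influential when B_i exceeds the mean plus twice
the sample standard deviation of all B_i.  The eigenvector of B with the
largest-magnitude eigenvalue (hmax) points at jointly influential
components.

Three weighting schemes are provided:

* Scheme I  — one weight per (transition, patient) record (r = N, null
  weights all one).  Delta column (g,k) is the printed closed form
  v_gk * U_gk with v_gk = 1 - exp(Z_gk' beta) / C_gk; censored records
  keep (zero) columns.
* Scheme II — one weight per transition (r = G, null weights all zero),
  each component scaled by 1 + (N_g/N) omega_g; Delta column g is
  (N_g/N) * sum of the transition's event score contributions.
* Scheme III — one weight per patient (r = M, null weights all one);
  Delta column i is the patient score U_i, so |b_ii| = p * D_i^(1) and the
  patient ranking coincides with the one-step Cook distance ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .influence_global import patient_scores
from .likelihood import FittedModel

__all__ = [
    "PerturbationScheme",
    "PerturbationJacobian",
    "CurvatureResult",
    "delta_scheme1",
    "delta_scheme2",
    "delta_scheme3",
    "delta_scheme1_full",
    "curvature_matrix",
    "directional_curvature",
    "hmax",
    "flag_influential",
]


@dataclass(frozen=True)
class PerturbationScheme:
    """A case-weight perturbation: its dimension, null point, and labels."""

    name: str
    r: int
    omega0: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        if len(self.omega0) != self.r or len(self.labels) != self.r:
            raise ValueError("omega0/labels length must equal r")


@dataclass(frozen=True)
class PerturbationJacobian:
    """Delta = d^2 L_P(beta|omega) / d beta d omega' at (beta_hat, omega_0)."""

    scheme: PerturbationScheme
    delta: np.ndarray  # (p, r)


def delta_scheme1(fitted: FittedModel) -> PerturbationJacobian:
    """Per-(transition, patient) record weights; Delta is p x N.

    Columns are ordered transition-major, record order within transition
    (the dataset's file order), matching per-transition index plots.
    Event columns are v_gk * U_gk; censored records contribute zero
    columns but remain components of omega.
    """
    design = _design(fitted)
    cols: list[np.ndarray] = []
    labels: list[tuple] = []
    for td, ev in zip(design.transitions, fitted.events):
        block = np.zeros((fitted.p, len(td.exit)))
        if len(ev.event_rows):
            block[:, ev.event_rows] = (ev.v[None, :] * ev.U.T)
        cols.append(block)
        labels.extend((td.g, pid) for pid in td.patient_ids)
    delta = np.hstack(cols) if cols else np.zeros((fitted.p, 0))
    scheme = PerturbationScheme(
        name="scheme1_transition_patient", r=delta.shape[1],
        omega0=np.ones(delta.shape[1]), labels=tuple(labels))
    return PerturbationJacobian(scheme, delta)


def delta_scheme2(fitted: FittedModel) -> PerturbationJacobian:
    """Per-transition weights; Delta is p x G with columns (N_g/N) sum_k U_gk."""
    design = _design(fitted)
    N = sum(len(td.exit) for td in design.transitions)
    cols = []
    for td, ev in zip(design.transitions, fitted.events):
        s = ev.U.sum(axis=0) if len(ev.U) else np.zeros(fitted.p)
        cols.append((len(td.exit) / N) * s)
    delta = np.column_stack(cols) if cols else np.zeros((fitted.p, 0))
    scheme = PerturbationScheme(
        name="scheme2_transition", r=delta.shape[1],
        omega0=np.zeros(delta.shape[1]),
        labels=tuple(td.g for td in design.transitions))
    return PerturbationJacobian(scheme, delta)


def delta_scheme3(fitted: FittedModel) -> PerturbationJacobian:
    """Per-patient weights; Delta is p x M with columns U_i (patient scores).

    At the optimum the columns sum to the zero vector.
    """
    U = patient_scores(fitted)
    scheme = PerturbationScheme(
        name="scheme3_patient", r=U.shape[0],
        omega0=np.ones(U.shape[0]), labels=tuple(fitted.patient_ids))
    return PerturbationJacobian(scheme, U.T.copy())


def delta_scheme1_full(fitted: FittedModel) -> PerturbationJacobian:
    """Full mixed partial of the record-weight perturbed likelihood.

    Diagnostic variant of Scheme I: because the record weights also sit
    inside the risk-set sums, the exact derivative carries cross terms
    linking record (g, l) to every event whose risk set contains it,

        d^2 L / d beta d omega_gl =
            d_gl * U_gl - sum_{events k: l in R(t_gk)} (Q_gl / C_gk)
                          * (Z_gl - Zbar_gk),

    where Zbar_gk is the Q-weighted risk-set mean.  The printed
    closed form (``delta_scheme1``) keeps only the own-record terms and is
    the canonical scheme; this variant is provided for comparison, not
    asserted equal.
    """
    design = _design(fitted)
    cols: list[np.ndarray] = []
    labels: list[tuple] = []
    for td, ev in zip(design.transitions, fitted.events):
        n_g = len(td.exit)
        block = np.zeros((fitted.p, n_g))
        if len(ev.event_rows):
            lp = td.Z @ fitted.beta if fitted.p else np.zeros(n_g)
            Q = np.exp(lp)
            Zbar = td.Z[ev.event_rows] - ev.U          # risk-set weighted mean per event
            # explicit loop kept readable; risk sets are small in practice
            block_T = np.zeros((n_g, fitted.p))
            for k_idx, row in enumerate(ev.event_rows):
                members = np.flatnonzero(td.risk_mask[k_idx])
                contrib = (Q[members, None] / ev.C[k_idx]) * (td.Z[members] - Zbar[k_idx])
                np.add.at(block_T, members, -contrib)
            block_T[ev.event_rows] += ev.U
            block = block_T.T
        cols.append(block)
        labels.extend((td.g, pid) for pid in td.patient_ids)
    delta = np.hstack(cols) if cols else np.zeros((fitted.p, 0))
    scheme = PerturbationScheme(
        name="scheme1_full_derivative", r=delta.shape[1],
        omega0=np.ones(delta.shape[1]), labels=tuple(labels))
    return PerturbationJacobian(scheme, delta)


@dataclass
class CurvatureResult:
    """Curvature matrix B with its index summaries and flagging rule."""

    scheme: PerturbationScheme
    B: np.ndarray
    trace: float
    b_ii: np.ndarray
    B_i: np.ndarray
    cutoff: float
    flagged: list
    _hmax: np.ndarray | None = field(default=None, repr=False)

    @property
    def labels(self) -> tuple:
        return self.scheme.labels

    def to_frame(self) -> pd.DataFrame:
        flagged = set(map(tuple, self.flagged)) if self.flagged and isinstance(
            self.flagged[0], tuple) else set(self.flagged)
        lab = self.labels
        inflag = [(l in flagged) for l in lab]
        return pd.DataFrame({
            "label": [str(l) for l in lab],
            "B_i": self.B_i,
            "cutoff": self.cutoff,
            "flag": np.array(inflag, dtype=int),
        })


def curvature_matrix(fitted: FittedModel, jac: PerturbationJacobian) -> CurvatureResult:
    """B = Delta' Hessian^{-1} Delta, via linear solves.

    B is negative semidefinite (the Hessian is negative definite at the
    fit), so tr(B) <= 0 and the index curvatures B_i = |b_ii / tr(B)| are
    well defined and sum to one whenever tr(B) != 0.  A zero Delta yields
    B = 0; that degenerate case is reported as all-zero curvatures with a
    warning.
    """
    delta = jac.delta
    if delta.shape[0] != fitted.p:
        raise ValueError("Delta row dimension must equal p")
    X = np.linalg.solve(fitted.hessian, delta) if fitted.p else np.zeros_like(delta)
    B = delta.T @ X
    B = (B + B.T) / 2.0
    tr = float(np.trace(B))
    b_ii = np.diag(B).copy()
    r = delta.shape[1]
    if tr == 0.0:
        warnings.warn("tr(B) = 0: curvature is degenerate, all B_i reported as 0",
                      RuntimeWarning, stacklevel=2)
        B_i = np.zeros(r)
        cutoff, flagged = float("nan"), []
    else:
        B_i = np.abs(b_ii / tr)
        if r >= 2:
            cutoff = float(np.mean(B_i) + 2.0 * np.std(B_i, ddof=1))
            flagged = [jac.scheme.labels[i] for i in np.flatnonzero(B_i > cutoff)]
        else:
            cutoff, flagged = float("nan"), []
    return CurvatureResult(scheme=jac.scheme, B=B, trace=tr, b_ii=b_ii,
                           B_i=B_i, cutoff=cutoff, flagged=flagged)


def directional_curvature(result: CurvatureResult, h: np.ndarray) -> float:
    """Conformal normal curvature B_h = |h' B h| / |tr(B)| for unit h."""
    h = np.asarray(h, dtype=float)
    if abs(np.linalg.norm(h) - 1.0) > 1e-12:
        raise ValueError("h must be a unit vector")
    if result.trace == 0.0:
        raise ValueError("tr(B) = 0: directional curvature undefined")
    return float(abs(h @ result.B @ h) / abs(result.trace))


def hmax(result: CurvatureResult) -> np.ndarray:
    """Unit eigenvector of B for the largest-magnitude eigenvalue.

    Computed on the symmetrized B; on a tie the eigenvalue of lowest index
    in the (ascending) eigendecomposition wins.  The sign is fixed so the
    largest-magnitude entry is positive; plot |hmax| against the component
    index to locate jointly influential components.
    """
    if result._hmax is None:
        w, v = np.linalg.eigh((result.B + result.B.T) / 2.0)
        k = int(np.argmax(np.abs(w)))
        h = v[:, k]
        j = int(np.argmax(np.abs(h)))
        if h[j] < 0:
            h = -h
        result._hmax = h / np.linalg.norm(h)
    return result._hmax


def flag_influential(result: CurvatureResult) -> list:
    """Labels with B_i strictly above mean(B) + 2 * sample sd(B)."""
    if result.scheme.r < 2:
        raise ValueError("flagging needs r >= 2 (sample sd undefined)")
    return list(result.flagged)


def _design(fitted: FittedModel):
    from .likelihood import build_design
    return build_design(fitted.dataset, fitted.covariates)
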