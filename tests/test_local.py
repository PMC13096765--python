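"""Case-weight local influence: Delta matrices, curvature, hmax, flags."""

import numpy as np
import pytest

import msinfluence as mi
from msinfluence.likelihood import FittedModel
from conftest import make_g1_dataset


def dummy_fitted(hessian):
    """A minimal FittedModel carrying only what curvature algebra needs."""
    p = hessian.shape[0]
    return FittedModel(dataset=None, covariates=[f"x{i}" for i in range(p)],
                       beta=np.zeros(p), loglik=0.0, score_vec=np.zeros(p),
                       hessian=hessian, variance=np.linalg.inv(-hessian),
                       events=[], n_iter=0, converged=True, final_score_norm=0.0)


def curvature_from(delta, hessian, labels=None):
    r = delta.shape[1]
    scheme = mi.PerturbationScheme("toy", r, np.ones(r),
                                   tuple(labels or range(r)))
    return mi.curvature_matrix(dummy_fitted(hessian), mi.PerturbationJacobian(scheme, delta))


# ---------------------------------------------------------------------------
# independent perturbed log-likelihoods (brute force, test-local)

def _event_terms(data, beta):
    """(g, patient_id, L_gk) per event record, by explicit risk-set loops."""
    beta = np.atleast_1d(beta)
    tab, covs = data.table, data.covariates
    out = []
    for _, row in tab[tab["status"] == 1].iterrows():
        g, t = row["trans"], row["Tstop"] - row["Tstart"]
        z = np.array([row[c] for c in covs])
        denom = 0.0
        for _, o in tab[tab["trans"] == g].iterrows():
            if 0.0 < t <= o["Tstop"] - o["Tstart"]:
                denom += np.exp(float(np.array([o[c] for c in covs]) @ beta))
        out.append((int(g), str(row["id"]), float(z @ beta) - np.log(denom)))
    return out


def perturbed_ll_scheme2(beta, omega, data):
    """Each component weighted by 1 + (N_g/N) * omega_g."""
    ng = data.n_per_transition
    N = data.n_records
    return sum((1.0 + ng[g] / N * omega[g - 1]) * lgk
               for g, _, lgk in _event_terms(data, beta))


def perturbed_ll_scheme3(beta, omega, data, patient_order):
    """Each component weighted by its patient's omega."""
    pos = {pid: i for i, pid in enumerate(patient_order)}
    return sum(omega[pos[pid]] * lgk for _, pid, lgk in _event_terms(data, beta))


def mixed_partial(perturbed_ll, beta, omega0, p, r, h_beta=1e-6, h_omega=0.5):
    """Central finite-difference d2 L / d beta d omega at (beta, omega0)."""
    delta = np.zeros((p, r))
    for j in range(r):
        ej = np.zeros(r)
        ej[j] = h_omega
        def dldw(b):
            return (perturbed_ll(b, omega0 + ej) - perturbed_ll(b, omega0 - ej)) / (2 * h_omega)
        for a in range(p):
            ea = np.zeros(p)
            ea[a] = h_beta
            delta[a, j] = (dldw(beta + ea) - dldw(beta - ea)) / (2 * h_beta)
    return delta


# ---------------------------------------------------------------------------

class TestDeltaScheme1:
    def test_dimension_and_censored_columns_zero(self, fitted_small):
        jac = mi.delta_scheme1(fitted_small)
        data = fitted_small.dataset
        assert jac.delta.shape == (fitted_small.p, data.n_records)
        assert jac.scheme.r == data.n_records
        np.testing.assert_allclose(jac.scheme.omega0, 1.0)
        # column labels are (g, patient) in transition-major order
        gs = [lab[0] for lab in jac.scheme.labels]
        assert gs == sorted(gs)
        # censored records occupy zero columns
        status = {}
        pos = 0
        for g in range(1, 10):
            sub = data.table[data.table["trans"] == g]
            for s in sub["status"]:
                status[pos] = s
                pos += 1
        for j, s in status.items():
            if s == 0:
                np.testing.assert_allclose(jac.delta[:, j], 0.0)

    def test_self_only_risk_set_gives_zero_column(self, two_state_graph):
        # last event's risk set is only itself: v = 0 and U = 0
        data = make_g1_dataset(two_state_graph, [2.0, 3.0, 5.0], [1, 0, 1],
                               [0.3, 1.7, -0.4])
        f = mi.fit(data)
        jac = mi.delta_scheme1(f)
        np.testing.assert_allclose(jac.delta[:, 2], 0.0, atol=1e-12)

    def test_hand_computed_columns_on_toy(self, toy_g1):
        f = mi.fit(toy_g1)
        b = f.beta[0]
        z = np.array([1.0, 0.0, 2.0])
        w = np.exp(b * z)
        u_a = 1.0 - w @ z / w.sum()
        v_a = 1.0 - w[0] / w.sum()
        u_b = 0.0 - (w[1] * 0 + w[2] * 2) / (w[1] + w[2])
        v_b = 1.0 - w[1] / (w[1] + w[2])
        jac = mi.delta_scheme1(f)
        np.testing.assert_allclose(jac.delta[0],
                                   [v_a * u_a, v_b * u_b, 0.0], atol=1e-12)

    def test_full_derivative_variant_differs_by_cross_terms(self, fitted_small):
        printed = mi.delta_scheme1(fitted_small).delta
        full = mi.delta_scheme1_full(fitted_small).delta
        assert full.shape == printed.shape
        # the full mixed partial has nonzero columns for censored records
        assert np.abs(full - printed).max() > 1e-6


class TestDeltaScheme2:
    def test_transition_without_events_gives_zero_column(self, fitted_small):
        jac = mi.delta_scheme2(fitted_small)
        assert jac.delta.shape == (2, 9)
        for idx, ev in enumerate(fitted_small.events):
            if len(ev.event_rows) == 0:
                np.testing.assert_allclose(jac.delta[:, idx], 0.0)

    def test_single_transition_column_vanishes_at_optimum(self, toy_g1):
        f = mi.fit(toy_g1)
        jac = mi.delta_scheme2(f)
        np.testing.assert_allclose(jac.delta, 0.0, atol=1e-8)

    def test_matches_finite_difference_mixed_partial(self, small_cohort):
        data, _ = small_cohort
        f = mi.fit(data)
        fd = mixed_partial(lambda b, w: perturbed_ll_scheme2(b, w, data),
                           f.beta, np.zeros(9), f.p, 9)
        jac = mi.delta_scheme2(f)
        assert np.abs(jac.delta - fd).max() <= 1e-6 * np.abs(fd).max()


class TestDeltaScheme3:
    def test_columns_are_patient_scores_and_sum_to_zero(self, fitted_small):
        jac = mi.delta_scheme3(fitted_small)
        np.testing.assert_allclose(jac.delta,
                                   mi.patient_scores(fitted_small).T)
        np.testing.assert_allclose(jac.delta.sum(axis=1), 0.0, atol=1e-8)
        assert jac.scheme.labels == tuple(fitted_small.patient_ids)

    def test_matches_finite_difference_mixed_partial(self, small_cohort):
        data, _ = small_cohort
        f = mi.fit(data)
        order = f.patient_ids
        fd = mixed_partial(
            lambda b, w: perturbed_ll_scheme3(b, w, data, order),
            f.beta, np.ones(len(order)), f.p, len(order))
        jac = mi.delta_scheme3(f)
        assert np.abs(jac.delta - fd).max() <= 1e-6 * np.abs(fd).max()


class TestCurvature:
    def test_two_by_two_hand_computation(self):
        res = curvature_from(np.diag([1.0, 2.0]), -np.eye(2))
        np.testing.assert_allclose(res.B, -np.diag([1.0, 4.0]))
        assert res.trace == pytest.approx(-5.0)
        np.testing.assert_allclose(res.B_i, [0.2, 0.8])
        assert mi.directional_curvature(res, np.array([1.0, 0.0])) == pytest.approx(0.2)
        np.testing.assert_allclose(mi.hmax(res), [0.0, 1.0])

    def test_zero_delta_degenerates_with_warning(self, fitted_small):
        r = 4
        scheme = mi.PerturbationScheme("toy", r, np.ones(r), tuple(range(r)))
        jac = mi.PerturbationJacobian(scheme, np.zeros((fitted_small.p, r)))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = mi.curvature_matrix(fitted_small, jac)
        np.testing.assert_allclose(res.B_i, 0.0)

    def test_normalization_and_bound(self, fitted_small):
        rng = np.random.default_rng(0)
        for build in (mi.delta_scheme1, mi.delta_scheme2, mi.delta_scheme3):
            res = mi.curvature_matrix(fitted_small, build(fitted_small))
            assert res.B_i.sum() == pytest.approx(1.0)
            hs = rng.normal(size=(1000, res.scheme.r))
            hs /= np.linalg.norm(hs, axis=1, keepdims=True)
            bh = np.abs(np.einsum("ki,ij,kj->k", hs, res.B, hs)) / abs(res.trace)
            assert bh.min() >= 0.0 and bh.max() <= 1.0 + 1e-12

    def test_basis_direction_equals_index_curvature(self, fitted_small):
        res = mi.curvature_matrix(fitted_small, mi.delta_scheme3(fitted_small))
        e = np.zeros(res.scheme.r)
        e[3] = 1.0
        assert mi.directional_curvature(res, e) == pytest.approx(res.B_i[3])

    def test_non_unit_direction_rejected(self, fitted_small):
        res = mi.curvature_matrix(fitted_small, mi.delta_scheme3(fitted_small))
        with pytest.raises(ValueError, match="unit"):
            mi.directional_curvature(res, np.full(res.scheme.r, 0.5))

    def test_rescaling_covariates_leaves_curvatures_invariant(self, small_cohort):
        data, _ = small_cohort
        f = mi.fit(data, tol=1e-10)
        scaled = data.copy()
        scaled.table["size"] = scaled.table["size"] * 2.5
        f2 = mi.fit(scaled, tol=1e-10)
        for build in (mi.delta_scheme1, mi.delta_scheme2, mi.delta_scheme3):
            b1 = mi.curvature_matrix(f, build(f)).B_i
            b2 = mi.curvature_matrix(f2, build(f2)).B_i
            np.testing.assert_allclose(b1, b2, atol=1e-8)


class TestHmax:
    def test_diagonal_dominant_entry(self):
        res = curvature_from(np.diag([np.sqrt(3.0), 1.0]), -np.eye(2))
        # B = -diag(3, 1): largest-magnitude eigenvalue belongs to coordinate 0
        np.testing.assert_allclose(mi.hmax(res), [1.0, 0.0], atol=1e-12)

    def test_unit_norm_and_dominates_random_directions(self, fitted_small):
        res = mi.curvature_matrix(fitted_small, mi.delta_scheme3(fitted_small))
        h = mi.hmax(res)
        assert np.linalg.norm(h) == pytest.approx(1.0)
        assert h[np.argmax(np.abs(h))] > 0
        best = mi.directional_curvature(res, h)
        rng = np.random.default_rng(1)
        hs = rng.normal(size=(10_000, res.scheme.r))
        hs /= np.linalg.norm(hs, axis=1, keepdims=True)
        bh = np.abs(np.einsum("ki,ij,kj->k", hs, res.B, hs)) / abs(res.trace)
        assert best >= bh.max() - 1e-12

    def test_duplicate_eigenvalue_tie_break_is_deterministic(self):
        res1 = curvature_from(np.eye(3), -np.eye(3))
        res2 = curvature_from(np.eye(3), -np.eye(3))
        np.testing.assert_allclose(mi.hmax(res1), mi.hmax(res2))


class TestFlagging:
    def test_no_flags_when_cutoff_above_all(self):
        delta = np.sqrt(np.diag([0.1, 0.1, 0.8]))
        res = curvature_from(delta, -np.eye(3))
        np.testing.assert_allclose(res.B_i, [0.1, 0.1, 0.8])
        assert res.cutoff == pytest.approx(1 / 3 + 2 * np.std([0.1, 0.1, 0.8], ddof=1))
        assert mi.flag_influential(res) == []

    def test_equal_curvatures_never_flag(self):
        res = curvature_from(np.ones((1, 5)), -np.eye(1))
        assert res.cutoff == pytest.approx(0.2)
        assert mi.flag_influential(res) == []

    def test_single_dominant_unit_flagged(self):
        vals = np.full(100, 0.5 / 99)
        vals[0] = 0.5
        res = curvature_from(np.sqrt(vals)[None, :], -np.eye(1))
        assert mi.flag_influential(res) == [0]

    def test_r_below_two_rejected(self):
        res = curvature_from(np.array([[1.0]]), -np.eye(1))
        with pytest.raises(ValueError, match="r >= 2"):
            mi.flag_influential(res)
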