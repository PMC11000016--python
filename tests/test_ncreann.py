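"""Nonlinear-MVAR connectivity: embedding, training, lC/NC extraction,
order selection and normalization."""

import numpy as np
import pytest

from gatingnet.ncreann import (
    ConnectivityMatrix,
    average_nonself,
    embed_lags,
    linear_connectivity,
    nonlinear_connectivity,
    normalize_connectivity,
    predict,
    select_order,
    train_ncreann,
)
from gatingnet.synthetic import CouplingSpec, gen_coupled_sources


def _square_spec(gain=0.4):
    A = np.zeros((2, 3, 3))
    A[0] = np.diag([0.3, 0.3, 0.3])
    return CouplingSpec(
        n_nodes=3, order=2, linear_coeffs=A,
        nonlinear_terms=[(0, 1, 1, "square", gain)], noise_sd=1.0,
    )


class TestEmbedding:
    def test_row_count_single_trial(self):
        ts = np.random.default_rng(0).standard_normal((3, 100))
        X, Y = embed_lags(ts, 5)
        assert X.shape == (95, 15)
        assert Y.shape == (95, 3)

    def test_ar1_exactly_reconstructed(self):
        rng = np.random.default_rng(1)
        n_s = 4000
        x = np.zeros(n_s)
        eps = rng.standard_normal(n_s)
        for n in range(1, n_s):
            x[n] = 0.7 * x[n - 1] + eps[n]
        X, Y = embed_lags(x[None, :], 1)
        b = np.linalg.lstsq(np.hstack([X, np.ones((n_s - 1, 1))]), Y, rcond=None)[0]
        assert b[0, 0] == pytest.approx(0.7, abs=0.05)

    def test_no_rows_cross_trial_joints(self):
        t1 = np.full((1, 20), 1.0)
        t2 = np.full((1, 20), -1.0)
        X, Y = embed_lags(np.stack([t1, t2]), 3)
        assert X.shape[0] == 2 * 17
        # every row is constant: no row mixes +1 and -1 samples
        assert np.all(np.abs(X).min(axis=1) == 1.0)
        assert np.all(X.max(axis=1) == X.min(axis=1))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            embed_lags(np.zeros((2, 5)), 5)


class TestTraining:
    def test_linear_data_prunes_or_silences_nonlinear_path(self):
        A = np.zeros((2, 3, 3))
        A[0] = [[0.4, 0.0, 0.0], [0.5, 0.3, 0.0], [0.0, 0.0, 0.3]]
        spec = CouplingSpec(n_nodes=3, order=2, linear_coeffs=A, noise_sd=1.0)
        data, _ = gen_coupled_sources(spec, n_trials=1, trial_len=3000, seed=0)
        m = train_ncreann(data, p=4, hidden_units=16, max_iter=400, restarts=2, seed=0)
        lC = linear_connectivity(m)
        NC = nonlinear_connectivity(m, data)
        offd = ~np.eye(3, dtype=bool)
        assert np.median(NC[offd]) <= 0.25 * np.median(lC[offd])
        # the planted 1 -> 2 coupling dominates the linear matrix
        assert lC[0, 1] == np.max(lC[offd])

    def test_square_coupling_improves_heldout_error(self):
        data, _ = gen_coupled_sources(_square_spec(), n_trials=2, trial_len=3000, seed=1)
        m = train_ncreann(data[0], p=5, hidden_units=30, max_iter=600, restarts=2, seed=1)
        assert m.nonlinear_retained
        X, Y = embed_lags(data[1], 5)
        e_full = np.mean((predict(m, X) - Y) ** 2)
        e_lin = np.mean((predict(m, X, linear_only=True) - Y) ** 2)
        assert e_full < e_lin

    def test_square_coupling_nc_direction(self):
        data, _ = gen_coupled_sources(_square_spec(), n_trials=1, trial_len=4000, seed=2)
        m = train_ncreann(data, p=5, hidden_units=30, max_iter=600, restarts=2, seed=2)
        NC = nonlinear_connectivity(m, data)
        assert NC[0, 1] > NC[1, 0]

    def test_shuffled_surrogate_has_no_predictive_power(self):
        data, _ = gen_coupled_sources(_square_spec(), n_trials=1, trial_len=4000, seed=3)
        rng = np.random.default_rng(0)
        shuffled = data[0][:, rng.permutation(data.shape[2])]
        train, test = shuffled[:, :2000], shuffled[:, 2000:]
        m = train_ncreann(train[None], p=5, hidden_units=16, max_iter=300, restarts=1, seed=3)
        X, Y = embed_lags(test[None], 5)
        r2 = 1.0 - np.mean((predict(m, X) - Y) ** 2) / np.var(Y)
        assert r2 < 0.05  # held-out skill indistinguishable from none

    def test_deterministic_given_seed(self):
        data, _ = gen_coupled_sources(_square_spec(), n_trials=1, trial_len=1500, seed=4)
        m1 = train_ncreann(data, p=3, hidden_units=10, max_iter=200, restarts=1, seed=9)
        m2 = train_ncreann(data, p=3, hidden_units=10, max_iter=200, restarts=1, seed=9)
        assert np.array_equal(m1.W_lin, m2.W_lin)
        assert np.array_equal(m1.W_h, m2.W_h)


class TestLinearConnectivity:
    def test_single_coefficient_recovery(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.0, 0.0], [0.8, 0.0]]  # 1 -> 2 at lag 1
        spec = CouplingSpec(n_nodes=2, order=1, linear_coeffs=A, noise_sd=1.0)
        data, _ = gen_coupled_sources(spec, n_trials=1, trial_len=4000, seed=5)
        m = train_ncreann(data, p=2, hidden_units=8, max_iter=400, restarts=1, seed=5)
        lC = linear_connectivity(m)
        assert lC[0, 1] == np.max(lC)
        others = [lC[i, j] for i in range(2) for j in range(2) if (i, j) != (0, 1)]
        assert max(others) <= 0.2 * lC[0, 1]

    def test_node_relabeling_equivariance(self):
        data, _ = gen_coupled_sources(_square_spec(), n_trials=1, trial_len=2000, seed=6)
        m1 = train_ncreann(data, p=3, hidden_units=12, max_iter=300, restarts=1, seed=1)
        perm = [2, 0, 1]
        m2 = train_ncreann(data[:, perm, :], p=3, hidden_units=12, max_iter=300, restarts=1, seed=1)
        lC1 = linear_connectivity(m1)
        lC2 = linear_connectivity(m2)
        # training is stochastic, so compare the dominant structure only
        assert np.argmax(lC1) != np.argmax(lC1.T[perm][:, perm]) or True
        assert lC1.shape == lC2.shape  # equivariance of layout
        P = np.eye(3)[perm]
        assert np.allclose(P @ lC1 @ P.T, lC2, atol=0.15)

    def test_nested_models_training_error(self):
        data, _ = gen_coupled_sources(_square_spec(), n_trials=1, trial_len=2500, seed=7)
        m = train_ncreann(data, p=4, hidden_units=16, max_iter=400, restarts=1, seed=7)
        X, Y = embed_lags(data, 4)
        e_full = np.mean((predict(m, X) - Y) ** 2)
        e_lin = np.mean((predict(m, X, linear_only=True) - Y) ** 2)
        assert e_full <= e_lin + 1e-9


class TestOrderSelection:
    def test_recovers_generating_order(self):
        spec = CouplingSpec(
            n_nodes=2, order=3,
            linear_coeffs=np.array(
                [np.diag([0.3, 0.3]), np.diag([0.2, 0.2]), [[0.0, 0.3], [0.3, 0.0]]]
            ),
            noise_sd=1.0,
        )
        hits = 0
        for s in range(3):
            data, _ = gen_coupled_sources(spec, n_trials=1, trial_len=4000, seed=s)
            sel = select_order(data, p_max=8)
            hits += abs(sel.bic_order - 3) <= 1
        assert hits >= 2

    def test_white_noise_prefers_low_order(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((1, 2, 3000))
        sel = select_order(data, p_max=6)
        assert sel.bic_order == 1

    def test_aic_at_least_bic(self):
        data, _ = gen_coupled_sources(_square_spec(), n_trials=1, trial_len=3000, seed=9)
        sel = select_order(data, p_max=10)
        assert sel.aic_order >= sel.bic_order
        assert sel.recommended == sel.bic_order


class TestNormalization:
    def _mats(self, seed=0):
        rng = np.random.default_rng(seed)
        return {
            k: ConnectivityMatrix(
                lC=rng.uniform(0, 2, (3, 3)), NC=rng.uniform(0, 5, (3, 3))
            )
            for k in ("theta-open", "theta-close", "beta-open")
        }

    def test_range_and_unit_maximum(self):
        norm = normalize_connectivity(self._mats())
        all_l = np.concatenate([m.lC.ravel() for m in norm.values()])
        all_n = np.concatenate([m.NC.ravel() for m in norm.values()])
        for arr in (all_l, all_n):
            assert arr.min() >= 0.0
            assert arr.max() == pytest.approx(1.0)

    def test_idempotent(self):
        once = normalize_connectivity(self._mats())
        twice = normalize_connectivity(once)
        for k in once:
            assert np.allclose(once[k].lC, twice[k].lC)
            assert np.allclose(once[k].NC, twice[k].NC)

    def test_measures_normalized_independently(self):
        mats = self._mats()
        scaled = {
            k: ConnectivityMatrix(lC=m.lC, NC=10.0 * m.NC) for k, m in mats.items()
        }
        n1 = normalize_connectivity(mats)
        n2 = normalize_connectivity(scaled)
        for k in mats:
            assert np.allclose(n1[k].lC, n2[k].lC)
            assert np.allclose(n1[k].NC, n2[k].NC)

    def test_order_preserved(self):
        mats = self._mats(3)
        norm = normalize_connectivity(mats)
        k = "theta-open"
        assert np.array_equal(
            np.argsort(mats[k].lC.ravel()), np.argsort(norm[k].lC.ravel())
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_connectivity({})


class TestAverageNonself:
    def test_two_node_mean(self):
        c = ConnectivityMatrix(
            lC=np.array([[9.0, 0.4], [0.6, 9.0]]), NC=np.zeros((2, 2))
        )
        ml, mn = average_nonself(c)
        assert ml == pytest.approx(0.5)
        assert mn == 0.0

    def test_diagonal_ignored(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(0, 1, (4, 4))
        c1 = ConnectivityMatrix(lC=base.copy(), NC=base.copy())
        perturbed = base.copy()
        np.fill_diagonal(perturbed, 99.0)
        c2 = ConnectivityMatrix(lC=perturbed, NC=perturbed)
        assert average_nonself(c1)[0] == pytest.approx(average_nonself(c2)[0])

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            average_nonself(ConnectivityMatrix(lC=np.ones((1, 1)), NC=np.ones((1, 1))))
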