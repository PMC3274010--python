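"""Hopfield-network disparity smoothing: mapping, energy and dynamics."""

import numpy as np
import pytest

from hemistereo import hopfield as hnn
from hemistereo.matching import DisparityMap


def _map(values):
    return DisparityMap(values=np.asarray(values, dtype=np.float64), theta_max=6.0)


def _uniform_map(value, shape=(8, 8)):
    return _map(np.full(shape, value))


class TestStateMapping:
    @pytest.mark.parametrize("d,expected", [(0.0, -1.0), (6.0, 1.0), (3.0, 0.0)])
    def test_normalize_endpoints(self, d, expected):
        assert hnn.normalize_disparity(d, 6.0) == pytest.approx(expected)

    def test_round_trip(self, rng):
        d = rng.uniform(0, 6, 50)
        back = hnn.denormalize_disparity(hnn.normalize_disparity(d, 6.0), 6.0)
        assert np.allclose(back, d)


class TestConsistencyAndContext:
    def test_consistency_coefficient(self):
        assert hnn.consistency_coefficient(0.5, 0.5) == 1.0
        assert hnn.consistency_coefficient(1.0, -1.0) == -1.0
        assert hnn.consistency_coefficient(0.2, 0.9, are_neighbours=False) == 0.0

    def test_contextual_extremes(self):
        assert hnn.contextual_term(1.0, [1.0] * 8) == 8.0
        assert hnn.contextual_term(-1.0, [-1.0] * 8) == 8.0
        assert hnn.contextual_term(1.0, [-1.0] * 8) == -8.0
        assert hnn.contextual_term(0.0, [1.0] * 8) == 0.0


class TestConnectionWeights:
    def test_direct_evaluation(self):
        assert hnn.connection_weight(0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_negative_consistency_punishes(self):
        t = hnn.connection_weight(-0.5, 0.4, 0.7)
        assert t == pytest.approx(-0.5)
        # energy term -(1/2) T D_i D_k is then positive (punishment)
        assert -0.5 * t * 0.4 * 0.7 > 0

    def test_diagonal_forced_zero(self):
        assert hnn.connection_weight(0.0, 1.0, 1.0, i=3, k=3) == 0.0

    def test_table_of_sign_patterns(self):
        """All eight (w, D_i, D_k) sign patterns drive the energy correctly:
        both consistencies agreeing lowers it, any disagreement raises it."""
        for w in (0.6, -0.6):
            for di in (0.8, -0.8):
                for dk in (0.8, -0.8):
                    T = hnn.connection_weight(w, di, dk)
                    e_c = -0.5 * T * di * dk
                    consistent = (w > 0) and (di * dk > 0)
                    assert (e_c < 0) == consistent


class TestEnergy:
    def test_all_zero_states(self):
        from scipy import sparse

        T = sparse.csr_matrix((2, 2))
        assert hnn.total_energy(np.zeros(2), T, np.zeros(2)) == 0.0

    def test_two_consistent_neighbours(self):
        from scipy import sparse

        D = np.array([1.0, 1.0])
        w = hnn.consistency_coefficient(D[0], D[1])
        t = hnn.connection_weight(w, D[0], D[1])
        T = sparse.csr_matrix(np.array([[0.0, t], [t, 0.0]]))
        U = D.copy()
        assert hnn.total_energy(D, T, U) == pytest.approx(-3.0)

    def test_flipping_a_consistent_neighbour_raises_energy(self):
        from scipy import sparse

        for d0 in (1.0, -1.0):
            D = np.array([d0, d0])
            t = hnn.connection_weight(hnn.consistency_coefficient(*D), *D)
            T = sparse.csr_matrix(np.array([[0.0, t], [t, 0.0]]))
            U = D.copy()
            base = hnn.total_energy(D, T, U)
            flipped = D.copy()
            flipped[1] *= -1
            assert hnn.total_energy(flipped, T, U) > base


class TestAnnealing:
    def test_beta0_calibration(self):
        assert hnn.calibrate_beta0(0.87) == pytest.approx(4.35)

    def test_gain_at_large_iteration(self):
        beta = hnn.annealing_beta(1e10, beta0=4.35)
        assert beta == pytest.approx(0.43, abs=0.005)
        assert round(1.0 / beta, 2) == pytest.approx(2.30)


class TestNetworkStructure:
    def test_weight_matrix_symmetric_zero_diagonal(self, rng):
        disp = _map(rng.uniform(0, 6, (10, 10)))
        state = hnn.build_network(disp, hnn.HNNParams())
        for _ in range(3):
            T, _ = hnn._weights_and_bias(state, hnn.HNNParams())
            dense = T.toarray()
            assert np.allclose(dense, dense.T)
            assert np.allclose(np.diag(dense), 0.0)
            hnn.hnn_iterate(state, hnn.HNNParams(inner_steps_K=50))

    def test_inactive_pixels_absent(self):
        values = np.full((6, 6), np.nan)
        values[2, 2] = 3.0
        values[2, 3] = 4.5
        state = hnn.build_network(_map(values), hnn.HNNParams())
        assert state.states_D.size == 2
        assert len(state.edges[0]) == 2  # one mutual neighbour pair


class TestDynamics:
    def test_states_stay_inside_open_interval(self, rng):
        disp = _map(rng.uniform(0, 6, (9, 9)))
        out, state = hnn.hnn_run(disp, hnn.HNNParams(t_max=3, inner_steps_K=200))
        assert np.all(np.abs(state.states_D) < 1.0)

    def test_zero_iterations_is_identity(self, rng):
        vals = rng.uniform(0, 6, (7, 7))
        vals[0, :] = np.nan
        disp = _map(vals)
        out, state = hnn.hnn_run(disp, hnn.HNNParams(t_max=0))
        assert np.allclose(out.values, disp.values, equal_nan=True)

    def test_nulls_never_change(self, rng):
        vals = rng.uniform(0, 6, (9, 9))
        vals[4:, :] = np.nan
        out, _ = hnn.hnn_run(_map(vals), hnn.HNNParams(t_max=2, inner_steps_K=200))
        assert np.all(~np.isfinite(out.values[4:, :]))
        assert np.all(np.isfinite(out.values[:4, :]))

    def test_uniform_midrange_map_is_a_fixed_point(self):
        """All states at 0 (disparity theta_max/2) receive zero input."""
        out, state = hnn.hnn_run(_uniform_map(3.0), hnn.HNNParams(t_max=5))
        assert np.allclose(state.states_D, 0.0, atol=1e-12)

    def test_uniform_saturated_map_stays_on_its_side(self):
        out, state = hnn.hnn_run(_uniform_map(6.0), hnn.HNNParams())
        assert np.all(state.states_D > 0.99)
        assert np.allclose(out.values, 6.0, atol=0.05)

    def test_isolated_node_fixed_point(self):
        """No neighbours: D converges near tanh(B * D / beta) ~ 0.981."""
        values = np.full((5, 5), np.nan)
        values[2, 2] = 6.0
        out, state = hnn.hnn_run(_map(values), hnn.HNNParams(t_max=20, epsilon_conv=1e-4))
        assert state.states_D[0] == pytest.approx(0.981, abs=0.03)

    def test_nonfinite_input_raises_with_context(self):
        state = hnn.build_network(_uniform_map(6.0, (4, 4)), hnn.HNNParams())
        state.inputs_u[0] = np.nan
        with pytest.raises(FloatingPointError, match="iteration"):
            hnn.hnn_iterate(state, hnn.HNNParams(inner_steps_K=1))


def _outlier_map(rng, shape=(20, 20), frac=0.1):
    vals = np.full(shape, 6.0)
    n = vals.size
    idx = rng.choice(n, size=int(frac * n), replace=False)
    flat = vals.ravel()
    flat[idx] = rng.uniform(0.0, 5.0, idx.size)
    return _map(flat.reshape(shape)), idx


class TestSmoothingRegression:
    def test_salt_and_pepper_outliers_pulled_to_local_median(self, rng):
        disp, idx = _outlier_map(rng)
        out, state = hnn.hnn_run(disp, hnn.HNNParams())
        smoothed = out.values.ravel()[idx]
        # the local median of a 10%-outlier field is the plateau value 6.0
        assert np.mean(np.abs(smoothed - 6.0) <= 0.5) >= 0.8

    def test_energy_descends_within_each_outer_iteration(self, rng):
        disp, _ = _outlier_map(rng, shape=(12, 12))
        _, state = hnn.hnn_run(
            disp, hnn.HNNParams(t_max=3, inner_steps_K=200), record_inner_energy=True
        )
        for trace in state.inner_energy:
            span = trace.max() - trace.min()
            slack = max(1e-9 * span, 1e-12)
            assert np.all(np.diff(trace) <= slack)

    def test_energy_trace_flattens_quickly(self, regression_run):
        trace = np.asarray(regression_run["state"].energy_trace)
        assert trace.size <= 10
        if trace.size >= 2:
            initial_drop = abs(trace[1] - trace[0])
            final_change = abs(trace[-1] - trace[-2])
            assert final_change <= max(0.01 * initial_drop, 1e-9)
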