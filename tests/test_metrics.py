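import numpy as np
import pytest

from cardiorom.errors import DegenerateFieldError, ShapeError
from cardiorom.metrics import (
    activation_map,
    ap_trace,
    error_indicator,
    relative_error_field,
    relative_error_means,
    sustained_activity_flag,
)
from cardiorom.solver import Trajectory


def _naive_error_indicator(trues, approxs):
    """Two-loop reference implementation of the scalar indicator."""
    vals = []
    for U, Ua in zip(trues, approxs):
        num = 0.0
        den = 0.0
        for k in range(U.shape[1]):
            num += np.linalg.norm(U[:, k] - Ua[:, k]) ** 2
            den += np.linalg.norm(U[:, k]) ** 2
        vals.append(np.sqrt(num / den))
    return float(np.mean(vals))


def _naive_relative_error_field(k, U, Ua):
    den = 0.0
    for j in range(U.shape[1]):
        den += np.linalg.norm(U[:, j])
    den /= U.shape[1]
    return np.array([abs(U[i, k] - Ua[i, k]) / den for i in range(U.shape[0])])


class TestErrorIndicator:
    def test_identical_fields_zero(self):
        U = np.random.default_rng(0).standard_normal((10, 5))
        assert error_indicator(U, U) == 0.0

    def test_zero_reconstruction_is_one(self):
        U = np.random.default_rng(1).standard_normal((10, 5))
        assert error_indicator(U, np.zeros_like(U)) == pytest.approx(1.0)

    @pytest.mark.parametrize("delta", [0.1, -0.03, 1.7])
    def test_uniform_scaling_gives_abs_delta(self, delta):
        U = np.random.default_rng(2).standard_normal((20, 7))
        assert error_indicator(U, (1 + delta) * U) == pytest.approx(abs(delta))

    def test_matches_two_loop_reference(self):
        rng = np.random.default_rng(3)
        trues = [rng.standard_normal((15, 6)) for _ in range(4)]
        approxs = [U + 0.1 * rng.standard_normal(U.shape) for U in trues]
        fast = error_indicator(trues, approxs)
        slow = _naive_error_indicator(trues, approxs)
        assert abs(fast - slow) < 1e-12

    def test_degenerate_and_shape_errors(self):
        with pytest.raises(DegenerateFieldError):
            error_indicator(np.zeros((4, 3)), np.ones((4, 3)))
        with pytest.raises(ShapeError):
            error_indicator(np.ones((4, 3)), np.ones((4, 2)))


class TestRelativeErrorField:
    def test_identical_gives_zero(self):
        U = np.random.default_rng(4).standard_normal((8, 5))
        assert np.all(relative_error_field(2, U, U) == 0.0)

    def test_single_node_offset(self):
        U = np.random.default_rng(5).standard_normal((8, 5))
        Ua = U.copy()
        Ua[3, 2] += 0.25
        denom = np.mean(np.linalg.norm(U, axis=0))
        eps = relative_error_field(2, U, Ua)
        expected = np.zeros(8)
        expected[3] = 0.25 / denom
        assert np.allclose(eps, expected, atol=1e-14)

    def test_matches_two_loop_reference(self):
        rng = np.random.default_rng(6)
        U = rng.standard_normal((12, 9))
        Ua = U + 0.05 * rng.standard_normal(U.shape)
        for k in (0, 4, 8):
            assert np.max(np.abs(
                relative_error_field(k, U, Ua) - _naive_relative_error_field(k, U, Ua)
            )) < 1e-12

    def test_spatial_means_consistent(self):
        rng = np.random.default_rng(7)
        U = rng.standard_normal((12, 9))
        Ua = U + 0.05 * rng.standard_normal(U.shape)
        means = relative_error_means(U, Ua)
        for k in (0, 3):
            assert means[k] == pytest.approx(relative_error_field(k, U, Ua).mean())


class TestActivationMap:
    def test_unique_peak(self):
        times = np.array([10.0, 12.5, 15.0])
        U = np.array([[0.0, 3.0, 1.0]])
        assert activation_map(U, times)[0] == 12.5

    def test_plateau_takes_earliest(self):
        times = np.array([9.5, 10.0, 10.5, 11.0])
        U = np.array([[0.0, 2.0, 2.0, 1.0]])
        assert activation_map(U, times)[0] == 10.0

    def test_threshold_sentinel(self):
        times = np.array([1.0, 2.0])
        U = np.array([[0.5, 0.2], [5.0, 1.0]])
        ac = activation_map(U, times, threshold=1.0)
        assert np.isnan(ac[0]) and ac[1] == 1.0

    def test_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(8)
        U = rng.standard_normal((6, 10))
        times = np.linspace(1, 10, 10)
        base = activation_map(U, times)
        rescaled = activation_map(3.0 * U + 7.0, times)
        assert np.array_equal(base, rescaled)


class TestApTrace:
    def test_zero_trajectory_zero_trace(self, unit_space):
        traj = Trajectory(mu=None, times=np.arange(1.0, 4.0),
                          u=np.zeros((unit_space.N_h, 3)),
                          ue=np.zeros((unit_space.N_h, 3)))
        u_tr, ue_tr = ap_trace((0.5, 0.5), traj, unit_space)
        assert np.all(u_tr == 0.0) and np.all(ue_tr == 0.0)

    def test_matches_basis_weighted_evaluation(self, unit_space):
        from cardiorom.splines import evaluate_basis
        rng = np.random.default_rng(9)
        traj = Trajectory(mu=None, times=np.arange(1.0, 5.0),
                          u=rng.standard_normal((unit_space.N_h, 4)),
                          ue=rng.standard_normal((unit_space.N_h, 4)))
        pt = (0.37, 0.81)
        u_tr, _ = ap_trace(pt, traj, unit_space)
        B, _, _ = evaluate_basis(unit_space, [list(pt)])
        assert np.max(np.abs(u_tr - (B.toarray()[0] @ traj.u))) < 1e-12


class TestSustainedActivity:
    def _traj(self, maxvals):
        n_t = len(maxvals)
        u = np.zeros((3, n_t))
        u[0] = maxvals
        return Trajectory(mu=None, times=np.arange(1.0, n_t + 1.0),
                          u=u, ue=np.zeros_like(u))

    def test_quiescent_false(self):
        assert not sustained_activity_flag(self._traj([0.0] * 5), 2.0, 1.0)

    def test_repolarized_false(self):
        # active early, silent after t_check
        assert not sustained_activity_flag(self._traj([50, 40, 0.5, 0.2, 0.1]), 3.0, 1.0)

    def test_persistent_true(self):
        assert sustained_activity_flag(self._traj([50, 40, 30, 20, 15]), 3.0, 1.0)

    def test_t_check_outside_window(self):
        with pytest.raises(ShapeError):
            sustained_activity_flag(self._traj([1, 2, 3]), 99.0, 0.5)
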