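import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiorom.errors import DegenerateFieldError, RankDeficiencyError, ShapeError
from cardiorom.pod import (
    build_snapshot_matrix,
    lift,
    project,
    projection_error_indicator,
    randomized_pod,
)
from cardiorom.solver import Trajectory


def _traj(mu, n_h=12, n_t=3, seed=0):
    rng = np.random.default_rng(seed)
    times = np.arange(1, n_t + 1, dtype=float)
    return Trajectory(mu=np.atleast_1d(mu), times=times,
                      u=rng.standard_normal((n_h, n_t)),
                      ue=rng.standard_normal((n_h, n_t)))


def _decaying_matrix(n_rows, n_cols, seed, decay=2.0):
    rng = np.random.default_rng(seed)
    U, _ = np.linalg.qr(rng.standard_normal((n_rows, n_cols)))
    W, _ = np.linalg.qr(rng.standard_normal((n_cols, n_cols)))
    s = decay ** (-np.arange(n_cols, dtype=float))
    return U @ (s[:, None] * W.T)


class TestSnapshotMatrix:
    def test_column_order_and_labels(self):
        trajs = [_traj(0.1, seed=1), _traj(0.2, seed=2)]
        snaps = build_snapshot_matrix(trajs, ("u", "ue"))
        assert snaps.channels["u"].shape == (12, 6)
        assert snaps.n_s == 6 and snaps.n_train == 2 and snaps.n_t == 3
        # mu-major, time-minor ordering
        assert np.allclose(snaps.channels["u"][:, :3], trajs[0].u)
        assert np.allclose(snaps.mus[:3], 0.1) and np.allclose(snaps.mus[3:], 0.2)

    def test_single_trajectory_time_order(self):
        tr = _traj(0.5, seed=3)
        snaps = build_snapshot_matrix([tr], ("u",))
        assert np.allclose(snaps.channels["u"], tr.u)

    def test_duplicate_trajectory_rejected(self):
        tr = _traj(0.1, seed=1)
        with pytest.raises(ShapeError):
            build_snapshot_matrix([tr, tr], ("u",))

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ShapeError):
            build_snapshot_matrix([_traj(0.1, n_h=12), _traj(0.2, n_h=10)], ("u",))


class TestRandomizedPOD:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(50), rng.standard_normal(30)
        basis = randomized_pod(np.outer(a, b), 1, seed=2)
        assert basis.sigma[0] == pytest.approx(
            np.linalg.norm(a) * np.linalg.norm(b), abs=1e-10)
        S = np.outer(a, b)
        resid = S - basis.V @ (basis.V.T @ S)
        assert np.linalg.norm(resid) < 1e-10

    def test_matches_full_svd_on_decaying_spectrum(self):
        S = _decaying_matrix(200, 100, seed=0)
        basis = randomized_pod(S, 10, oversampling=10, n_power_iter=2, seed=1)
        ref = np.linalg.svd(S, compute_uv=False)[:10]
        assert np.max(np.abs(basis.sigma - ref) / ref) < 1e-8

    def test_deterministic_given_seed(self):
        S = _decaying_matrix(60, 40, seed=2)
        b1 = randomized_pod(S, 5, seed=7)
        b2 = randomized_pod(S, 5, seed=7)
        assert np.array_equal(b1.V, b2.V) and np.array_equal(b1.sigma, b2.sigma)

    def test_sign_convention(self):
        S = _decaying_matrix(60, 40, seed=3)
        basis = randomized_pod(S, 5, seed=0)
        idx = np.argmax(np.abs(basis.V), axis=0)
        assert np.all(basis.V[idx, np.arange(5)] > 0)

    def test_rank_deficiency_refused(self):
        rng = np.random.default_rng(6)
        S = rng.standard_normal((40, 3)) @ rng.standard_normal((3, 25))
        with pytest.raises(RankDeficiencyError):
            randomized_pod(S, 10, seed=0)
        with pytest.raises(RankDeficiencyError):
            randomized_pod(S, 30, seed=0)   # N > min(shape)


class TestProjectLift:
    @given(seed=st.integers(0, 100))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_projection_properties(self, seed):
        S = _decaying_matrix(40, 30, seed=seed)
        basis = randomized_pod(S, 6, seed=0)
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        coords = project(basis, x)
        assert np.linalg.norm(coords) <= np.linalg.norm(x) + 1e-12
        # lift(project(.)) is the orthogonal projection: idempotent
        proj_x = lift(basis, coords)
        assert np.allclose(project(basis, proj_x), coords, atol=1e-10)

    def test_in_span_and_orthogonal(self):
        S = _decaying_matrix(40, 30, seed=1)
        basis = randomized_pod(S, 6, seed=0)
        y = basis.V @ np.arange(1.0, 7.0)
        assert np.allclose(lift(basis, project(basis, y)), y, atol=1e-10)
        # a vector orthogonal to span(V) projects to zero
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        x -= basis.V @ (basis.V.T @ x)
        assert np.max(np.abs(project(basis, x))) < 1e-10

    def test_shape_mismatch(self):
        S = _decaying_matrix(40, 30, seed=1)
        basis = randomized_pod(S, 6, seed=0)
        with pytest.raises(ShapeError):
            project(basis, np.zeros(39))
        with pytest.raises(ShapeError):
            lift(basis, np.zeros(5))


class TestProjectionErrorIndicator:
    def test_exact_span_gives_zero(self):
        S = _decaying_matrix(40, 10, seed=4)
        basis = randomized_pod(S, 10, seed=0)
        assert projection_error_indicator(basis, [S]) < 1e-10

    def test_empty_basis_gives_one(self):
        S = _decaying_matrix(40, 10, seed=4)
        assert projection_error_indicator(np.zeros((40, 0)), [S]) == pytest.approx(1.0)

    def test_monotone_in_basis_dimension(self):
        S = _decaying_matrix(80, 60, seed=5, decay=1.2)
        tests = [_decaying_matrix(80, 7, seed=9, decay=1.2)]
        vals = [projection_error_indicator(randomized_pod(S, N, seed=0), tests)
                for N in (4, 8, 16)]
        assert vals[0] > vals[1] > vals[2]

    def test_lower_bound_for_any_lifted_reconstruction(self):
        # projection is the per-snapshot best approximation in span(V)
        from cardiorom.metrics import error_indicator
        S = _decaying_matrix(50, 40, seed=6, decay=1.3)
        basis = randomized_pod(S, 8, seed=0)
        U = _decaying_matrix(50, 12, seed=11, decay=1.3)
        proj_eps = projection_error_indicator(basis, [U])
        rng = np.random.default_rng(3)
        for _ in range(5):
            coords = basis.V.T @ U + 0.1 * rng.standard_normal((8, 12))
            eps = error_indicator([U], [basis.V @ coords])
            assert eps >= proj_eps - 1e-12

    def test_degenerate_inputs(self):
        basis = randomized_pod(_decaying_matrix(20, 10, seed=7), 3, seed=0)
        with pytest.raises(DegenerateFieldError):
            projection_error_indicator(basis, [])
        with pytest.raises(DegenerateFieldError):
            projection_error_indicator(basis, [np.zeros((20, 4))])
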