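import numpy as np
import pytest

from cardiorom.errors import InvalidInputError, ShapeError
from cardiorom.pod import randomized_pod
from cardiorom.rom import (
    ArchitectureConfig,
    MinMaxStats,
    TrainingConfig,
    denormalize,
    flatten_from_grid,
    normalize,
    per_example_loss,
    predict,
    reshape_to_grid,
    train,
)


class TestNormalization:
    def test_extremes_map_to_unit_interval(self):
        stats = MinMaxStats.fit(np.array([[2.0, -1.0], [6.0, 3.0], [4.0, 1.0]]))
        low = normalize(np.array([2.0, -1.0]), stats)
        high = normalize(np.array([6.0, 3.0]), stats)
        assert np.allclose(low, 0.0) and np.allclose(high, 1.0)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((50, 4)) * 10
        stats = MinMaxStats.fit(data)
        assert np.max(np.abs(denormalize(normalize(data, stats), stats) - data)) < 1e-12

    def test_degenerate_channel_maps_to_half(self):
        with pytest.warns(UserWarning):
            stats = MinMaxStats.fit(np.full((10, 1), 3.0))
        assert np.allclose(normalize(np.full(4, 3.0), stats), 0.5)
        assert np.allclose(denormalize(np.full(4, 0.5), stats), 3.0)


class TestGridReshape:
    def test_shape_and_row_major(self):
        grid = reshape_to_grid(np.arange(4.0), 4, 1)
        assert grid.shape == (2, 2, 1)
        assert np.array_equal(grid[:, :, 0], [[0.0, 1.0], [2.0, 3.0]])

    def test_two_channel_example(self):
        grid = reshape_to_grid(np.arange(512.0), 256, 2)
        assert grid.shape == (16, 16, 2)
        # channel 0 holds the first 256 coordinates
        assert grid[0, 0, 0] == 0.0 and grid[0, 0, 1] == 256.0

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        coords = rng.standard_normal((5, 18))   # batch of N=9, d=2
        grid = reshape_to_grid(coords, 9, 2)
        assert np.array_equal(flatten_from_grid(grid), coords)

    def test_non_square_rejected(self):
        with pytest.raises(ShapeError):
            reshape_to_grid(np.arange(12.0), 12, 1)


class TestLoss:
    def test_perfect_match_is_zero(self):
        y = np.ones((3, 8))
        z = np.ones((3, 2))
        assert per_example_loss(y, y, z, z, 0.5) == 0.0

    def test_omega_extremes_select_terms(self):
        rng = np.random.default_rng(2)
        y, yhat = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        ze, zd = rng.standard_normal((4, 2)), rng.standard_normal((4, 2))
        rec = 0.5 * np.mean(np.sum((y - yhat) ** 2, axis=1))
        lat = 0.5 * np.mean(np.sum((ze - zd) ** 2, axis=1))
        assert per_example_loss(y, yhat, ze, zd, 1.0) == pytest.approx(rec)
        assert per_example_loss(y, yhat, ze, zd, 0.0) == pytest.approx(lat)
        assert per_example_loss(y, yhat, ze, zd, 0.3) == pytest.approx(
            0.3 * rec + 0.7 * lat)

    def test_omega_out_of_range(self):
        y = np.zeros((1, 4))
        z = np.zeros((1, 2))
        with pytest.raises(InvalidInputError):
            per_example_loss(y, y, z, z, 1.5)


def _toy_dataset(seed=0):
    """Snapshots G c(t, mu) with a smooth rank-4 coefficient manifold."""
    rng = np.random.default_rng(seed)
    ts = np.linspace(0, 1, 40)
    mus = np.linspace(0.5, 1.5, 6)
    T, M = np.meshgrid(ts, mus, indexing="ij")
    t, m = T.ravel(), M.ravel()
    C = np.vstack([np.sin(2 * np.pi * t) * m, np.cos(2 * np.pi * t) + m,
                   t * m, t ** 2])
    G = rng.standard_normal((500, 4))
    snaps = G @ C
    X = np.column_stack([t, m])
    return X, snaps, G, ts, mus


class TestTraining:
    def test_learns_low_dimensional_manifold(self):
        """On snapshots with exact latent dimension 2, the surrogate
        reconstructs held-out parameter instances to ~1% field error."""
        from cardiorom.metrics import error_indicator
        X, snaps, G, ts, mus = _toy_dataset()
        basis = randomized_pod(snaps, 4, seed=4)
        Y = (basis.V.T @ snaps).T
        cfg = TrainingConfig(n_epochs=6000, batch_size=40, lr=1e-2, lr_final=1e-4,
                             patience=5999, val_fraction=0.2, seed=0)
        nets, hist = train(X, Y, n=2, N=4, channel_names=("u",), cfg=cfg)
        assert hist["best_val"] < 1e-2 * hist["val"][0]
        mu_t = 1.05
        truth = G @ np.array([
            [np.sin(2 * np.pi * t) * mu_t, np.cos(2 * np.pi * t) + mu_t,
             t * mu_t, t ** 2] for t in ts]).T
        pred = predict(nets, {"u": basis}, ts, [mu_t])
        assert error_indicator(truth, pred["u"]) < 2e-2

    def test_early_stopping_halts_before_budget(self):
        rng = np.random.default_rng(3)
        X = rng.random((60, 2))
        Y = rng.standard_normal((60, 4))      # pure noise: nothing to learn
        cfg = TrainingConfig(n_epochs=400, batch_size=20, lr=1e-3,
                             patience=10, val_fraction=0.2, seed=0)
        _, hist = train(X, Y, n=3, N=4, channel_names=("u",), cfg=cfg)
        assert len(hist["train"]) < 400

    def test_deterministic_given_seed(self):
        X, snaps, *_ = _toy_dataset()
        basis = randomized_pod(snaps, 4, seed=4)
        Y = (basis.V.T @ snaps).T
        cfg = TrainingConfig(n_epochs=50, batch_size=40, lr=1e-3,
                             patience=49, seed=11)
        _, h1 = train(X, Y, n=2, N=4, channel_names=("u",), cfg=cfg)
        _, h2 = train(X, Y, n=2, N=4, channel_names=("u",), cfg=cfg)
        assert h1["train"] == h2["train"] and h1["val"] == h2["val"]

    def test_latent_dimension_floor(self):
        X, snaps, *_ = _toy_dataset()
        basis = randomized_pod(snaps, 4, seed=4)
        Y = (basis.V.T @ snaps).T
        cfg = TrainingConfig(n_epochs=10, patience=5, seed=0)
        with pytest.raises(InvalidInputError):
            train(X, Y, n=1, N=4, channel_names=("u",), cfg=cfg)  # n < n_mu + 1


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self):
        X, snaps, G, ts, mus = _toy_dataset()
        basis = randomized_pod(snaps, 4, seed=4)
        Y = (basis.V.T @ snaps).T
        cfg = TrainingConfig(n_epochs=300, batch_size=40, lr=3e-3,
                             patience=299, seed=0)
        nets, _ = train(X, Y, n=2, N=4, channel_names=("u",), cfg=cfg)
        return nets, basis, ts

    def test_output_length_is_field_dimension(self, trained):
        nets, basis, ts = trained
        out = predict(nets, {"u": basis}, 0.5, [1.0])
        assert out["u"].shape == (500,)

    def test_batch_equals_looped_single_predictions(self, trained):
        nets, basis, ts = trained
        batch = predict(nets, {"u": basis}, ts[:5], [1.0])["u"]
        for k, t in enumerate(ts[:5]):
            single = predict(nets, {"u": basis}, t, [1.0])["u"]
            # single-precision network arithmetic: row-count-dependent BLAS
            # kernels may differ at the last float32 bit
            assert np.allclose(batch[:, k], single, atol=1e-5, rtol=1e-5)

    def test_extrapolation_warns_but_returns(self, trained):
        nets, basis, _ = trained
        with pytest.warns(UserWarning, match="extrapolat"):
            out = predict(nets, {"u": basis}, 5.0, [1.0])
        assert np.all(np.isfinite(out["u"]))
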