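"""POD-enhanced deep-learning reduced-order model (autoencoder + DFNN).

The surrogate approximates the map ``(t, mu) -> V^T u_h(t; mu)`` from the
``N``-dimensional intrinsic (POD) coordinates of the training snapshots:

* an *encoder* compresses intrinsic coordinates to ``n``-dimensional latent
  (minimal) coordinates, ``n`` close to the intrinsic dimension
  ``n_mu + 1`` of the solution manifold (time acts as one extra coordinate);
* a *deep feedforward network* (DFNN) maps the normalized pair ``(t, mu)``
  directly to latent coordinates — the reduced dynamics;
* a *decoder* expands latent coordinates back to intrinsic coordinates — the
  nonlinear trial manifold.

Training minimizes, over all (t, mu) training pairs, the per-example loss

    L = omega_h/2 ||V^T u_h - u~_N||^2 + (1 - omega_h)/2 ||u~_n - u_n||^2

(reconstruction through DFNN+decoder, plus encoder/DFNN latent consistency).
At prediction time the encoder is discarded: ``u~_h = V decoder(dfnn(t, mu))``
per channel, so the online cost is independent of N_h except the final lift.

The ``d`` field channels (u, ue) are min-max normalized per channel; the
intrinsic coordinates of the channels are stacked and can be viewed as a
``sqrt(N) x sqrt(N) x d`` grid (N must be a perfect square).  Networks here
are dense stacks on the flattened grid (widths configurable); at intrinsic
scale (N <= 256) this matches the capacity a small convolutional
autoencoder would provide, with a far simpler dependency footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, ShapeError, TrainingError
from .nn import MLP, Adam, FourierLift
from .pod import PODBasis, SnapshotSet

__all__ = [
    "MinMaxStats",
    "normalize",
    "denormalize",
    "reshape_to_grid",
    "flatten_from_grid",
    "per_example_loss",
    "ArchitectureConfig",
    "TrainingConfig",
    "ROMNetworks",
    "intrinsic_dataset",
    "train",
    "predict",
]


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MinMaxStats:
    """Per-coordinate training min/max defining an affine map onto [0, 1].

    Degenerate coordinates (max == min) map to the constant 0.5.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray, axis=0) -> "MinMaxStats":
        v = np.asarray(values, dtype=float)
        mins = np.atleast_1d(v.min(axis=axis))
        maxs = np.atleast_1d(v.max(axis=axis))
        if np.any(maxs == mins):
            warnings.warn("degenerate (constant) coordinate in normalization stats")
        return cls(mins=mins, maxs=maxs)

    @property
    def span(self) -> np.ndarray:
        return np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)


def normalize(values: np.ndarray, stats: MinMaxStats) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    out = (v - stats.mins) / stats.span
    return np.where(stats.maxs == stats.mins, 0.5, out)


def denormalize(values: np.ndarray, stats: MinMaxStats) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return np.where(stats.maxs == stats.mins, stats.mins, v * stats.span + stats.mins)


# --------------------------------------------------------------------------
# grid reshape
# --------------------------------------------------------------------------

def _grid_side(N: int) -> int:
    side = int(round(np.sqrt(N)))
    if side * side != N:
        raise ShapeError(f"N={N} is not a perfect square; cannot form a grid")
    return side


def reshape_to_grid(coords: np.ndarray, N: int, d: int) -> np.ndarray:
    """View stacked intrinsic coordinates (length N*d) as a (sqrt(N), sqrt(N), d) grid.

    Row-major per channel; exact inverse of :func:`flatten_from_grid`.
    """
    c = np.asarray(coords)
    if c.shape[-1] != N * d:
        raise ShapeError(f"expected last dimension {N * d}, got {c.shape[-1]}")
    side = _grid_side(N)
    chans = c.reshape(c.shape[:-1] + (d, side, side))
    return np.moveaxis(chans, -3, -1)


def flatten_from_grid(grid: np.ndarray) -> np.ndarray:
    g = np.asarray(grid)
    side1, side2, d = g.shape[-3:]
    chans = np.moveaxis(g, -1, -3)
    return chans.reshape(g.shape[:-3] + (d * side1 * side2,))


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def per_example_loss(
    true_intrinsic: np.ndarray,
    predicted_intrinsic: np.ndarray,
    encoded_latent: np.ndarray,
    dfnn_latent: np.ndarray,
    omega_h: float,
) -> float:
    """Joint reconstruction + latent-consistency loss (mean over examples).

    ``omega_h/2 ||V^T u - u~_N||^2 + (1-omega_h)/2 ||u~_n - u_n||^2``;
    for batched inputs the mean over rows is returned (the total training
    objective is the mean over all N_s training pairs).
    """
    if not (0.0 <= omega_h <= 1.0):
        raise InvalidInputError("omega_h must lie in [0, 1]")
    yt = np.atleast_2d(true_intrinsic)
    yp = np.atleast_2d(predicted_intrinsic)
    ze = np.atleast_2d(encoded_latent)
    zd = np.atleast_2d(dfnn_latent)
    rec = 0.5 * np.sum((yt - yp) ** 2, axis=1)
    lat = 0.5 * np.sum((ze - zd) ** 2, axis=1)
    return float(np.mean(omega_h * rec + (1.0 - omega_h) * lat))


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureConfig:
    """Layer widths of the three networks (hidden layers only).

    ``decoder_fourier_modes`` prepends a sinusoidal feature lift to the
    decoder input: intrinsic coordinates of travelling fronts oscillate
    along the latent phase coordinate, and the lift removes the dense
    stack's bias against such maps (0 disables it).
    """

    encoder_widths: tuple = (64,)
    dfnn_widths: tuple = (50, 50)
    decoder_widths: tuple = (64,)
    decoder_fourier_modes: int = 8


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings for the joint autoencoder / DFNN training."""

    n_epochs: int = 3000
    batch_size: int = 40
    lr: float = 1e-3
    lr_final: float | None = None    # exponential decay target over n_epochs
    patience: int = 500
    omega_h: float = 0.5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.omega_h <= 1.0):
            raise InvalidInputError("omega_h must lie in [0, 1]")
        if not (0 < self.val_fraction < 1):
            raise InvalidInputError("val_fraction must lie in (0, 1)")
        if self.patience >= self.n_epochs:
            raise InvalidInputError("patience must be smaller than n_epochs")


@dataclass
class ROMNetworks:
    """Trained networks plus the normalization statistics they assume.

    ``output_stats`` holds one scalar (min, max) pair per field channel,
    applied to all N intrinsic coordinates of the channel (fitted on the
    training split only), preserving the coordinates' relative scales.
    """

    encoder: MLP
    dfnn: MLP
    decoder: MLP
    n: int
    N: int
    d: int
    channel_names: tuple
    input_stats: MinMaxStats
    output_stats: dict              # channel -> MinMaxStats (scalar per channel)
    decoder_fourier_modes: int = 0

    def __post_init__(self):
        _grid_side(self.N)      # N must be a perfect square
        n_cond = len(self.input_stats.mins)
        if self.n < n_cond:
            raise InvalidInputError(
                f"latent dimension n={self.n} below intrinsic dimension "
                f"n_mu+1={n_cond} of the solution manifold"
            )

    # -- normalized-space passes (training / diagnostics) -------------------
    def encode_normalized(self, y: np.ndarray) -> np.ndarray:
        return self.encoder(y)

    def dynamics_normalized(self, x: np.ndarray) -> np.ndarray:
        return self.dfnn(x)

    def decode_normalized(self, z: np.ndarray) -> np.ndarray:
        return self.decoder(self.decoder_lift(z))

    @property
    def decoder_lift(self) -> FourierLift:
        lift = getattr(self, "_decoder_lift", None)
        if lift is None:
            lift = FourierLift(self.n, self.decoder_fourier_modes)
            object.__setattr__(self, "_decoder_lift", lift)
        return lift


def intrinsic_dataset(
    snapshots: SnapshotSet,
    bases: dict,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Project snapshots to stacked per-channel intrinsic coordinates.

    Returns ``(X, Y, channel_names)``: X rows are (t, mu_1..mu_p); Y rows
    are the concatenated V_c^T u_c over channels c (length N*d).
    """
    names = snapshots.channel_names
    blocks = []
    for ch in names:
        V = bases[ch].V
        blocks.append((V.T @ snapshots.channels[ch]).T)    # (N_s, N)
    Y = np.concatenate(blocks, axis=1)
    X = np.column_stack([snapshots.times, snapshots.mus])
    return X, Y, names


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _normalize_outputs(Y: np.ndarray, stats: dict, names, N: int) -> np.ndarray:
    out = np.empty_like(Y)
    for j, ch in enumerate(names):
        sl = slice(j * N, (j + 1) * N)
        out[:, sl] = normalize(Y[:, sl], stats[ch])
    return out


def _denormalize_outputs(Yn: np.ndarray, stats: dict, names, N: int) -> np.ndarray:
    out = np.empty_like(Yn)
    for j, ch in enumerate(names):
        sl = slice(j * N, (j + 1) * N)
        out[:, sl] = denormalize(Yn[:, sl], stats[ch])
    return out


def train(
    X: np.ndarray,
    Y: np.ndarray,
    n: int,
    N: int,
    channel_names: Sequence[str],
    cfg: TrainingConfig,
    arch: ArchitectureConfig = ArchitectureConfig(),
) -> tuple[ROMNetworks, dict]:
    """Train encoder, DFNN and decoder jointly on intrinsic coordinates.

    ``X``: (N_s, 1+n_mu) raw (t, mu) pairs; ``Y``: (N_s, N*d) raw stacked
    intrinsic coordinates.  A seed-fixed validation split of (t, mu) pairs
    is held out; normalization statistics come from the training split only.
    Early stopping restores the best-validation parameters.  Returns the
    networks and the full loss history.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ShapeError("X and Y row counts differ")
    d = len(channel_names)
    if Y.shape[1] != N * d:
        raise ShapeError(f"Y must have N*d = {N * d} columns")

    rng = np.random.default_rng(cfg.seed)
    n_s = X.shape[0]
    perm = rng.permutation(n_s)
    n_val = max(1, int(round(cfg.val_fraction * n_s)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    in_stats = MinMaxStats.fit(X[tr_idx])
    # one scalar range per channel: preserves the relative scales of the POD
    # coordinates, so the normalized loss stays proportional to the field
    # reconstruction error (trailing modes carry proportionally small weight)
    out_stats = {
        ch: MinMaxStats.fit(Y[tr_idx, j * N:(j + 1) * N].ravel())
        for j, ch in enumerate(channel_names)
    }
    Xn = normalize(X, in_stats)
    Yn = _normalize_outputs(Y, out_stats, channel_names, N)
    Xtr, Ytr = Xn[tr_idx], Yn[tr_idx]
    Xva, Yva = Xn[val_idx], Yn[val_idx]

    encoder = MLP((N * d, *arch.encoder_widths, n), rng)
    dfnn = MLP((X.shape[1], *arch.dfnn_widths, n), rng)
    lift = FourierLift(n, arch.decoder_fourier_modes)
    decoder = MLP((lift.out_dim, *arch.decoder_widths, N * d), rng)
    opt = Adam(encoder.params + dfnn.params + decoder.params, lr=cfg.lr)
    omega = cfg.omega_h

    def eval_loss(Xb, Yb) -> float:
        z_enc = encoder(Yb)
        z_dyn = dfnn(Xb)
        y_hat = decoder(lift(z_dyn))
        return per_example_loss(Yb, y_hat, z_enc, z_dyn, omega)

    history = {"train": [], "val": []}
    best_val = np.inf
    best_epoch = -1
    best_state = None
    n_tr = len(tr_idx)

    decay = (
        (cfg.lr_final / cfg.lr) ** (1.0 / max(cfg.n_epochs - 1, 1))
        if cfg.lr_final else 1.0
    )

    for epoch in range(cfg.n_epochs):
        opt.lr = cfg.lr * decay ** epoch
        order = rng.permutation(n_tr)
        running = 0.0
        for start in range(0, n_tr, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            Xb, Yb = Xtr[sel], Ytr[sel]
            b = len(sel)
            z_enc = encoder(Yb)
            z_dyn = dfnn(Xb)
            y_hat = decoder(lift(z_dyn))
            rec = Yb - y_hat
            lat = z_enc - z_dyn
            loss = per_example_loss(Yb, y_hat, z_enc, z_dyn, omega)
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged at epoch {epoch}")
            running += loss * b
            # gradients of the batch-mean loss
            g_dec_in = lift.backward(decoder.backward(-omega * rec / b))
            dfnn.backward(g_dec_in + (1.0 - omega) * (z_dyn - z_enc) / b)
            encoder.backward((1.0 - omega) * lat / b)
            opt.step(encoder.grads + dfnn.grads + decoder.grads)
        history["train"].append(running / n_tr)
        val = eval_loss(Xva, Yva)
        history["val"].append(val)
        if val < best_val:
            best_val = val
            best_epoch = epoch
            best_state = (encoder.state(), dfnn.state(), decoder.state())
        elif epoch - best_epoch >= cfg.patience:
            break

    encoder.load_state(best_state[0])
    dfnn.load_state(best_state[1])
    decoder.load_state(best_state[2])
    history["best_epoch"] = best_epoch
    history["best_val"] = best_val

    nets = ROMNetworks(
        encoder=encoder, dfnn=dfnn, decoder=decoder,
        n=n, N=N, d=d, channel_names=tuple(channel_names),
        input_stats=in_stats, output_stats=out_stats,
        decoder_fourier_modes=arch.decoder_fourier_modes,
    )
    return nets, history


# --------------------------------------------------------------------------
# online prediction
# --------------------------------------------------------------------------

def predict(
    nets: ROMNetworks,
    bases: dict,
    t,
    mu=None,
    return_intrinsic: bool = False,
):
    """Reconstructed fields at (t, mu): normalize -> DFNN -> decoder ->
    denormalize -> lift with the per-channel POD bases.  No encoder is
    involved; the cost is independent of N_h until the final lift.

    ``t`` may be a scalar or an array of times (batch prediction); ``mu`` a
    parameter vector shared by all times.  Queries outside the training
    range warn (extrapolation) but do not fail.  Returns a dict
    ``channel -> (N_h,) or (N_h, n_t) array``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    mu_arr = np.zeros((len(t_arr), 0)) if mu is None else np.tile(
        np.atleast_1d(np.asarray(mu, dtype=float)), (len(t_arr), 1)
    )
    X = np.column_stack([t_arr, mu_arr])
    if X.shape[1] != len(nets.input_stats.mins):
        raise ShapeError("(t, mu) dimension does not match the trained networks")
    Xn = normalize(X, nets.input_stats)
    if np.any(Xn < -1e-9) or np.any(Xn > 1.0 + 1e-9):
        warnings.warn("(t, mu) outside the training range: extrapolating")
    z = nets.dfnn(Xn)
    Yn = nets.decode_normalized(z)
    Yr = _denormalize_outputs(Yn, nets.output_stats, nets.channel_names, nets.N)
    out = {}
    for j, ch in enumerate(nets.channel_names):
        coords = Yr[:, j * nets.N:(j + 1) * nets.N].T    # (N, n_t)
        fields = bases[ch].V @ coords
        out[ch] = fields[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else fields
    if return_intrinsic:
        return out, Yr
    return out
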