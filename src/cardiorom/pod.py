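"""Snapshot matrices and randomized proper orthogonal decomposition.

The full-order trajectories sampled over ``N_train`` parameter instances and
``N_t`` time instances are collected column-wise into a snapshot matrix
``S`` of shape ``(N_h, N_s)`` with ``N_s = N_train * N_t`` (one matrix per
field channel; the transmembrane and extracellular potentials have different
scales and each gets its own orthonormal basis).  The rank-``N`` POD basis
``V`` holds the leading left singular vectors of ``S``, computed with the
Halko-style randomized SVD: a Gaussian range finder with oversampling and a
few subspace (power) iterations with re-orthonormalization.  Snapshots are
not centered: the basis projects the raw fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateFieldError, RankDeficiencyError, ShapeError
from .solver import Trajectory

__all__ = [
    "SnapshotSet",
    "PODBasis",
    "build_snapshot_matrix",
    "randomized_pod",
    "project",
    "lift",
    "projection_error_indicator",
]


@dataclass
class SnapshotSet:
    """Per-channel snapshot matrices with (mu, t) column labels.

    Columns are ordered parameter-major, time-minor; all channels share the
    same labels.  ``n_train`` and ``n_t`` record the design that produced
    the columns.
    """

    channels: dict               # name -> (N_h, N_s) array
    times: np.ndarray            # (N_s,)
    mus: np.ndarray              # (N_s, n_mu)
    n_train: int
    n_t: int

    @property
    def n_s(self) -> int:
        return int(self.times.shape[0])

    @property
    def channel_names(self) -> tuple:
        return tuple(self.channels.keys())


@dataclass
class PODBasis:
    """Orthonormal POD basis of one field channel.

    ``V`` has orthonormal columns (sign-fixed: the largest-magnitude entry
    of each column is positive); ``sigma`` the corresponding singular
    values, non-increasing.
    """

    V: np.ndarray                # (N_h, N)
    sigma: np.ndarray            # (N,)
    channel: str = "u"
    oversampling: int = 10
    n_power_iter: int = 2
    seed: int = 0

    @property
    def N(self) -> int:
        return int(self.V.shape[1])

    def __post_init__(self):
        if self.V.ndim != 2:
            raise ShapeError("V must be a matrix")
        if self.N > 0:
            gram = self.V.T @ self.V
            if np.linalg.norm(gram - np.eye(self.N)) > 1e-10:
                raise ShapeError("POD basis columns are not orthonormal")
        if np.any(np.diff(self.sigma) > 1e-12 * max(self.sigma[0], 1.0) if self.N > 1 else [False]):
            raise ShapeError("singular values must be non-increasing")


def build_snapshot_matrix(
    trajectories: Sequence[Trajectory],
    channels: Sequence[str] = ("u", "ue"),
) -> SnapshotSet:
    """Stack trajectories into per-channel snapshot matrices.

    All trajectories must share ``N_h`` and the sampled times; duplicate
    (mu, t) column labels (e.g. the same trajectory appended twice) are an
    error.
    """
    if not trajectories:
        raise ShapeError("no trajectories given")
    t0 = trajectories[0]
    for tr in trajectories[1:]:
        if tr.u.shape[0] != t0.u.shape[0]:
            raise ShapeError("trajectories disagree on N_h")
        if tr.times.shape != t0.times.shape or not np.allclose(tr.times, t0.times):
            raise ShapeError("trajectories disagree on sampled times")
    mus = []
    for tr in trajectories:
        mu = np.zeros(0) if tr.mu is None else np.atleast_1d(tr.mu)
        mus.append(mu)
    n_mu = max((len(m) for m in mus), default=0)
    if any(len(m) not in (0, n_mu) for m in mus):
        raise ShapeError("trajectories disagree on parameter dimension")
    mu_rows = np.array([np.pad(m, (0, n_mu - len(m))) for m in mus])
    if len({tuple(r) for r in mu_rows}) != len(mu_rows):
        raise ShapeError("duplicate parameter labels across trajectories")

    n_t = len(t0.times)
    mats = {}
    for ch in channels:
        cols = [getattr(tr, ch) for tr in trajectories]
        mats[ch] = np.concatenate(cols, axis=1)
    times = np.tile(t0.times, len(trajectories))
    mus_full = np.repeat(mu_rows, n_t, axis=0)
    return SnapshotSet(
        channels=mats, times=times, mus=mus_full,
        n_train=len(trajectories), n_t=n_t,
    )


def _fix_signs(V: np.ndarray) -> np.ndarray:
    if V.shape[1] == 0:
        return V
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def randomized_pod(
    S: np.ndarray,
    N: int,
    oversampling: int = 10,
    n_power_iter: int = 2,
    seed: int = 0,
    channel: str = "u",
) -> PODBasis:
    """Leading-``N`` left singular subspace of ``S`` by randomized SVD.

    Gaussian test matrix with ``N + oversampling`` columns drawn from
    ``seed``; ``n_power_iter`` subspace iterations with QR
    re-orthonormalization; then an exact SVD of the small projected matrix.
    Deterministic given the seed.  Raises if ``N`` exceeds the numerical
    rank (the basis is never padded).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ShapeError("snapshot matrix must be 2-D")
    n_rows, n_cols = S.shape
    if N > min(n_rows, n_cols):
        raise RankDeficiencyError(
            f"N={N} exceeds min(N_h, N_s)={min(n_rows, n_cols)}"
        )
    rng = np.random.default_rng(seed)
    k = min(N + oversampling, n_cols)
    omega = rng.standard_normal((n_cols, k))
    Y = S @ omega
    Q, _ = np.linalg.qr(Y)
    for _ in range(n_power_iter):
        Z, _ = np.linalg.qr(S.T @ Q)
        Q, _ = np.linalg.qr(S @ Z)
    B = Q.T @ S
    Ub, sig, _ = np.linalg.svd(B, full_matrices=False)
    rank_tol = max(n_rows, n_cols) * np.finfo(float).eps * (sig[0] if len(sig) else 0.0)
    rank = int(np.sum(sig > rank_tol))
    if rank < N:
        raise RankDeficiencyError(
            f"requested N={N} POD modes but snapshots have numerical rank {rank}"
        )
    V = _fix_signs(Q @ Ub[:, :N])
    return PODBasis(
        V=V, sigma=sig[:N], channel=channel,
        oversampling=oversampling, n_power_iter=n_power_iter, seed=seed,
    )


def project(basis: PODBasis | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Intrinsic coordinates ``V^T x`` (x may be a vector or matrix of columns)."""
    V = basis.V if isinstance(basis, PODBasis) else basis
    if x.shape[0] != V.shape[0]:
        raise ShapeError(f"field length {x.shape[0]} != basis rows {V.shape[0]}")
    return V.T @ x

def lift(basis: PODBasis | np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Reconstruct ``V c`` from intrinsic coordinates."""
    V = basis.V if isinstance(basis, PODBasis) else basis
    if coords.shape[0] != V.shape[1]:
        raise ShapeError(f"coords length {coords.shape[0]} != basis cols {V.shape[1]}")
    return V @ coords


def projection_error_indicator(
    basis: PODBasis | np.ndarray,
    test_snapshots: Sequence[np.ndarray] | np.ndarray,
) -> float:
    """Relative projection error of test snapshots onto span(V).

    ``test_snapshots`` is a list of per-instance matrices (N_h, N_t) (or one
    3-D array (N_h, N_t, N_test)); the indicator is the mean over instances
    of ``sqrt(sum_k ||u_k - V V^T u_k||^2 / sum_k ||u_k||^2)``.  With an
    empty basis (N = 0) the projection is zero and the indicator is one.
    This is the per-snapshot best approximation in span(V), hence a lower
    bound for the error of *any* reconstruction of the form ``V c``.
    """
    V = basis.V if isinstance(basis, PODBasis) else basis
    if isinstance(test_snapshots, np.ndarray) and test_snapshots.ndim == 3:
        test_snapshots = [test_snapshots[:, :, i] for i in range(test_snapshots.shape[2])]
    if len(test_snapshots) == 0:
        raise DegenerateFieldError("empty test set")
    vals = []
    for U in test_snapshots:
        U = np.atleast_2d(U)
        denom = np.sum(U ** 2)
        if denom == 0.0:
            raise DegenerateFieldError("test snapshots are identically zero")
        if V.shape[1] == 0:
            vals.append(1.0)
            continue
        R = U - V @ (V.T @ U)
        vals.append(float(np.sqrt(np.sum(R ** 2) / denom)))
    return float(np.mean(vals))
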