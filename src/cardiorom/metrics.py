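"""Evaluation metrics: error indicators, activation maps, AP traces.

Two error measures quantify how well a reconstruction matches the full-order
fields over a testing set:

* the scalar indicator: mean over test instances of
  ``sqrt(sum_k ||u_k - u~_k||^2 / sum_k ||u_k||^2)`` (Euclidean norms of
  coefficient vectors, summed over the sampled times);
* the space-resolved relative error at time ``k``:
  ``|u_k - u~_k| / ((1/N_t) sum_k ||u_k||_2)`` — entrywise absolute
  deviation scaled by the time-averaged snapshot norm.

Clinical-style outputs: the activation map (per point, the earliest sampled
time at which the potential attains its temporal maximum), action-potential
traces at a physical point, and a sustained-activity flag operationalizing
re-entry detection after an S1-S2 protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateFieldError, ShapeError
from .solver import Trajectory
from .splines import SplineSpace, evaluate_basis

__all__ = [
    "ErrorReport",
    "error_indicator",
    "relative_error_field",
    "relative_error_means",
    "activation_map",
    "ap_trace",
    "sustained_activity_flag",
]


def _as_instances(arr) -> list[np.ndarray]:
    if isinstance(arr, np.ndarray):
        if arr.ndim == 2:
            return [arr]
        if arr.ndim == 3:
            return [arr[:, :, i] for i in range(arr.shape[2])]
        raise ShapeError("expected (N_h, N_t) or (N_h, N_t, N_test) array")
    return [np.atleast_2d(a) for a in arr]


def error_indicator(true_fields, approx_fields) -> float:
    """Scalar relative error indicator over a testing set.

    Accepts single matrices, lists of per-instance matrices, or 3-D arrays
    ``(N_h, N_t, N_test)``; true and approximate fields must agree in shape.
    """
    trues = _as_instances(true_fields)
    approxs = _as_instances(approx_fields)
    if len(trues) != len(approxs):
        raise ShapeError("true/approx instance counts differ")
    vals = []
    for U, Ua in zip(trues, approxs):
        if U.shape != Ua.shape:
            raise ShapeError("true/approx shapes differ")
        denom = np.sum(U ** 2)
        if denom == 0.0:
            raise DegenerateFieldError("true fields are identically zero")
        vals.append(float(np.sqrt(np.sum((U - Ua) ** 2) / denom)))
    return float(np.mean(vals))


def _time_avg_norm(U: np.ndarray) -> float:
    denom = float(np.mean(np.linalg.norm(U, axis=0)))
    if denom <= 0.0:
        raise DegenerateFieldError("time-averaged snapshot norm is zero")
    return denom


def relative_error_field(k: int, true_fields: np.ndarray, approx_fields: np.ndarray) -> np.ndarray:
    """Space-resolved relative error at time index ``k`` for one instance."""
    U = np.atleast_2d(true_fields)
    Ua = np.atleast_2d(approx_fields)
    if U.shape != Ua.shape:
        raise ShapeError("true/approx shapes differ")
    return np.abs(U[:, k] - Ua[:, k]) / _time_avg_norm(U)


def relative_error_means(true_fields: np.ndarray, approx_fields: np.ndarray) -> np.ndarray:
    """Spatial mean of the relative error field at every sampled time."""
    U = np.atleast_2d(true_fields)
    Ua = np.atleast_2d(approx_fields)
    if U.shape != Ua.shape:
        raise ShapeError("true/approx shapes differ")
    return np.abs(U - Ua).mean(axis=0) / _time_avg_norm(U)


@dataclass
class ErrorReport:
    """Summary of one reconstruction evaluation (per field channel)."""

    epsilon_rel: dict                    # channel -> scalar indicator
    epsilon_k_mean: dict = field(default_factory=dict)   # channel -> (N_t,) spatial means
    projection_epsilon_rel: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for ch, v in self.epsilon_rel.items():
            if v < 0:
                raise ShapeError(f"epsilon_rel[{ch}] must be >= 0")


def activation_map(
    trajectory: Trajectory | np.ndarray,
    times: np.ndarray | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Activation time per degree of freedom.

    The activation time at a point is the *earliest* sampled time at which
    the potential attains its temporal maximum (ties resolved to the first
    occurrence).  Points whose temporal maximum stays below ``threshold``
    never activated and are flagged with NaN.  Invariant under monotone
    increasing rescaling of the potential.
    """
    if isinstance(trajectory, Trajectory):
        U, times = trajectory.u, trajectory.times
    else:
        U = np.atleast_2d(trajectory)
        if times is None:
            raise ShapeError("times required when passing a bare array")
    idx = np.argmax(U, axis=1)           # first index of the max: earliest time
    ac = np.asarray(times, dtype=float)[idx]
    if threshold is not None:
        ac = np.where(U.max(axis=1) >= threshold, ac, np.nan)
    return ac


def ap_trace(
    point: Sequence[float],
    trajectory: Trajectory,
    space: SplineSpace,
) -> tuple[np.ndarray, np.ndarray]:
    """Time series of (u, ue) at a fixed physical point.

    The fields are evaluated through the spline basis, so the trace at a
    point equals the basis-weighted combination of coefficient rows.
    """
    B, _, _ = evaluate_basis(space, [list(point)])
    row = B.toarray()[0]
    return row @ trajectory.u, row @ trajectory.ue


def sustained_activity_flag(
    trajectory: Trajectory,
    t_check: float,
    threshold: float,
) -> bool:
    """True iff the tissue is active at every sampled time from t_check on.

    "Active" means ``max_x u(x, t) > threshold``.  After a plain S1 beat the
    tissue repolarizes and the flag is False; a re-entrant circuit keeps a
    depolarization front alive indefinitely and the flag is True.
    """
    times = trajectory.times
    if t_check > times[-1]:
        raise ShapeError("t_check outside the sampled window")
    sel = times >= t_check
    return bool(np.all(trajectory.u[:, sel].max(axis=0) > threshold))
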