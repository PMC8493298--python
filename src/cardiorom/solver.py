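"""Semi-implicit BDF2 time integration of the semi-discrete Bidomain system.

The coupled system for the transmembrane potential u, the extracellular
potential ue, and the gating field w is

    M du/dt + A_i u + A_i ue + I_ion(u, w) = l_i(t)        (parabolic)
    A_i u + (A_i + A_e) ue                 = l_i(t) + l_e(t)  (elliptic)
    dw/dt = g(u, w)                                          (pointwise)

Scheme (IMEX-BDF2, one constant factorization per (mu, dt)):

* diffusion implicit; the ionic current is evaluated at the second-order
  extrapolant ``u* = 2 u^k - u^(k-1)`` (first step bootstrapped with
  implicit Euler);
* the extracellular potential enters the parabolic solve at its extrapolant
  and is then updated from the elliptic row;
* the gating ODE is integrated at quadrature points (sum-factorized
  "state-variable interpolation": the ionic current is sampled where it is
  integrated, because spline coefficients are not interpolatory).  Given the
  extrapolated potential the recovery ODE is linear in w and solved exactly
  per point (the Aliev-Panfilov restitution factor is frozen at the
  extrapolated w).

The elliptic row is a pure Neumann problem whose matrix A has the constant
vector in its kernel.  With an intracellular-only stimulus the right-hand
side is incompatible; a spatially uniform balancing current is subtracted
(bordered system with the column m = M 1) and ue is fixed to M-weighted
zero mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import (
    AssembledOperators,
    ConductivityModel,
    StimulusSpec,
    assemble_operators,
)
from .errors import EllipticSolveError, InstabilityError, InvalidInputError
from .ionic import IonicModelParams, gating_linear_coeffs, potential_scale, reaction_terms
from .splines import SplineSpace

__all__ = [
    "FOMState",
    "SolverConfig",
    "Trajectory",
    "advance_step",
    "solve_elliptic",
    "simulate",
    "sample_times",
]


@dataclass
class FOMState:
    """Solver state at one time level."""

    u: np.ndarray        # transmembrane coefficients, length N_h
    ue: np.ndarray       # extracellular coefficients, length N_h
    w_quad: np.ndarray   # gating values at quadrature points
    t: float             # ms


@dataclass(frozen=True)
class SolverConfig:
    """Time-integration settings.

    ``n_save`` sampled instants are placed uniformly on ``window`` (default
    the full interval ``(0, T]``) and snapped to the time grid.
    ``ionic_mode`` selects where the ionic current is evaluated: ``"svi"``
    (quadrature points, default) or ``"ici"`` (coefficient-level evaluation,
    cheaper and less accurate, for comparisons only).  ``forcing`` is an
    optional extra parabolic load ``t -> vector`` (used e.g. in convergence
    studies).  ``zero_ue_coupling`` skips the elliptic solve (ue = 0), a
    monodomain-like shortcut.
    """

    dt: float
    T: float
    n_save: int = 1
    window: tuple[float, float] | None = None
    tol: float = 1e-9
    ionic_mode: str = "svi"
    zero_ue_coupling: bool = False
    forcing: Callable[[float], np.ndarray] | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (0 < self.dt < self.T):
            raise InvalidInputError("require 0 < dt < T")
        if self.n_save < 1:
            raise InvalidInputError("n_save must be >= 1")
        if self.ionic_mode not in ("svi", "ici"):
            raise InvalidInputError("ionic_mode must be 'svi' or 'ici'")


@dataclass
class Trajectory:
    """Sampled fields of one simulation: columns of u/ue follow `times`."""

    mu: np.ndarray | None
    times: np.ndarray
    u: np.ndarray    # (N_h, N_t)
    ue: np.ndarray   # (N_h, N_t)
    meta: dict = field(default_factory=dict)


def sample_times(cfg: SolverConfig) -> tuple[np.ndarray, np.ndarray]:
    """Step indices and times of the sampled instants (snapped to the grid)."""
    lo, hi = cfg.window if cfg.window is not None else (0.0, cfg.T)
    if not (0.0 <= lo < hi <= cfg.T + 1e-12):
        raise InvalidInputError("sampling window must lie inside (0, T]")
    targets = lo + (hi - lo) * np.arange(1, cfg.n_save + 1) / cfg.n_save
    idx = np.unique(np.clip(np.rint(targets / cfg.dt).astype(int), 1, None))
    if len(idx) != cfg.n_save:
        raise InvalidInputError(
            "sampled instants collide on the time grid; reduce n_save or dt"
        )
    return idx, idx * cfg.dt


class _EllipticSolver:
    """Bordered factorization of [[A, m], [m^T, 0]] with m = M 1.

    Solves A ue = rhs - lambda m subject to m^T ue = 0: the multiplier
    absorbs the incompatible (mean) part of the load as a uniform balancing
    current, and the constraint removes the kernel component.
    """

    def __init__(self, ops: AssembledOperators, tol: float = 1e-9):
        m = ops.mass_vector
        n = ops.A.shape[0]
        K = sp.bmat(
            [[ops.A, m[:, None]], [m[None, :], None]], format="csc"
        )
        self._lu = spla.splu(K)
        self._A = ops.A
        self._m = m
        self._ones = np.ones(n)
        self._tol = tol

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        sol = self._lu.solve(np.concatenate([rhs, [0.0]]))
        ue, lam = sol[:-1], sol[-1]
        resid = np.linalg.norm(self._A @ ue + lam * self._m - rhs)
        scale = max(np.linalg.norm(rhs), 1.0)
        if not np.isfinite(resid) or resid > self._tol * scale:
            raise EllipticSolveError(
                f"elliptic residual {resid:.3e} above tolerance {self._tol:.1e}"
            )
        return ue


def solve_elliptic(
    u: np.ndarray,
    ops: AssembledOperators,
    rhs: np.ndarray,
    tol: float = 1e-9,
    _solver: _EllipticSolver | None = None,
) -> np.ndarray:
    """Solve the extracellular row A ue = rhs - A_i u (zero M-weighted mean).

    The load is balanced by a uniform current (see :class:`_EllipticSolver`),
    so adding any multiple of the uniform-current load vector ``M 1`` to
    ``rhs`` leaves the returned ue unchanged.
    """
    solver = _solver if _solver is not None else _EllipticSolver(ops, tol)
    return solver.solve(np.asarray(rhs) - ops.A_i @ np.asarray(u))


class _TimeStepper:
    """Pre-factorized IMEX-BDF2 stepper for fixed (operators, dt)."""

    def __init__(
        self,
        space: SplineSpace,
        ops: AssembledOperators,
        ionic: IonicModelParams,
        stimuli: Sequence[StimulusSpec],
        cfg: SolverConfig,
    ):
        self.space = space
        self.ops = ops
        self.ionic = ionic
        self.cfg = cfg
        dt = cfg.dt
        self._lu_bdf1 = spla.splu((ops.M / dt + ops.A_i).tocsc())
        self._lu_bdf2 = spla.splu((1.5 * ops.M / dt + ops.A_i).tocsc())
        self._elliptic = None if cfg.zero_ue_coupling else _EllipticSolver(ops, cfg.tol)
        self._scale = potential_scale(ionic)
        if cfg.ionic_mode == "svi":
            self._B = space.quad_values
            self._wq = space.quad_weights
        else:  # ici: coefficient-level evaluation, mass-matrix lumping of the load
            self._B = sp.identity(space.N_h, format="csr")
            self._wq = None
        # static spatial load per stimulus, split by compartment
        self._loads: list[tuple[StimulusSpec, np.ndarray]] = []
        for stim in stimuli:
            mask = stim.spatial_mask(space.quad_points).astype(float)
            vec = np.asarray(
                space.quad_values.T @ (space.quad_weights * stim.amplitude * mask)
            )
            self._loads.append((stim, vec))

    def stimulus_loads(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        n = self.ops.M.shape[0]
        l_i = np.zeros(n)
        l_e = np.zeros(n)
        for stim, vec in self._loads:
            if stim.active(t):
                if stim.compartment == "intracellular":
                    l_i += vec
                else:
                    l_e += vec
        return l_i, l_e

    def _ionic_load(self, u_star: np.ndarray, w_new: np.ndarray) -> np.ndarray:
        u_pts = self._B @ u_star
        i_ion, _ = reaction_terms(self.ionic, u_pts, w_new)
        if self.cfg.ionic_mode == "svi":
            return np.asarray(self.space.quad_values.T @ (self._wq * i_ion))
        return np.asarray(self.ops.M @ i_ion)

    def initial_state(self, u0: np.ndarray, w0: np.ndarray) -> FOMState:
        l_i, l_e = self.stimulus_loads(0.0)
        if self.cfg.zero_ue_coupling:
            ue0 = np.zeros_like(u0)
        else:
            ue0 = self._elliptic.solve(l_i + l_e - self.ops.A_i @ u0)
        return FOMState(u=u0.copy(), ue=ue0, w_quad=w0.copy(), t=0.0)

    def step(self, prev: FOMState, prev2: FOMState | None) -> FOMState:
        """Advance one step; ``prev2 is None`` triggers the BDF1 bootstrap."""
        dt = self.cfg.dt
        t_new = prev.t + dt
        first = prev2 is None
        if first:
            u_star = prev.u
            ue_star = prev.ue
            w_star = prev.w_quad
        else:
            u_star = 2.0 * prev.u - prev2.u
            ue_star = 2.0 * prev.ue - prev2.ue
            w_star = 2.0 * prev.w_quad - prev2.w_quad

        # gating update, implicit in w given the extrapolated potential
        u_pts_star = self._B @ u_star
        g0, g1 = gating_linear_coeffs(self.ionic, u_pts_star, w_star)
        if first:
            w_new = (prev.w_quad + dt * g0) / (1.0 - dt * g1)
        else:
            c = 2.0 * dt / 3.0
            w_new = ((4.0 * prev.w_quad - prev2.w_quad) / 3.0 + c * g0) / (1.0 - c * g1)

        l_i, l_e = self.stimulus_loads(t_new)
        rhs = l_i - self.ops.A_i @ ue_star - self._ionic_load(u_star, w_new)
        if self.cfg.forcing is not None:
            rhs = rhs + self.cfg.forcing(t_new)
        if first:
            rhs = rhs + self.ops.M @ (prev.u / dt)
            u_new = self._lu_bdf1.solve(rhs)
        else:
            rhs = rhs + self.ops.M @ ((4.0 * prev.u - prev2.u) / (2.0 * dt))
            u_new = self._lu_bdf2.solve(rhs)

        lo, hi = -0.3 * self._scale, 1.3 * self._scale
        if not np.all(np.isfinite(u_new)) or u_new.min() < lo or u_new.max() > hi:
            raise InstabilityError(
                f"potential left [{lo:.3g}, {hi:.3g}] at t={t_new:.4g} ms; "
                f"dt={dt} is too large for this problem"
            )

        if self.cfg.zero_ue_coupling:
            ue_new = np.zeros_like(u_new)
        else:
            ue_new = self._elliptic.solve(l_i + l_e - self.ops.A_i @ u_new)
        return FOMState(u=u_new, ue=ue_new, w_quad=w_new, t=t_new)


def advance_step(
    history: Sequence[FOMState],
    ops: AssembledOperators,
    ionic: IonicModelParams,
    stimuli: Sequence[StimulusSpec],
    dt: float,
    space: SplineSpace,
    cfg: SolverConfig | None = None,
) -> FOMState:
    """One IMEX-BDF2 step from the last two states (one state: BDF1 bootstrap).

    Convenience wrapper that factorizes on every call; inside a simulation
    loop use :func:`simulate`, which reuses the factorizations.
    """
    if cfg is None:
        cfg = SolverConfig(dt=dt, T=history[-1].t + 2 * dt, n_save=1)
    stepper = _TimeStepper(space, ops, ionic, stimuli, cfg)
    if len(history) == 1:
        return stepper.step(history[0], None)
    return stepper.step(history[-1], history[-2])


def simulate(
    space: SplineSpace,
    cond: ConductivityModel,
    ionic: IonicModelParams,
    stimuli: Sequence[StimulusSpec],
    cfg: SolverConfig,
    mu: np.ndarray | None = None,
    ops: AssembledOperators | None = None,
    u0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
    store_w: bool = False,
) -> Trajectory:
    """Run the full-order model for one parameter instance.

    Parameter hooks on the conductivity model and the stimuli are applied
    before assembly, so matrices affected by ``mu`` are rebuilt.  The result
    is deterministic given ``(mu, cfg, space)``.  Initial data default to the
    rest state ``u0 = 0, w0 = 0``.
    """
    cond_mu = cond.with_mu(mu)
    stimuli_mu = [s.with_mu(mu) for s in stimuli]
    if ops is None or cond_mu is not cond:
        ops = assemble_operators(space, cond_mu)

    stepper = _TimeStepper(space, ops, ionic, stimuli_mu, cfg)
    n_w = space.quad_points.shape[0] if cfg.ionic_mode == "svi" else space.N_h
    u_init = np.zeros(space.N_h) if u0 is None else np.asarray(u0, dtype=float)
    w_init = np.zeros(n_w) if w0 is None else np.asarray(w0, dtype=float)

    save_idx, save_t = sample_times(cfg)
    n_steps = int(save_idx[-1])
    U = np.empty((space.N_h, len(save_idx)))
    UE = np.empty_like(U)
    W = np.empty((n_w, len(save_idx))) if store_w else None
    save_set = {int(k): j for j, k in enumerate(save_idx)}

    prev2 = None
    state = stepper.initial_state(u_init, w_init)
    for k in range(1, n_steps + 1):
        new = stepper.step(state, prev2)
        prev2, state = state, new
        j = save_set.get(k)
        if j is not None:
            U[:, j] = state.u
            UE[:, j] = state.ue
            if store_w:
                W[:, j] = state.w_quad
    meta = {"dt": cfg.dt, "T": cfg.T, "ionic_mode": cfg.ionic_mode}
    if store_w:
        meta["w_quad"] = W
    return Trajectory(
        mu=None if mu is None else np.atleast_1d(np.asarray(mu, dtype=float)),
        times=save_t,
        u=U,
        ue=UE,
        meta=meta,
    )
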