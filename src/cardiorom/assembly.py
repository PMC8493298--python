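"""Conductivity tensors, fiber fields, stimuli, and Galerkin assembly.

Cardiac tissue is an anisotropic conductor: along the local fiber direction
``f0(x)`` the conductivity is higher than transverse to it.  With an
axisymmetric fiber distribution the intracellular / extracellular tensors are

    D_i(x) = sigma_t_i I + (sigma_l_i - sigma_t_i) f0 f0^T
    D_e(x) = sigma_t_e I + (sigma_l_e - sigma_t_e) f0 f0^T

(symmetric positive definite, eigenvalues {sigma_l, sigma_t}).  This module
assembles the mass matrix M, the stiffness matrices A_i, A_e built from
D_i, D_e, and indicator-function stimulus load vectors.  Boundary conditions
of the tissue model are natural (homogeneous Neumann), so no boundary terms
are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DegenerateFiberError, InvalidConductivityError, InvalidInputError
from .splines import SplineSpace

__all__ = [
    "ConductivityModel",
    "StimulusSpec",
    "AssembledOperators",
    "make_fiber_field",
    "assemble_operators",
    "assemble_stimulus",
]


# --------------------------------------------------------------------------
# fiber fields
# --------------------------------------------------------------------------

def _laplace_fiber(space: SplineSpace, markers: Tuple[str, str]) -> np.ndarray:
    """Fibers directed along grad(phi) of a Laplace problem.

    Dirichlet data 0 on the first marked edge, 1 on the second, homogeneous
    Neumann elsewhere.  Because the end knots are open, the boundary basis
    functions interpolate the edges, so Dirichlet data is imposed exactly by
    fixing the corresponding coefficients.
    """
    B = space.quad_values
    Gx, Gy = space.quad_grads
    w = space.quad_weights
    K = (Gx.T @ (Gx.multiply(w[:, None])) + Gy.T @ (Gy.multiply(w[:, None]))).tocsr()

    phi = np.zeros(space.N_h)
    fixed = np.zeros(space.N_h, dtype=bool)
    for edge, value in zip(markers, (0.0, 1.0)):
        idx = space.boundary_indices(edge)
        phi[idx] = value
        fixed[idx] = True
    free = ~fixed
    rhs = -K[:, fixed] @ phi[fixed]
    phi[free] = spla.spsolve(K[free][:, free].tocsc(), rhs[free])

    grad = np.column_stack([Gx @ phi, Gy @ phi])
    norms = np.linalg.norm(grad, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateFiberError("vanishing gradient in Laplace fiber rule")
    return grad / norms[:, None]


def make_fiber_field(
    space: SplineSpace,
    rule: Literal["constant", "laplace_gradient"] = "constant",
    direction: Sequence[float] = (1.0, 0.0),
    markers: Tuple[str, str] = ("left", "right"),
) -> np.ndarray:
    """Unit fiber vectors f0 at every quadrature point, shape (n_qp, 2)."""
    n_qp = space.quad_points.shape[0]
    if rule == "constant":
        d = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            raise DegenerateFiberError("constant fiber direction has zero norm")
        return np.tile(d / nrm, (n_qp, 1))
    if rule == "laplace_gradient":
        return _laplace_fiber(space, markers)
    raise InvalidInputError(f"unknown fiber rule '{rule}'")


# --------------------------------------------------------------------------
# conductivity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductivityModel:
    """Axisymmetric intracellular/extracellular conductivities (1/(Ohm cm)).

    ``param_map`` names which conductivity is replaced by a component of the
    parameter vector mu, e.g. ``{"sigma_l_e": 0}`` for the slab benchmark
    where mu is the longitudinal extracellular conductivity.
    """

    sigma_l_i: float
    sigma_t_i: float
    sigma_l_e: float
    sigma_t_e: float
    fiber: np.ndarray = field(repr=False)
    param_map: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("sigma_l_i", "sigma_t_i", "sigma_l_e", "sigma_t_e"):
            if getattr(self, name) <= 0:
                raise InvalidConductivityError(f"{name} must be > 0")
        f = np.asarray(self.fiber, dtype=float)
        if f.ndim != 2 or f.shape[1] != 2:
            raise InvalidInputError("fiber field must have shape (n_qp, 2)")
        if np.max(np.abs(np.linalg.norm(f, axis=1) - 1.0)) > 1e-12:
            raise DegenerateFiberError("fiber vectors must be unit length")
        object.__setattr__(self, "fiber", f)

    def with_mu(self, mu: np.ndarray | None) -> "ConductivityModel":
        """Return a copy with parameter-mapped conductivities substituted."""
        if mu is None or not self.param_map:
            return self
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        updates = {name: float(mu[i]) for name, i in self.param_map.items()}
        return replace(self, **updates)

    def tensor_components(self, compartment: Literal["i", "e"]):
        """Per-quadrature-point (D11, D12, D22) of the selected tensor."""
        if compartment == "i":
            sl, st = self.sigma_l_i, self.sigma_t_i
        else:
            sl, st = self.sigma_l_e, self.sigma_t_e
        fx, fy = self.fiber[:, 0], self.fiber[:, 1]
        d = sl - st
        return st + d * fx * fx, d * fx * fy, st + d * fy * fy


# --------------------------------------------------------------------------
# stimuli
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """A rectangular-window applied current on an indicator region.

    ``I_app(x, t) = amplitude * 1_region(x) * 1_[t_start, t_end](t)``.
    ``center_from_mu`` optionally names the components of the parameter
    vector that position the ball center (stimulation-site parametrization).
    A protocol is an ordered list of StimulusSpec (S1, S2, ...).
    """

    amplitude: float                      # mA
    region: Literal["half_space", "ball"]
    t_start: float                        # ms
    t_end: float                          # ms
    x0: float | None = None               # half_space: {x <= x0}
    center: Tuple[float, float] | None = None
    radius: float | None = None
    compartment: Literal["intracellular", "extracellular"] = "intracellular"
    center_from_mu: Tuple[int, ...] | None = None

    def __post_init__(self):
        if not (self.t_end > self.t_start >= 0):
            raise InvalidInputError("stimulus window requires t_end > t_start >= 0")
        if self.region == "half_space":
            if self.x0 is None:
                raise InvalidInputError("half_space stimulus requires x0")
        elif self.region == "ball":
            if self.center_from_mu is None and self.center is None:
                raise InvalidInputError("ball stimulus requires a center")
            if self.radius is None or self.radius <= 0:
                raise InvalidInputError("ball stimulus requires radius > 0")
        else:
            raise InvalidInputError(f"unknown stimulus region '{self.region}'")

    def with_mu(self, mu: np.ndarray | None) -> "StimulusSpec":
        if mu is None or self.center_from_mu is None:
            return self
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        cx, cy = (float(mu[i]) for i in self.center_from_mu)
        return replace(self, center=(cx, cy))

    def spatial_mask(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        if self.region == "half_space":
            return pts[:, 0] <= self.x0
        cx, cy = self.center
        return (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= self.radius ** 2

    def active(self, t: float) -> bool:
        return self.t_start <= t <= self.t_end


# --------------------------------------------------------------------------
# operators
# --------------------------------------------------------------------------

@dataclass
class AssembledOperators:
    """Mass and stiffness matrices of the semi-discrete tissue model.

    M is SPD; A_i, A_e are symmetric positive semidefinite with the constant
    vector in their kernel (pure Neumann problem); A = A_i + A_e.
    """

    M: sp.csc_matrix
    A_i: sp.csc_matrix
    A_e: sp.csc_matrix
    A: sp.csc_matrix

    @property
    def mass_vector(self) -> np.ndarray:
        """m = M 1: integrals of the basis functions (weights of the
        M-weighted mean and the load vector of a uniform unit current)."""
        return np.asarray(self.M @ np.ones(self.M.shape[0]))


def _weighted_stiffness(Gx, Gy, w, d11, d12, d22) -> sp.csc_matrix:
    Wx = Gx.multiply((w * d11)[:, None]) + Gy.multiply((w * d12)[:, None])
    Wy = Gx.multiply((w * d12)[:, None]) + Gy.multiply((w * d22)[:, None])
    K = Gx.T @ Wx + Gy.T @ Wy
    # symmetrize away round-off so eigensolvers / CG see an exact symmetric matrix
    K = (K + K.T) * 0.5
    return K.tocsc()


def assemble_operators(space: SplineSpace, cond: ConductivityModel) -> AssembledOperators:
    """Assemble M, A_i, A_e (and A = A_i + A_e) for a conductivity model."""
    B = space.quad_values
    Gx, Gy = space.quad_grads
    w = space.quad_weights
    if cond.fiber.shape[0] != space.quad_points.shape[0]:
        raise InvalidInputError("fiber field not defined at the quadrature points")
    M = (B.T @ (B.multiply(w[:, None]))).tocsc()
    A_i = _weighted_stiffness(Gx, Gy, w, *cond.tensor_components("i"))
    A_e = _weighted_stiffness(Gx, Gy, w, *cond.tensor_components("e"))
    return AssembledOperators(M=M, A_i=A_i, A_e=A_e, A=(A_i + A_e).tocsc())


def assemble_stimulus(space: SplineSpace, stim: StimulusSpec, t: float) -> np.ndarray:
    """Load vector of one stimulus at time t (zero outside its window).

    The indicator region is integrated with the element quadrature rule (no
    sub-cell cutting), so elements cut by the region boundary contribute an
    O(h) localized error.
    """
    if t < 0:
        raise InvalidInputError("time must be non-negative")
    if not stim.active(t):
        return np.zeros(space.N_h)
    mask = stim.spatial_mask(space.quad_points).astype(float)
    return np.asarray(space.quad_values.T @ (space.quad_weights * stim.amplitude * mask))
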