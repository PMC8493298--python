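"""Tensor-product B-spline spaces on rectangular slabs.

The full-order model is a Galerkin discretization over smooth spline bases:
degree-``p`` B-splines with open uniform knot vectors, giving global
``C^(p-1)`` continuity.  High-order continuity limits numerical dispersion,
which matters for the steep travelling fronts of cardiac tissue.  The slab
geometry is a flat patch, so plain B-splines (all rational weights equal to
one) are used; the knot vectors live directly in physical coordinates, so
the parametric-to-physical map is the identity.

Basis values and derivatives are evaluated through
``scipy.interpolate.BSpline.design_matrix``; the derivative of a degree-``p``
basis function is expressed in the standard way as a difference of two
degree-``(p-1)`` functions on the same knot vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Tuple

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .errors import InvalidGeometryError, OutOfRangeError

__all__ = ["SplineSpace", "build_spline_space", "evaluate_basis"]


def open_knot_vector(n_el: int, p: int, a: float, b: float) -> np.ndarray:
    """Open uniform knot vector on [a, b] with ``n_el`` elements."""
    breaks = np.linspace(a, b, n_el + 1)
    return np.concatenate([np.full(p, a), breaks, np.full(p, b)])


def _derivative_operator(t: np.ndarray, p: int) -> sp.csr_matrix:
    """Sparse map from degree-(p-1) basis values (on knots t[1:-1]) to the
    derivatives of the degree-p basis functions on knots t.

    Column ``i`` holds the two-term recurrence coefficients of ``B'_{i,p}``;
    terms with a vanishing knot span (repeated end knots) drop out.
    """
    n = len(t) - p - 1            # number of degree-p functions
    rows, cols, vals = [], [], []
    for i in range(n):
        d1 = t[i + p] - t[i]
        if d1 > 0:                # uses B_{i,p-1} == column i-1 on t[1:-1]
            rows.append(i - 1)
            cols.append(i)
            vals.append(p / d1)
        d2 = t[i + p + 1] - t[i + 1]
        if d2 > 0:                # uses B_{i+1,p-1} == column i on t[1:-1]
            rows.append(i)
            cols.append(i)
            vals.append(-p / d2)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n - 1, n))


def _basis_matrices_1d(x: np.ndarray, t: np.ndarray, p: int):
    """Values and first derivatives of all basis functions at points x.

    Returns sparse matrices of shape ``(len(x), n_basis)``.
    """
    x = np.asarray(x, dtype=float)
    Bv = BSpline.design_matrix(x, t, p).tocsr()
    if p == 0:
        return Bv, sp.csr_matrix(Bv.shape)
    Bm1 = BSpline.design_matrix(x, t[1:-1], p - 1).tocsr()
    Bd = (Bm1 @ _derivative_operator(t, p)).tocsr()
    return Bv, Bd


@dataclass(frozen=True)
class SplineSpace:
    """Tensor-product B-spline space on a rectangle.

    ``N_h = prod(n_el + p)`` basis functions; global index convention is
    x-major: ``i = ix * n_basis_y + iy``.  The quadrature rule is
    Gauss-Legendre with ``p+1`` points per direction per element, which
    integrates the mass matrix exactly on affine elements.
    """

    degrees: Tuple[int, int]
    n_el: Tuple[int, int]
    extents: Tuple[Tuple[float, float], Tuple[float, float]]
    knots: Tuple[np.ndarray, np.ndarray] = field(repr=False)

    @property
    def n_basis(self) -> Tuple[int, int]:
        return tuple(ne + p for ne, p in zip(self.n_el, self.degrees))

    @property
    def N_h(self) -> int:
        nx, ny = self.n_basis
        return nx * ny

    @property
    def n_elements(self) -> int:
        return self.n_el[0] * self.n_el[1]

    # ---- quadrature -----------------------------------------------------
    def _quadrature_1d(self, axis: int):
        p = self.degrees[axis]
        a, b = self.extents[axis]
        breaks = np.linspace(a, b, self.n_el[axis] + 1)
        gp, gw = np.polynomial.legendre.leggauss(p + 1)
        h = np.diff(breaks)
        mid = 0.5 * (breaks[:-1] + breaks[1:])
        pts = (mid[:, None] + 0.5 * h[:, None] * gp[None, :]).ravel()
        wts = (0.5 * h[:, None] * gw[None, :]).ravel()
        return pts, wts

    @cached_property
    def quad_points(self) -> np.ndarray:
        """Physical coordinates of all quadrature points, shape (n_qp, 2)."""
        px, _ = self._quadrature_1d(0)
        py, _ = self._quadrature_1d(1)
        X, Y = np.meshgrid(px, py, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    @cached_property
    def quad_weights(self) -> np.ndarray:
        _, wx = self._quadrature_1d(0)
        _, wy = self._quadrature_1d(1)
        return np.kron(wx, wy)

    @cached_property
    def _collocation(self):
        """Sparse (n_qp x N_h) value/gradient matrices at quadrature points."""
        px, _ = self._quadrature_1d(0)
        py, _ = self._quadrature_1d(1)
        Bx, Dx = _basis_matrices_1d(px, self.knots[0], self.degrees[0])
        By, Dy = _basis_matrices_1d(py, self.knots[1], self.degrees[1])
        B = sp.kron(Bx, By, format="csr")
        Gx = sp.kron(Dx, By, format="csr")
        Gy = sp.kron(Bx, Dy, format="csr")
        return B, Gx, Gy

    @property
    def quad_values(self) -> sp.csr_matrix:
        return self._collocation[0]

    @property
    def quad_grads(self) -> Tuple[sp.csr_matrix, sp.csr_matrix]:
        return self._collocation[1], self._collocation[2]

    @cached_property
    def greville_points(self) -> np.ndarray:
        """Greville abscissae (one collocation point per basis function)."""
        pts = []
        for axis in (0, 1):
            t, p = self.knots[axis], self.degrees[axis]
            n = self.n_basis[axis]
            pts.append(np.array([t[i + 1: i + p + 1].mean() for i in range(n)]))
        X, Y = np.meshgrid(pts[0], pts[1], indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    # ---- index helpers --------------------------------------------------
    def boundary_indices(self, edge: str) -> np.ndarray:
        """Global indices of basis functions interpolating one edge."""
        nx, ny = self.n_basis
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        flat = (ix * ny + iy)
        if edge == "left":
            return flat[0, :]
        if edge == "right":
            return flat[-1, :]
        if edge == "bottom":
            return flat[:, 0]
        if edge == "top":
            return flat[:, -1]
        raise ValueError(f"unknown edge '{edge}'")


def build_spline_space(
    p: int | Tuple[int, int],
    n_el: Tuple[int, int],
    extents: Tuple[Tuple[float, float], Tuple[float, float]],
) -> SplineSpace:
    """Construct a tensor-product spline space on a rectangle.

    Parameters
    ----------
    p : degree per direction (a single int applies to both).
    n_el : element counts per direction (>= 1).
    extents : ``((x0, x1), (y0, y1))`` domain box in cm.
    """
    degrees = (p, p) if np.isscalar(p) else tuple(p)
    n_el = tuple(int(n) for n in n_el)
    extents = tuple((float(a), float(b)) for a, b in extents)
    if any(d < 1 for d in degrees):
        raise InvalidGeometryError("spline degree must be >= 1")
    if any(n < 1 for n in n_el):
        raise InvalidGeometryError("element count must be >= 1")
    if any(b <= a for a, b in extents):
        raise InvalidGeometryError("domain extents must have positive length")
    knots = tuple(
        open_knot_vector(n_el[ax], degrees[ax], *extents[ax]) for ax in (0, 1)
    )
    return SplineSpace(degrees=degrees, n_el=n_el, extents=extents, knots=knots)


def evaluate_basis(space: SplineSpace, points: np.ndarray):
    """Basis values and physical gradients at arbitrary points.

    Returns sparse matrices ``(B, Gx, Gy)`` of shape ``(n_points, N_h)``;
    each row has the ``(p+1)^2`` non-zero local basis values / gradient
    components.  Points must lie inside the (closed) domain box.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise OutOfRangeError("points must have shape (n, 2)")
    for ax in (0, 1):
        a, b = space.extents[ax]
        if np.any(pts[:, ax] < a) or np.any(pts[:, ax] > b):
            raise OutOfRangeError("evaluation point outside the domain")
    Bx, Dx = _basis_matrices_1d(pts[:, 0], space.knots[0], space.degrees[0])
    By, Dy = _basis_matrices_1d(pts[:, 1], space.knots[1], space.degrees[1])
    ny = space.n_basis[1]
    n_pts = pts.shape[0]

    def _rowwise_kron(A, Bm):
        # row-by-row outer product: result[r, ix*ny+iy] = A[r, ix] * Bm[r, iy]
        rows, cols, vals = [], [], []
        A = A.tocsr()
        Bm = Bm.tocsr()
        for r in range(n_pts):
            ax_cols = A.indices[A.indptr[r]: A.indptr[r + 1]]
            ax_vals = A.data[A.indptr[r]: A.indptr[r + 1]]
            by_cols = Bm.indices[Bm.indptr[r]: Bm.indptr[r + 1]]
            by_vals = Bm.data[Bm.indptr[r]: Bm.indptr[r + 1]]
            for ic, iv in zip(ax_cols, ax_vals):
                rows.extend([r] * len(by_cols))
                cols.extend(ic * ny + by_cols)
                vals.extend(iv * by_vals)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n_pts, space.N_h))

    return _rowwise_kron(Bx, By), _rowwise_kron(Dx, By), _rowwise_kron(Bx, Dy)
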