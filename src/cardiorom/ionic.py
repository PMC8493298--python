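"""Phenomenological ionic models: Aliev-Panfilov and Rogers-McCulloch.

Both models describe the transmembrane current ``I_ion(u, w)`` and the
recovery dynamics of a single gating variable ``w``:

* Aliev-Panfilov (dimensionless potential, u in roughly [0, 1])::

      I_ion(u, w) = K u (u - a)(u - 1) + u w
      g(u, w)     = (eps0 + c1 w / (c2 + u)) (-w - K u (u - b - 1))

* Rogers-McCulloch (potential in mV, u in [0, u_p])::

      I_ion(u, w) = G u (1 - u/u_th)(1 - u/u_p) + eta1 u w
      g(u, w)     = eta2 (u/u_p - eta3 w)

Sign convention
---------------
The parabolic tissue equation reads ``du/dt + I_ion = div(D grad(u + ue)) +
I_app``, i.e. a positive ``I_ion`` is an outward (repolarizing) current.  The
gating variable evolves as ``dw/dt = g(u, w)``: ``g`` as written above is the
*right-hand side* of the recovery ODE, so ``w`` grows during the action
potential and relaxes back to zero at rest.  Integrators must apply ``g``
with this sign; flipping it makes the rest state unstable.

Time is in ms throughout and the membrane capacitance coefficient
multiplying ``du/dt`` is absorbed into the model constants (equal to one).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np

from .errors import InvalidInputError, SingularDenominatorError

__all__ = [
    "IonicModel",
    "IonicModelParams",
    "reaction_terms",
    "gating_linear_coeffs",
    "potential_scale",
    "PRESETS",
]


class IonicModel(str, Enum):
    ALIEV_PANFILOV = "aliev_panfilov"
    ROGERS_MCCULLOCH = "rogers_mcculloch"


@dataclass(frozen=True, repr=False)
class IonicModelParams:
    """Constants of one phenomenological ionic model.

    Exactly one parameter set is populated, selected by ``model_id``;
    accessing a constant of the other model raises ``AttributeError``.
    """

    model_id: IonicModel
    # Aliev-Panfilov constants (dimensionless)
    K: float | None = None
    a: float | None = None
    b: float | None = None
    eps0: float | None = None
    c1: float | None = None
    c2: float | None = None
    # Rogers-McCulloch constants
    G: float | None = None          # 1/ms
    eta1: float | None = None       # 1/ms
    eta2: float | None = None       # dimensionless
    eta3: float | None = None       # dimensionless
    u_th: float | None = None       # mV, threshold potential
    u_p: float | None = None        # mV, peak potential

    _AP_FIELDS = ("K", "a", "b", "eps0", "c1", "c2")
    _RM_FIELDS = ("G", "eta1", "eta2", "eta3", "u_th", "u_p")

    def __post_init__(self):
        model = IonicModel(self.model_id)
        object.__setattr__(self, "model_id", model)
        if model is IonicModel.ALIEV_PANFILOV:
            own, other = self._AP_FIELDS, self._RM_FIELDS
        else:
            own, other = self._RM_FIELDS, self._AP_FIELDS
        for name in own:
            value = object.__getattribute__(self, name)
            if value is None:
                raise InvalidInputError(f"{model.value} requires '{name}'")
            if not np.isfinite(value):
                raise InvalidInputError(f"'{name}' must be finite")
        for name in other:
            if object.__getattribute__(self, name) is not None:
                raise InvalidInputError(
                    f"'{name}' does not belong to the {model.value} model"
                )
        if model is IonicModel.ALIEV_PANFILOV:
            if not (0.0 < self.a < 1.0):
                raise InvalidInputError("A-P threshold must satisfy 0 < a < 1")
            for name in ("K", "eps0", "c1", "c2"):
                if getattr(self, name) <= 0:
                    raise InvalidInputError(f"A-P constant '{name}' must be > 0")
            if self.b <= 0:
                raise InvalidInputError("A-P constant 'b' must be > 0")
        else:
            for name in ("G", "eta1", "eta2", "eta3", "u_th", "u_p"):
                if getattr(self, name) <= 0:
                    raise InvalidInputError(f"R-M constant '{name}' must be > 0")
            if not (self.u_p > self.u_th > 0):
                raise InvalidInputError("R-M requires u_p > u_th > 0")

    def __getattribute__(self, name):
        value = object.__getattribute__(self, name)
        if name in ("_AP_FIELDS", "_RM_FIELDS") or name.startswith("__"):
            return value
        cls = type(self)
        if name in cls._AP_FIELDS or name in cls._RM_FIELDS:
            model = object.__getattribute__(self, "model_id")
            if model is IonicModel.ALIEV_PANFILOV and name in cls._RM_FIELDS:
                raise AttributeError(
                    f"'{name}' is a Rogers-McCulloch constant; model is A-P"
                )
            if model is IonicModel.ROGERS_MCCULLOCH and name in cls._AP_FIELDS:
                raise AttributeError(
                    f"'{name}' is an Aliev-Panfilov constant; model is R-M"
                )
        return value

    def __repr__(self):
        cls = type(self)
        own = cls._AP_FIELDS if self.model_id is IonicModel.ALIEV_PANFILOV else cls._RM_FIELDS
        parts = ", ".join(f"{k}={object.__getattribute__(self, k)!r}" for k in own)
        return f"IonicModelParams({self.model_id.value}, {parts})"


def _check_finite(u: np.ndarray, w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(w))):
        raise InvalidInputError("non-finite potential or gating value")
    return u, w


def reaction_terms(params: IonicModelParams, u, w):
    """Evaluate ``(I_ion(u, w), g(u, w))`` elementwise.

    ``u`` and ``w`` may be scalars or arrays of matching (broadcastable)
    shape; the solver calls this at every quadrature point per time step.
    Returns arrays of the broadcast shape.  See the module docstring for the
    sign convention (``du/dt + I_ion = ...``, ``dw/dt = g``).
    """
    u, w = _check_finite(u, w)
    if params.model_id is IonicModel.ALIEV_PANFILOV:
        denom = params.c2 + u
        if np.any(denom == 0.0):
            raise SingularDenominatorError("c2 + u vanished in A-P gating term")
        i_ion = params.K * u * (u - params.a) * (u - 1.0) + u * w
        g = (params.eps0 + params.c1 * w / denom) * (
            -w - params.K * u * (u - params.b - 1.0)
        )
    else:
        i_ion = (
            params.G * u * (1.0 - u / params.u_th) * (1.0 - u / params.u_p)
            + params.eta1 * u * w
        )
        g = params.eta2 * (u / params.u_p - params.eta3 * w)
    return i_ion, g


def gating_linear_coeffs(params: IonicModelParams, u, w_star):
    """Coefficients ``(g0, g1)`` such that ``dw/dt = g0(u) + g1(u) * w``.

    Used by the semi-implicit integrator: given the potential (at the BDF2
    extrapolant) the recovery ODE is treated implicitly in ``w``.  The R-M
    model is exactly linear in ``w``; the A-P model is quadratic through its
    restitution factor ``eps0 + c1 w/(c2+u)``, which is frozen at the
    extrapolated gating value ``w_star`` (second-order accurate).
    """
    u, w_star = _check_finite(u, w_star)
    if params.model_id is IonicModel.ALIEV_PANFILOV:
        denom = params.c2 + u
        if np.any(denom == 0.0):
            raise SingularDenominatorError("c2 + u vanished in A-P gating term")
        eps = params.eps0 + params.c1 * w_star / denom
        g0 = -eps * params.K * u * (u - params.b - 1.0)
        g1 = -eps
    else:
        g0 = params.eta2 / params.u_p * u
        g1 = -params.eta2 * params.eta3 * np.ones_like(u)
    return g0, g1


def potential_scale(params: IonicModelParams) -> float:
    """Peak potential: 1 for the dimensionless A-P model, u_p (mV) for R-M."""
    if params.model_id is IonicModel.ALIEV_PANFILOV:
        return 1.0
    return float(params.u_p)


def _ap_preset() -> IonicModelParams:
    return IonicModelParams(
        model_id=IonicModel.ALIEV_PANFILOV,
        K=8.0, a=0.1, b=0.1, eps0=0.01, c1=0.05, c2=0.3,
    )


def _rm_preset() -> IonicModelParams:
    return IonicModelParams(
        model_id=IonicModel.ROGERS_MCCULLOCH,
        G=1.5, eta1=4.4, eta2=1.2e-2, eta3=1.0, u_th=13.0, u_p=100.0,
    )


#: Named parameter sets used by the shipped slab / atrium benchmarks.
PRESETS = {
    "test1_1_rm": _rm_preset(),
    "test1_2_ap": _ap_preset(),
}
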