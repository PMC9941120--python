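"""Coupled-ODE family for tumor-habitat volume dynamics.

Three compartments track the volumes (mm^3) of the image-defined habitats:

* ``C1`` — high-vascularity high-cellularity (HV-HC) rim,
* ``C2`` — low-vascularity high-cellularity (LV-HC) band,
* ``C3`` — low-vascularity low-cellularity (LV-LC, necrotic-like) core.

The parent model has logistic growth of C1 and C2 against a shared carrying
capacity ``theta`` and first-order transitions C1->C2, C2->C1, C1->C3 and
C2->C3; C3 only accumulates.  Three nested variants zero out the rarely
observed back-transition (C2->C1) and/or the direct necrosis route (C1->C3):

=======  ==================  ==============
variant  rates fixed to 0    free parameters
=======  ==================  ==============
A        —                   7
B        d21                 6
C        d13                 6
D        d21, d13            5
=======  ==================  ==============
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "PARAM_NAMES",
    "RATE_BOUNDS",
    "THETA_BOUNDS",
    "PARAM_BOUNDS",
    "ModelParams",
    "ModelVariant",
    "VARIANTS",
    "rhs",
    "simulate",
    "IntegrationError",
]

#: Canonical parameter order used everywhere a flat vector is exchanged.
PARAM_NAMES = ("k1", "k2", "d12", "d21", "d13", "d23", "theta")

#: Box constraints used in nonlinear fitting (rates in day^-1, theta in mm^3).
RATE_BOUNDS = (0.0, 5.0)
THETA_BOUNDS = (0.0, 2000.0)
PARAM_BOUNDS: Mapping[str, tuple[float, float]] = {
    **{name: RATE_BOUNDS for name in PARAM_NAMES[:-1]},
    "theta": THETA_BOUNDS,
}

#: Undershoots below this (mm^3) abort integration; milder ones clamp to 0.
_NEG_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces invalid state."""


@dataclass(frozen=True)
class ModelParams:
    """Parent-model parameters.

    Rates (``k1``, ``k2``, ``d12``, ``d21``, ``d13``, ``d23``) carry units of
    day^-1; ``theta`` is the carrying capacity in mm^3.
    """

    k1: float
    k2: float
    d12: float
    d21: float
    d13: float
    d23: float
    theta: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES[:-1]:
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"rate {name} must be non-negative, got {value}")
        if self.theta <= 0:
            raise ValueError(f"carrying capacity theta must be positive, got {self.theta}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def within_bounds(self, atol: float = 0.0) -> bool:
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            value = getattr(self, name)
            if value < lo - atol or value > hi + atol:
                return False
        return True


@dataclass(frozen=True)
class ModelVariant:
    """A member of the nested model family, defined by rates pinned to zero."""

    name: str
    fixed_zero: frozenset[str]

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.fixed_zero)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(PARAM_NAMES) - len(self.fixed_zero)

    def validate_params(self, params: ModelParams) -> None:
        for name in self.fixed_zero:
            if getattr(params, name) != 0.0:
                raise ValueError(
                    f"variant {self.name} fixes {name}=0 but params carry "
                    f"{name}={getattr(params, name)}"
                )


VARIANTS: Mapping[str, ModelVariant] = {
    "A": ModelVariant("A", frozenset()),
    "B": ModelVariant("B", frozenset({"d21"})),
    "C": ModelVariant("C", frozenset({"d13"})),
    "D": ModelVariant("D", frozenset({"d21", "d13"})),
}


def _rhs_core(state, t, k1, k2, d12, d21, d13, d23, theta):
    c1, c2, c3 = state
    growth = 1.0 - (c1 + c2 + c3) / theta
    dc1 = k1 * c1 * growth - d12 * c1 + d21 * c2 - d13 * c1
    dc2 = k2 * c2 * growth + d12 * c1 - d21 * c2 - d23 * c2
    dc3 = d13 * c1 + d23 * c2
    return [dc1, dc2, dc3]


def rhs(variant: ModelVariant, params: ModelParams, state, t: float = 0.0) -> np.ndarray:
    """Time derivative of the habitat volumes (mm^3/day).

    The instantaneous total-volume fraction V = (C1+C2+C3)/theta is evaluated
    from the supplied state at every call.
    """
    variant.validate_params(params)
    state = np.asarray(state, dtype=float)
    if state.shape != (3,):
        raise ValueError(f"state must be a 3-vector, got shape {state.shape}")
    return np.array(
        _rhs_core(
            state, t, params.k1, params.k2, params.d12, params.d21,
            params.d13, params.d23, params.theta,
        )
    )


def simulate(
    variant: ModelVariant,
    params: ModelParams,
    initial,
    days,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the variant forward, returning volumes at the requested days.

    Parameters
    ----------
    initial : array-like, shape (3,)
        Habitat volumes (mm^3) at ``days[0]``.
    days : array-like, increasing from 0
        Observation times in days.

    Returns
    -------
    ndarray, shape (len(days), 3)
        Columns are (C1, C2, C3) in mm^3.  Tiny negative undershoots (above
        -1e-9 mm^3) are clamped to zero; larger ones raise
        :class:`IntegrationError`.
    """
    variant.validate_params(params)
    days = np.asarray(days, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if days.ndim != 1 or days.size < 1:
        raise ValueError("days must be a non-empty 1-D vector")
    if days[0] != 0:
        raise ValueError(f"days must start at 0, got {days[0]}")
    if days.size > 1 and not np.all(np.diff(days) > 0):
        raise ValueError("days must be strictly increasing")
    if initial.shape != (3,) or np.any(initial < 0):
        raise ValueError("initial state must be three non-negative volumes")

    if days.size == 1:
        return initial[None, :].copy()

    args = (params.k1, params.k2, params.d12, params.d21,
            params.d13, params.d23, params.theta)
    traj, info = odeint(
        _rhs_core, initial, days, args=args,
        rtol=rtol, atol=atol, full_output=True, mxstep=10000,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"ODE integration failed for variant {variant.name} with params "
            f"{params}: {info['message']}"
        )
    if np.any(traj < -_NEG_TOL):
        raise IntegrationError(
            f"trajectory undershot below {-_NEG_TOL} mm^3 for params {params}"
        )
    return np.clip(traj, 0.0, None)
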