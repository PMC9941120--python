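"""Forward and inverse models for the four quantitative MRI parameters.

DCE-MRI is analyzed with the standard Kety-Tofts model: tissue contrast
concentration is the convolution of the arterial input function (AIF)
C_p with an exponential impulse response,

    C_t(t) = K^trans * integral_0^t C_p(u) exp(-(K^trans/v_e)(t - u)) du,

yielding the volume transfer constant K^trans (min^-1), the
extravascular/extracellular volume fraction v_e (unitless) and the efflux
rate k_ep = K^trans / v_e (min^-1).  DW-MRI is analyzed with the
monoexponential decay S(b) = S0 exp(-b * ADC), fitted log-linearly.  A
reference-tissue ratio correction compensates slow scanner/physiology drift
between visits using a stable muscle ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AifSpec",
    "VoxelFeatures",
    "kety_tofts_forward",
    "fit_kety_tofts",
    "fit_adc",
    "reference_correct",
]

KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (1e-6, 1.0)


@dataclass(frozen=True)
class VoxelFeatures:
    """Per-voxel quantitative-MRI 4-vector, the clustering feature space."""

    ktrans: float  # min^-1
    ve: float      # unitless fraction
    kep: float     # min^-1
    adc: float     # mm^2/s

    def __post_init__(self) -> None:
        if self.ktrans < 0 or self.adc < 0:
            raise ValueError("ktrans and adc must be non-negative")
        if not 0 < self.ve <= 1:
            raise ValueError(f"ve must be in (0, 1], got {self.ve}")
        expected = self.ktrans / self.ve
        scale = max(abs(expected), 1e-30)
        if abs(self.kep - expected) > 1e-9 * scale:
            raise ValueError(
                f"kep={self.kep} violates kep = ktrans/ve = {expected}"
            )


@dataclass(frozen=True)
class AifSpec:
    """Arterial input function: biexponential, step, or tabulated.

    * ``biexponential``: C_p(t) = sum_i amplitudes[i] * exp(-decays[i] * t),
      the standard population-AIF form.
    * ``step``: constant ``amplitudes[0]`` for t >= 0 (closed-form checkable).
    * ``tabulated``: linear interpolation of (times, concentrations) samples.
    """

    form: str = "biexponential"
    amplitudes: tuple[float, ...] = (5.0, 1.0)   # mM
    decays: tuple[float, ...] = (3.0, 0.016)     # min^-1
    times: tuple[float, ...] = ()
    concentrations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.form not in ("biexponential", "step", "tabulated"):
            raise ValueError(f"unknown AIF form {self.form!r}")
        if self.form == "tabulated":
            t = np.asarray(self.times, dtype=float)
            c = np.asarray(self.concentrations, dtype=float)
            if t.size < 2 or t.size != c.size:
                raise ValueError("tabulated AIF needs matching times/concentrations")
            if not np.all(np.diff(t) > 0):
                raise ValueError("tabulated AIF times must be increasing")
            if np.any(c < 0):
                raise ValueError("AIF concentrations must be non-negative")
        elif np.any(np.asarray(self.amplitudes) < 0):
            raise ValueError("AIF amplitudes must be non-negative")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.form == "step":
            return np.where(t >= 0, self.amplitudes[0], 0.0)
        if self.form == "tabulated":
            return np.interp(t, self.times, self.concentrations)
        out = np.zeros_like(t)
        for a, m in zip(self.amplitudes, self.decays):
            out = out + a * np.exp(-m * t)
        return out


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D vector with >= 2 points")
    if times[0] != 0:
        raise ValueError(f"times must start at 0, got {times[0]}")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def kety_tofts_forward(
    ktrans: float,
    ve: float,
    aif: AifSpec,
    times,
    refine: int = 10,
) -> np.ndarray:
    """Tissue concentration curve from the Kety-Tofts convolution.

    The convolution integral is evaluated by trapezoidal quadrature on the
    acquisition grid refined ``refine``-fold internally, then sampled back at
    the requested times.
    """
    times = _check_times(times)
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    if ve <= 0 or ve > 1:
        raise ValueError(f"ve must be in (0, 1], got {ve}")
    if ktrans == 0:
        return np.zeros_like(times)
    kep = ktrans / ve

    # refined uniform grid covering the acquisition window
    n_fine = (times.size - 1) * refine + 1
    tf = np.linspace(times[0], times[-1], n_fine)
    cp = aif(tf)
    # Causal convolution C_t(t_i) = ktrans * int_0^{t_i} cp(u) e^{-kep (t_i-u)} du,
    # advanced with the exponential's semigroup property and the exact integral
    # of a linearly interpolated AIF over each step (exponential integrator).
    # A piecewise-constant AIF (step form) is therefore integrated exactly.
    ct = np.zeros(n_fine)
    dt = tf[1] - tf[0]
    decay = np.exp(-kep * dt)
    w0 = (1.0 - decay) / kep                  # int_0^dt e^{-kep(dt-s)} ds
    w1 = (dt - w0) / (kep * dt)               # int_0^dt (s/dt) e^{-kep(dt-s)} ds
    for i in range(1, n_fine):
        increment = cp[i - 1] * w0 + (cp[i] - cp[i - 1]) * w1
        ct[i] = ct[i - 1] * decay + ktrans * increment
    return np.interp(times, tf, ct)


def fit_kety_tofts(
    curve,
    aif: AifSpec,
    times,
    x0: tuple[float, float] = (0.1, 0.2),
) -> dict:
    """Least-squares Kety-Tofts estimates (ktrans, ve, kep) from a curve.

    Box constraints: ktrans in [0, 5] min^-1, ve in (0, 1].  A single start
    suffices here; the inverse problem is well-conditioned.  An all-zero
    curve returns (0, lower-bound ve, 0) flagged degenerate.
    """
    times = _check_times(times)
    curve = np.asarray(curve, dtype=float)
    if curve.shape != times.shape:
        raise ValueError("curve and times must have the same shape")
    if times.size < 4:
        raise ValueError("need at least 4 time points to fit two parameters")
    if np.allclose(curve, 0):
        return {"ktrans": 0.0, "ve": VE_BOUNDS[0], "kep": 0.0, "degenerate": True}

    def resid(x):
        return kety_tofts_forward(x[0], x[1], aif, times) - curve

    sol = least_squares(
        resid, x0,
        bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]], [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    ktrans, ve = sol.x
    return {"ktrans": float(ktrans), "ve": float(ve),
            "kep": float(ktrans / ve), "degenerate": False}


def fit_adc(signals, bvalues) -> dict:
    """Monoexponential ADC fit by log-linear least squares.

    Returns the apparent diffusion coefficient (mm^2/s) and extrapolated
    b=0 signal.  Non-positive signals exclude the voxel (flagged), since the
    log transform is undefined there.
    """
    signals = np.asarray(signals, dtype=float)
    bvalues = np.asarray(bvalues, dtype=float)
    if signals.shape != bvalues.shape or signals.size < 2:
        raise ValueError("need >= 2 signals at matching b-values")
    if np.unique(bvalues).size < 2:
        raise ValueError("need >= 2 distinct b-values")
    if np.any(signals <= 0):
        return {"adc": np.nan, "s0": np.nan, "excluded": True}
    slope, intercept = np.polyfit(bvalues, np.log(signals), 1)
    return {"adc": float(-slope), "s0": float(np.exp(intercept)), "excluded": False}


def reference_correct(
    tumor_value: float,
    muscle_value_this_visit: float,
    muscle_reference_value: float,
) -> float:
    """Ratio-form reference-tissue drift correction.

    Scales a tumor parameter by (reference muscle value / this visit's muscle
    value), so visits where the whole acquisition reads high are pulled back
    down.  A non-positive muscle value skips the correction with a warning.
    """
    if muscle_value_this_visit <= 0 or muscle_reference_value <= 0:
        import warnings

        warnings.warn(
            "non-positive muscle value; reference correction skipped",
            stacklevel=2,
        )
        return tumor_value
    return tumor_value * (muscle_reference_value / muscle_value_this_visit)


def reference_correct_cohort(
    tumor_values: Sequence[float],
    muscle_values: Sequence[float],
    reference: float | None = None,
) -> np.ndarray:
    """Apply the ratio correction across visits.

    The reference defaults to the median muscle value across visits, so the
    correction is an identity on average.
    """
    tumor_values = np.asarray(tumor_values, dtype=float)
    muscle_values = np.asarray(muscle_values, dtype=float)
    if reference is None:
        reference = float(np.median(muscle_values))
    return np.array([
        reference_correct(tv, mv, reference)
        for tv, mv in zip(tumor_values, muscle_values)
    ])
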