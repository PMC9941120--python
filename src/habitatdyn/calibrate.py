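"""Model calibration, goodness-of-fit and parsimony-based model selection.

Each variant of the habitat ODE family is fitted to one subject's
habitat-volume time series by bounded nonlinear least squares on normalized
residuals, restarted from Latin-hypercube initial guesses within the fitting
bounds.  Initial compartment volumes are taken from the first imaging visit.

Residuals are normalized per habitat by that habitat's maximum observed
volume, making the residual sum of squares (RSS) dimensionless and
comparable across habitats of very different size.  Goodness of fit is
summarized by per-habitat normalized SSE and Lin's concordance correlation
coefficient (CCC); parsimony by the small-sample-corrected Akaike
information criterion

    AICc = T ln(RSS / T) + 2 k + 2 k (k + 1) / (T - k - 1),

where T counts residual points (visits x 3 habitats) and k the variant's
free parameters.  The variant with the smallest AICc wins; ties break toward
fewer parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .habitats import HABITAT_NAMES, HabitatSeries
from .models import (
    PARAM_BOUNDS,
    PARAM_NAMES,
    IntegrationError,
    ModelParams,
    ModelVariant,
    simulate,
)

__all__ = [
    "CalibrationResult",
    "normalized_residuals",
    "normalized_sse",
    "ccc",
    "aicc",
    "fit",
    "fit_all_variants",
    "select_model",
    "compare_cohort_params",
]


@dataclass
class CalibrationResult:
    """Outcome of calibrating one variant to one subject's series."""

    variant: ModelVariant
    params: ModelParams
    rss: float
    sse_per_habitat: np.ndarray
    aicc: float
    ccc: float
    T: int
    k: int
    n_starts: int
    converged_fraction: float
    subject_id: str = ""
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.name,
            "params": {n: getattr(self.params, n) for n in PARAM_NAMES},
            "rss": self.rss,
            "sse_per_habitat": dict(zip(HABITAT_NAMES, map(float, self.sse_per_habitat))),
            "aicc": self.aicc,
            "ccc": self.ccc,
            "T": self.T,
            "k": self.k,
            "n_starts": self.n_starts,
            "converged_fraction": self.converged_fraction,
            "subject_id": self.subject_id,
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# residuals and fit metrics
# ---------------------------------------------------------------------------

def _habitat_scales(series: HabitatSeries) -> tuple[np.ndarray, list[str]]:
    scales = series.volumes.max(axis=0)
    flags = []
    if np.any(scales == 0):
        fallback = scales.max()
        if fallback == 0:
            raise ValueError("all observed volumes are zero; nothing to normalize by")
        for h in np.flatnonzero(scales == 0):
            flags.append(f"habitat {HABITAT_NAMES[h]} all-zero; normalized by global max")
        scales = np.where(scales == 0, fallback, scales)
    return scales, flags


def normalized_residuals(trajectory: np.ndarray, series: HabitatSeries) -> np.ndarray:
    """Residual vector (model - data) scaled by per-habitat max observed volume.

    The trajectory must be evaluated at the series' visit days.  Returned
    flat with visit-major order; reshape to (n_visits, 3) to recover the
    per-habitat layout.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape != series.volumes.shape:
        raise ValueError(
            f"trajectory shape {trajectory.shape} does not match observed "
            f"{series.volumes.shape}"
        )
    scales, _ = _habitat_scales(series)
    return ((trajectory - series.volumes) / scales).ravel()


def normalized_sse(trajectory: np.ndarray, series: HabitatSeries) -> np.ndarray:
    """Per-habitat normalized sum of squared errors (3-vector)."""
    r = normalized_residuals(trajectory, series).reshape(series.volumes.shape)
    return (r ** 2).sum(axis=0)


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    Degenerate cases: both sequences constant and equal -> 1; one or both
    constant otherwise -> 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("ccc needs two equal-length sequences of length >= 2")
    vx, vy = x.var(), y.var()
    mx, my = x.mean(), y.mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * np.mean((x - mx) * (y - my)) / denom)


def aicc(rss: float, T: int, k: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if rss <= 0:
        raise ValueError(f"rss must be positive, got {rss}")
    if T - k - 1 <= 0:
        raise ValueError(
            f"AICc undefined: T - k - 1 = {T - k - 1} <= 0 (T={T}, k={k}); "
            "too few residual points for this many parameters"
        )
    return T * math.log(rss / T) + 2 * k + 2 * k * (k + 1) / (T - k - 1)


# ---------------------------------------------------------------------------
# multistart bounded least-squares calibration
# ---------------------------------------------------------------------------

def _lhs_starts(
    variant: ModelVariant,
    n_starts: int,
    series: HabitatSeries,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latin-hypercube initial guesses over the fitting bounds.

    Rates sample uniformly over their box; carrying-capacity guesses sample
    log-uniformly between the maximum observed total volume and the upper
    bound, since theta below the observed volume is implausible as a start.
    """
    names = variant.free_names
    sampler = qmc.LatinHypercube(d=len(names), seed=rng)
    # Blocks of 10 from one sampler stream: the first n starts of a larger
    # multistart are exactly the starts of a smaller one (same seed), so more
    # restarts can only improve the best RSS.
    blocks = []
    while 10 * len(blocks) < n_starts:
        blocks.append(sampler.random(10))
    unit = np.vstack(blocks)[:n_starts]
    starts = np.empty_like(unit)
    theta_lo = max(series.total_volumes.max(), 1.0)
    theta_hi = PARAM_BOUNDS["theta"][1]
    theta_lo = min(theta_lo, theta_hi * 0.99)
    for j, name in enumerate(names):
        if name == "theta":
            starts[:, j] = np.exp(
                np.log(theta_lo) + unit[:, j] * (np.log(theta_hi) - np.log(theta_lo))
            )
        else:
            lo, hi = PARAM_BOUNDS[name]
            starts[:, j] = lo + unit[:, j] * (hi - lo)
    return starts


def _expand(variant: ModelVariant, free_values: np.ndarray) -> ModelParams:
    full = dict.fromkeys(PARAM_NAMES, 0.0)
    full.update(dict(zip(variant.free_names, free_values)))
    full["theta"] = max(full["theta"], 1e-12)  # guard the positivity invariant
    return ModelParams(**full)


def fit(
    variant: ModelVariant,
    series: HabitatSeries,
    n_starts: int = 50,
    seed: int | None = None,
    sim_rtol: float = 1e-10,
    sim_atol: float = 1e-12,
) -> CalibrationResult:
    """Calibrate one variant to one series by multistart bounded least squares.

    ``n_starts`` Latin-hypercube guesses are refined with a trust-region
    least-squares solver under the fitting box constraints; the solution with
    the lowest RSS is kept.  Initial compartment volumes come from the first
    visit and are not fitted.
    """
    rng = np.random.default_rng(seed)
    initial = series.volumes[0]
    days = series.days
    data = series.volumes

    if np.all(data == 0):
        # no dynamics and no scale: report the trivial exact solution
        params = _expand(variant, np.array(
            [PARAM_BOUNDS[n][0] for n in variant.free_names]))
        return CalibrationResult(
            variant=variant, params=params, rss=0.0,
            sse_per_habitat=np.zeros(3), aicc=math.nan, ccc=1.0,
            T=data.size, k=variant.k, n_starts=n_starts,
            converged_fraction=1.0, subject_id=series.subject_id,
            flags=["degenerate series: all volumes zero"],
        )

    scales, flags = _habitat_scales(series)
    degenerate = bool(np.all(data == data[0]))  # no dynamics to fit

    names = variant.free_names
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])
    if "theta" in names:
        j = names.index("theta")
        lo[j] = 1e-3  # theta = 0 is singular; keep strictly positive

    def residual_fn(free_values: np.ndarray) -> np.ndarray:
        params = _expand(variant, free_values)
        try:
            traj = simulate(variant, params, initial, days,
                            rtol=sim_rtol, atol=sim_atol)
        except IntegrationError:
            return np.full(data.size, 1e6)
        return ((traj - data) / scales).ravel()

    starts = _lhs_starts(variant, n_starts, series, rng)
    best = None
    n_converged = 0
    failures = []
    for x0 in starts:
        try:
            sol = least_squares(
                residual_fn, np.clip(x0, lo, hi), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # noqa: BLE001 - collected for diagnostics
            failures.append(str(exc))
            continue
        n_converged += int(sol.success)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"all {n_starts} calibration starts failed for variant "
            f"{variant.name}: {failures[:3]}"
        )

    params = _expand(variant, best.x)
    traj = simulate(variant, params, initial, days, rtol=sim_rtol, atol=sim_atol)
    resid = ((traj - data) / scales).ravel()
    rss = float(resid @ resid)
    sse = ((traj - data) / scales) ** 2
    T = data.size
    k = variant.k
    try:
        aicc_value = aicc(rss, T, k) if rss > 0 else -math.inf
    except ValueError:
        aicc_value = math.nan
        flags = flags + [f"aicc undefined (T={T}, k={k})"]
    if degenerate:
        flags = flags + ["degenerate series: no dynamics"]
    return CalibrationResult(
        variant=variant,
        params=params,
        rss=rss,
        sse_per_habitat=sse.sum(axis=0),
        aicc=aicc_value,
        ccc=ccc(traj.ravel(), data.ravel()),
        T=T,
        k=k,
        n_starts=n_starts,
        converged_fraction=n_converged / n_starts,
        subject_id=series.subject_id,
        flags=flags,
    )


def fit_all_variants(
    series: HabitatSeries,
    variants: Sequence[ModelVariant] | None = None,
    n_starts: int = 50,
    seed: int | None = None,
) -> list[CalibrationResult]:
    """Calibrate every variant to one series (independent multistarts)."""
    from .models import VARIANTS

    if variants is None:
        variants = list(VARIANTS.values())
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(variants))
    return [
        fit(v, series, n_starts=n_starts, seed=s)
        for v, s in zip(variants, seeds)
    ]


def select_model(results: Sequence[CalibrationResult]) -> CalibrationResult:
    """Pick the most parsimonious calibration by smallest AICc.

    Non-finite AICc values are excluded (with a warning flag on the chosen
    result); AICc ties within 1e-9 break toward fewer free parameters.
    """
    finite = [r for r in results if math.isfinite(r.aicc)]
    excluded = [r.variant.name for r in results if not math.isfinite(r.aicc)]
    if not finite:
        raise ValueError("no variant produced a finite AICc")
    best = min(finite, key=lambda r: (r.aicc, r.k))
    for r in finite:
        if r is not best and abs(r.aicc - best.aicc) <= 1e-9 and r.k < best.k:
            best = r
    if excluded:
        best.flags = best.flags + [f"variants excluded (non-finite AICc): {excluded}"]
    return best


def compare_cohort_params(
    control: Sequence[CalibrationResult],
    treated: Sequence[CalibrationResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter two-sided Wilcoxon rank-sum comparison across cohorts."""
    if len(control) < 3 or len(treated) < 3:
        raise ValueError("need at least 3 subjects per cohort")
    rows = []
    for name in PARAM_NAMES:
        a = np.array([getattr(r.params, name) for r in control])
        b = np.array([getattr(r.params, name) for r in treated])
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = 0.0, 1.0  # identical degenerate distributions
        else:
            stat, p = stats.ranksums(a, b)
        rows.append({
            "parameter": name,
            "control_median": float(np.median(a)),
            "treated_median": float(np.median(b)),
            "statistic": float(stat),
            "p_value": float(p),
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)
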