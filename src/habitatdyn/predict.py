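"""Forecasting a held-out subject's habitat dynamics from a calibrated cohort.

Two complementary strategies:

* **Leave-one-out (LOO) weighted averaging** — the held-out subject's
  parameters are a similarity-weighted average of the cohort's fitted
  parameters.  Similarity is inverse distance on a first-visit summary under
  one of three schemes: initial total tumor volume, initial habitat
  composition (volume fractions), or initial HV-HC volume.

* **Bootstrap with data updating** — each parameter gets a normal
  distribution from the cohort's leave-one-out mean and SD, sampled N_b
  times restricted to the central (25th-75th percentile) interval; every
  draw is simulated and the pointwise mean forms the forecast, with a
  2.5/97.5-percentile band.  As the subject's early visits arrive, the
  bootstrap mean curve is blended with an individual calibration to those
  visits, with blend weight w = (v - 1)/(V_total - 1) growing linearly in
  the number of visits used.

Forecast error is the per-habitat normalized SSE against the held-out
visits, and methods are compared per habitat with Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import CalibrationResult, fit, normalized_sse
from .habitats import HABITAT_NAMES, HabitatSeries
from .models import ModelParams, ModelVariant, simulate

__all__ = [
    "LOO_SCHEMES",
    "BootstrapConfig",
    "PredictionResult",
    "initial_summary",
    "loo_weights",
    "loo_predict",
    "bootstrap_predict",
    "update_with_data",
    "compare_predictions",
]

#: The three similarity schemes for LOO weighting.
LOO_SCHEMES = ("initial_total_volume", "initial_composition", "initial_HVHC_volume")

_EPS = 1e-6  # smoothing of the inverse-distance kernel, native units


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for truncated-normal bootstrap forecasting."""

    n_b: int = 200
    truncation: tuple[float, float] = (0.25, 0.75)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_b < 1:
            raise ValueError("n_b must be >= 1")
        lo, hi = self.truncation
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("truncation quantiles must be ordered within [0, 1]")


@dataclass
class PredictionResult:
    """A forecast trajectory with uncertainty band and held-out error."""

    days: np.ndarray
    mean: np.ndarray                 # (n_days, 3) mm^3, columns = habitats
    lower: np.ndarray
    upper: np.ndarray
    sse_per_habitat: np.ndarray | None
    method: str
    n_visits_used: int = 1
    subject_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        for name in ("mean", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (np.all(self.lower <= self.mean + 1e-9)
                and np.all(self.mean <= self.upper + 1e-9)):
            raise ValueError("band must bracket the mean pointwise")
        if self.sse_per_habitat is not None and np.any(np.asarray(self.sse_per_habitat) < 0):
            raise ValueError("SSE must be non-negative")


def initial_summary(series: HabitatSeries, scheme: str) -> np.ndarray:
    """First-visit summary on which a LOO similarity scheme measures distance."""
    v0 = series.volumes[0]
    if scheme == "initial_total_volume":
        return np.array([v0.sum()])
    if scheme == "initial_composition":
        total = v0.sum()
        if total == 0:
            raise ValueError("initial composition undefined for zero total volume")
        return v0 / total
    if scheme == "initial_HVHC_volume":
        return np.array([v0[0]])
    raise ValueError(f"unknown LOO scheme {scheme!r}")


def loo_weights(
    scheme: str,
    heldout_summary,
    cohort_summaries: Sequence,
) -> np.ndarray:
    """Inverse-distance similarity weights, normalized to sum to one.

    w_i is proportional to 1/(d_i + eps) with Euclidean distance d_i between
    first-visit summaries and eps = 1e-6 in native units, so an exact match
    dominates without dividing by zero.
    """
    if scheme not in LOO_SCHEMES:
        raise ValueError(f"unknown LOO scheme {scheme!r}")
    if len(cohort_summaries) == 0:
        raise ValueError("cohort must have at least one member")
    heldout = np.asarray(heldout_summary, dtype=float)
    dists = np.array([
        np.linalg.norm(np.asarray(s, dtype=float) - heldout)
        for s in cohort_summaries
    ])
    w = 1.0 / (dists + _EPS)
    return w / w.sum()


def _check_common_variant(cohort: Sequence[CalibrationResult]) -> ModelVariant:
    if len(cohort) == 0:
        raise ValueError("cohort must not be empty")
    variants = {r.variant.name for r in cohort}
    if len(variants) != 1:
        raise ValueError(f"cohort results mix variants: {sorted(variants)}")
    return cohort[0].variant


def _heldout_sse(trajectory: np.ndarray, days: np.ndarray,
                 heldout: HabitatSeries) -> np.ndarray | None:
    """Normalized SSE against held-out data when the grid covers its visits."""
    if days.shape == heldout.days.shape and np.allclose(days, heldout.days):
        return normalized_sse(trajectory, heldout)
    return None


def loo_predict(
    scheme: str,
    heldout: HabitatSeries,
    cohort: Sequence[tuple[CalibrationResult, HabitatSeries]],
    days=None,
) -> PredictionResult:
    """Similarity-weighted leave-one-out forecast for a held-out subject.

    ``cohort`` pairs each remaining subject's calibration with its observed
    series (the series supplies the first-visit summary that the similarity
    kernel compares against the held-out subject).  The forecast parameter
    vector is the weighted average of cohort fitted parameters; the
    trajectory starts from the held-out subject's first-visit volumes.
    """
    results = [r for r, _ in cohort]
    variant = _check_common_variant(results)
    weights = loo_weights(
        scheme,
        initial_summary(heldout, scheme),
        [initial_summary(s, scheme) for _, s in cohort],
    )
    param_matrix = np.vstack([r.params.to_array() for r in results])
    params = ModelParams.from_array(weights @ param_matrix)
    if days is None:
        days = heldout.days
    days = np.asarray(days, dtype=float)
    traj = simulate(variant, params, heldout.volumes[0], days)
    return PredictionResult(
        days=days, mean=traj, lower=traj, upper=traj,
        sse_per_habitat=_heldout_sse(traj, days, heldout),
        method=f"LOO-{scheme}",
        n_visits_used=1,
        subject_id=heldout.subject_id,
        extra={"weights": weights, "params": params},
    )


def _truncated_normal_draws(
    mean: np.ndarray,
    sd: np.ndarray,
    truncation: tuple[float, float],
    n_b: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-CDF sampling of each parameter's normal within its central band.

    Drawing u ~ Uniform(q_lo, q_hi) and mapping through the normal quantile
    function restricts samples to the (q_lo, q_hi) percentile interval
    deterministically per seed (no rejection).  Zero-SD parameters stay
    fixed at their mean.
    """
    lo, hi = truncation
    u = rng.uniform(lo, hi, size=(n_b, mean.size))
    draws = stats.norm.ppf(u, loc=mean, scale=np.where(sd > 0, sd, 1.0))
    return np.where(sd > 0, draws, mean)


def bootstrap_predict(
    cohort: Sequence[CalibrationResult],
    heldout_initial,
    days,
    config: BootstrapConfig = BootstrapConfig(),
    heldout: HabitatSeries | None = None,
) -> PredictionResult:
    """Truncated-normal bootstrap forecast from cohort parameter spread.

    Each parameter's normal takes the cohort's (leave-one-out) mean and SD;
    N_b draws restricted to the 25th-75th percentile interval are simulated
    from the held-out subject's first-visit volumes.  The forecast is the
    pointwise mean curve with a 2.5/97.5-percentile band.
    """
    variant = _check_common_variant(cohort)
    if len(cohort) < 2:
        raise ValueError("bootstrap needs >= 2 cohort members for a mean and SD")
    rng = np.random.default_rng(config.seed)
    days = np.asarray(days, dtype=float)
    param_matrix = np.vstack([r.params.to_array() for r in cohort])
    mean = param_matrix.mean(axis=0)
    sd = param_matrix.std(axis=0, ddof=1)
    draws = _truncated_normal_draws(mean, sd, config.truncation, config.n_b, rng)
    draws = np.clip(draws, 0.0, None)  # bounds guard: rates must stay >= 0
    draws[:, -1] = np.maximum(draws[:, -1], 1e-6)  # theta must stay positive
    curves = np.empty((config.n_b, days.size, 3))
    heldout_initial = np.asarray(heldout_initial, dtype=float)
    for i, row in enumerate(draws):
        curves[i] = simulate(variant, ModelParams.from_array(row), heldout_initial, days)
    mean_curve = curves.mean(axis=0)
    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    sse = _heldout_sse(mean_curve, days, heldout) if heldout is not None else None
    return PredictionResult(
        days=days, mean=mean_curve,
        lower=np.minimum(lower, mean_curve), upper=np.maximum(upper, mean_curve),
        sse_per_habitat=sse,
        method="bootstrap",
        n_visits_used=1,
        subject_id=heldout.subject_id if heldout is not None else "",
        extra={"curves": curves, "param_mean": mean, "param_sd": sd,
               "variant": variant},
    )


def update_with_data(
    boot: PredictionResult,
    heldout: HabitatSeries,
    n_visits: int,
    n_starts: int = 20,
    seed: int | None = None,
) -> PredictionResult:
    """Blend the bootstrap forecast with an individual fit to early visits.

    The variant is calibrated to the held-out subject's first ``n_visits``
    visits only, and the blended curve is (1 - w) * bootstrap mean +
    w * individual fit with w = (v - 1)/(V_total - 1), so one visit falls
    back to the pure bootstrap and all visits to the pure individual fit.
    SSE is reported against the withheld later visits.
    """
    total = heldout.n_visits
    if not 1 <= n_visits <= total:
        raise ValueError(f"n_visits must be in [1, {total}]")
    w = (n_visits - 1) / (total - 1)
    days = boot.days
    if days.shape != heldout.days.shape or not np.allclose(days, heldout.days):
        raise ValueError("bootstrap grid must match the held-out visit days")

    flags = []
    if n_visits == 1:
        blended = boot.mean.copy()
        individual = None
    else:
        variant = boot.extra.get("variant")
        if variant is None:
            raise ValueError("bootstrap result lacks 'variant' in extra")
        truncated = heldout.truncate(n_visits)
        calib = fit(variant, truncated, n_starts=n_starts, seed=seed)
        individual = simulate(variant, calib.params, heldout.volumes[0], days)
        blended = (1.0 - w) * boot.mean + w * individual
    if n_visits == total:
        flags.append("pure retrospective fit: no forecast remains")
    withheld = np.arange(n_visits, total)
    if withheld.size > 0:
        scales = heldout.volumes.max(axis=0)
        scales = np.where(scales == 0, max(scales.max(), 1.0), scales)
        r = (blended[withheld] - heldout.volumes[withheld]) / scales
        sse = (r ** 2).sum(axis=0)
    else:
        sse = np.zeros(3)
    lower = np.minimum((1.0 - w) * boot.lower + (w * individual if individual is not None else 0.0), blended)
    upper = np.maximum((1.0 - w) * boot.upper + (w * individual if individual is not None else 0.0), blended)
    return PredictionResult(
        days=days, mean=blended, lower=lower, upper=upper,
        sse_per_habitat=sse,
        method=f"bootstrap-update-{n_visits}v",
        n_visits_used=n_visits,
        subject_id=heldout.subject_id,
        extra={"w": w, "flags": flags},
    )


def compare_predictions(
    results_by_method: dict[str, Sequence[PredictionResult]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-habitat pairwise Wilcoxon rank-sum comparison of forecast SSEs.

    ``results_by_method`` maps method name to one PredictionResult per
    subject; every method must cover the same subjects.  Returns a tidy
    frame of medians, IQRs and pairwise p-values with 5%-level flags.
    """
    methods = list(results_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    subject_sets = {
        m: tuple(sorted(r.subject_id for r in results_by_method[m])) for m in methods
    }
    if len(set(subject_sets.values())) != 1:
        raise ValueError(f"methods evaluated on different subjects: {subject_sets}")
    sse = {
        m: np.vstack([r.sse_per_habitat for r in results_by_method[m]])
        for m in methods
    }
    rows = []
    for h, habitat in enumerate(HABITAT_NAMES):
        for m in methods:
            q1, q3 = np.percentile(sse[m][:, h], [25, 75])
            rows.append({
                "habitat": habitat, "comparison": f"summary {m}",
                "median": float(np.median(sse[m][:, h])),
                "iqr": float(q3 - q1), "p_value": np.nan, "significant": False,
            })
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1:]:
                a, b = sse[m1][:, h], sse[m2][:, h]
                if np.array_equal(a, b):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = stats.ranksums(a, b)
                rows.append({
                    "habitat": habitat, "comparison": f"{m1} vs {m2}",
                    "median": np.nan, "iqr": np.nan,
                    "p_value": float(p), "significant": p < alpha,
                })
    return pd.DataFrame(rows)
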