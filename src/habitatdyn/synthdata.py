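"""Seeded synthetic inputs for every stage of the habitat pipeline.

Three generators cover the pipeline's inputs:

* a 3-D digital phantom with the concentric-shell anatomy of a growing
  solid tumor — a well-perfused HV-HC rim, an LV-HC band, and a
  necrotic-like LV-LC core — whose per-voxel (K^trans, v_e, k_ep, ADC)
  vectors are drawn from habitat-specific normal distributions with the
  published cohort means and SDs;
* raw DCE concentration curves and multi-b-value DW signals to exercise
  the quantitative-MRI fitting layer;
* cohorts of subjects whose habitat-volume time series are forward
  simulations of the ODE family under per-subject parameters, with
  multiplicative observation noise.

Treatment is emulated purely through parameter differences (the ODEs carry
no dose term): the treated cohort's growth-rate distribution locations are
scaled down relative to control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .habitats import HABITAT_NAMES, HabitatSeries
from .models import PARAM_BOUNDS, PARAM_NAMES, ModelParams, ModelVariant, VARIANTS, simulate
from .qmri import AifSpec, kety_tofts_forward

__all__ = [
    "HabitatClassParams",
    "PhantomGeometry",
    "CohortConfig",
    "DEFAULT_CLASS_PARAMS",
    "default_cohort_config",
    "generate_phantom",
    "generate_dce_signal",
    "generate_dw_signal",
    "generate_cohort",
]

#: Positivity floor applied to clipped feature draws, in each native unit.
CLIP_FLOOR = 1e-6


@dataclass(frozen=True)
class HabitatClassParams:
    """Feature-distribution moments for one habitat.

    Vectors are ordered (K^trans min^-1, v_e, k_ep min^-1, ADC mm^2/s).
    Each parameter is drawn as an independent normal; negative draws are
    clipped to a small positive floor.
    """

    habitat_label: str
    mean_vector: tuple[float, float, float, float]
    sd_vector: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.habitat_label not in HABITAT_NAMES:
            raise ValueError(f"unknown habitat label {self.habitat_label!r}")
        if any(m <= 0 for m in self.mean_vector):
            raise ValueError("all feature means must be positive")
        if any(s < 0 for s in self.sd_vector):
            raise ValueError("feature SDs must be non-negative")


#: Cohort feature moments measured in the rat glioma study
#: (k-means habitats over 168k pooled voxels), order (ktrans, ve, kep, adc).
DEFAULT_CLASS_PARAMS: tuple[HabitatClassParams, ...] = (
    HabitatClassParams("HV-HC", (0.307, 0.232, 1.625, 0.826e-3),
                       (0.155, 0.158, 0.788, 0.216e-3)),
    HabitatClassParams("LV-HC", (0.070, 0.181, 0.447, 0.852e-3),
                       (0.054, 0.118, 0.310, 0.186e-3)),
    HabitatClassParams("LV-LC", (0.0276, 0.848, 0.029, 0.945e-3),
                       (0.034, 0.199, 0.097, 0.280e-3)),
)


@dataclass(frozen=True)
class PhantomGeometry:
    """Concentric-shell phantom layout: LV-LC core, LV-HC band, HV-HC rim.

    Default radii scale as 1 : 2^(1/3) : 3^(1/3) so the three shells have
    equal volumes (~3.3k voxels each on the default grid), sampling every
    habitat's feature distribution equally well.
    """

    grid_shape: tuple[int, int, int] = (28, 28, 28)
    voxel_volume: float = 0.1  # mm^3
    core_radius: float = 9.3
    band_radius: float = 11.7
    rim_radius: float = 13.4

    def __post_init__(self) -> None:
        if not 0 < self.core_radius < self.band_radius < self.rim_radius:
            raise ValueError("radii must satisfy 0 < core < band < rim")
        if self.rim_radius > min(self.grid_shape) / 2:
            raise ValueError("rim radius exceeds the grid")
        if self.voxel_volume <= 0:
            raise ValueError("voxel volume must be positive")


def generate_phantom(
    geometry: PhantomGeometry,
    class_params: Sequence[HabitatClassParams] = DEFAULT_CLASS_PARAMS,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shell-structured label map and per-voxel feature map.

    Returns ``(label_map, feature_map)`` where the label map holds 0 for
    background and 1/2/3 for (HV-HC rim, LV-HC band, LV-LC core), and the
    feature map is (x, y, z, 4) with channels (ktrans, ve, kep, adc);
    background voxels carry NaN features.
    """
    labels_given = [cp.habitat_label for cp in class_params]
    if sorted(labels_given) != sorted(HABITAT_NAMES):
        raise ValueError(f"need one parameter set per habitat, got {labels_given}")
    by_label = {cp.habitat_label: cp for cp in class_params}

    rng = np.random.default_rng(seed)
    center = (np.array(geometry.grid_shape) - 1) / 2.0
    coords = np.indices(geometry.grid_shape)
    r = np.sqrt(sum((coords[i] - center[i]) ** 2 for i in range(3)))

    label_map = np.zeros(geometry.grid_shape, dtype=np.int8)
    label_map[r <= geometry.rim_radius] = 1     # HV-HC rim (outermost shell)
    label_map[r <= geometry.band_radius] = 2    # LV-HC band
    label_map[r <= geometry.core_radius] = 3    # LV-LC core

    feature_map = np.full(geometry.grid_shape + (4,), np.nan)
    for code, name in zip((1, 2, 3), HABITAT_NAMES):
        mask = label_map == code
        n = int(mask.sum())
        cp = by_label[name]
        draws = rng.normal(cp.mean_vector, cp.sd_vector, size=(n, 4))
        feature_map[mask] = np.clip(draws, CLIP_FLOOR, None)
    return label_map, feature_map


def generate_dce_signal(
    ktrans: float,
    ve: float,
    aif: AifSpec,
    times,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Kety-Tofts tissue concentration curve with additive Gaussian noise."""
    clean = kety_tofts_forward(ktrans, ve, aif, times)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, noise_sd, size=clean.shape)


def generate_dw_signal(
    adc: float,
    s0: float,
    bvalues,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Monoexponential diffusion-weighted signal S0 exp(-b ADC) plus noise."""
    bvalues = np.asarray(bvalues, dtype=float)
    if adc < 0 or s0 <= 0:
        raise ValueError("need adc >= 0 and s0 > 0")
    if np.unique(bvalues).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    clean = s0 * np.exp(-bvalues * adc)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, noise_sd, size=clean.shape)


# ---------------------------------------------------------------------------
# cohort synthesis from the ODE family
# ---------------------------------------------------------------------------

#: Control-cohort parameter distribution centers (day^-1 except theta, mm^3).
#: k1 matches the in-vivo average HV-HC growth rate reported for the
#: most parsimonious model; the back/direct transition rates d21, d13 sit one
#: to two orders of magnitude below the forward rates, as observed.
_CONTROL_LOCATIONS: Mapping[str, float] = {
    "k1": 1.99, "k2": 0.6, "d12": 0.35, "d21": 0.03, "d13": 0.02,
    "d23": 0.25, "theta": 300.0,
}
#: Relative spread (CV) of each parameter across subjects.
_PARAM_CV = 0.25


@dataclass(frozen=True)
class CohortConfig:
    """Stated world for one synthetic cohort.

    Defaults mirror the study design: 8 subjects per arm, 7 visits spaced
    1.5 days (5-7 visits every 1-2 days in the study), 5% multiplicative
    observation noise on habitat volumes.  Initial (day 0 = first imaging
    visit) habitat volumes are lognormal around ``init_volume_location``.
    """

    n_subjects: int = 8
    visits_per_subject: int = 7
    visit_spacing_days: float = 1.5
    noise_cv: float = 0.05
    param_location: Mapping[str, float] = field(
        default_factory=lambda: dict(_CONTROL_LOCATIONS))
    param_spread: Mapping[str, float] = field(
        default_factory=lambda: {n: _PARAM_CV * _CONTROL_LOCATIONS[n]
                                 for n in PARAM_NAMES})
    init_volume_location: tuple[float, float, float] = (30.0, 15.0, 5.0)
    init_volume_cv: float = 0.3
    cohort_tag: str = "control"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.visits_per_subject < 5:
            raise ValueError("study design requires >= 5 visits per subject")
        if not 1.0 <= self.visit_spacing_days <= 2.0:
            raise ValueError("visit spacing must be 1-2 days")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.cohort_tag not in ("control", "treated"):
            raise ValueError("cohort_tag must be 'control' or 'treated'")


#: Scale applied to growth-rate locations for the treated arm (radiation
#: slows proliferation; treatment enters only through parameter differences).
TREATED_GROWTH_SCALE = 0.5


def default_cohort_config(cohort_tag: str = "control", **overrides) -> CohortConfig:
    """Stated-world cohort config for an arm, with optional field overrides.

    Explicit ``param_location``/``param_spread`` overrides are taken as-is
    (no treated-arm growth scaling is applied on top of them).
    """
    loc = overrides.pop("param_location", None)
    if loc is None:
        loc = dict(_CONTROL_LOCATIONS)
        if cohort_tag == "treated":
            loc["k1"] *= TREATED_GROWTH_SCALE
            loc["k2"] *= TREATED_GROWTH_SCALE
    spread = overrides.pop(
        "param_spread", {n: _PARAM_CV * loc[n] for n in PARAM_NAMES})
    return CohortConfig(
        cohort_tag=cohort_tag, param_location=loc, param_spread=spread,
        **overrides,
    )


_MAX_REDRAWS = 10_000


def _draw_params(
    config: CohortConfig,
    variant: ModelVariant,
    rng: np.random.Generator,
) -> ModelParams:
    values = {}
    for name in PARAM_NAMES:
        if name in variant.fixed_zero:
            values[name] = 0.0
            continue
        lo, hi = PARAM_BOUNDS[name]
        loc = config.param_location[name]
        spread = config.param_spread[name]
        for attempt in range(_MAX_REDRAWS):
            draw = rng.normal(loc, spread)
            if lo <= draw <= hi and (name != "theta" or draw > 0):
                values[name] = draw
                break
        else:
            raise RuntimeError(
                f"could not draw {name} within bounds [{lo}, {hi}] after "
                f"{_MAX_REDRAWS} attempts (location {loc}, spread {spread})"
            )
    return ModelParams(**values)


def generate_cohort(
    config: CohortConfig,
    variant: ModelVariant = VARIANTS["D"],
) -> list[HabitatSeries]:
    """Forward-simulated habitat-volume series for one cohort.

    Per subject: model parameters are drawn from the config's normal
    distributions (bounded rejection inside the fitting box), initial habitat
    volumes lognormally at day 0, the trajectory integrated at the visit
    days, and multiplicative observation noise (1 + N(0, noise_cv)) applied
    per habitat per visit, floored at zero.  Ground truth is attached to each
    series for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    days = np.arange(config.visits_per_subject) * config.visit_spacing_days
    series = []
    mu = np.log(np.asarray(config.init_volume_location))
    sigma = np.sqrt(np.log(1.0 + config.init_volume_cv ** 2))
    for i in range(config.n_subjects):
        params = _draw_params(config, variant, rng)
        initial = np.exp(rng.normal(mu - sigma**2 / 2, sigma, size=3))
        traj = simulate(variant, params, initial, days)
        noisy = traj * (1.0 + rng.normal(0.0, config.noise_cv, size=traj.shape))
        noisy = np.clip(noisy, 0.0, None)
        series.append(HabitatSeries(
            subject_id=f"{config.cohort_tag}_{i + 1:02d}",
            cohort=config.cohort_tag,
            days=days.copy(),
            volumes=noisy,
            true_params=params,
            true_variant=variant.name,
        ))
    return series
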