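"""Formats, configuration, and the umbrella end-to-end workflow.

The package is used from Python; these functions are the workflow surface.
``run_pipeline`` chains the stages — synthesize a cohort, build and cluster a
phantom feature matrix, extract habitat series, calibrate all model variants,
select the most parsimonious one, forecast held-out subjects, and compare
prediction methods — writing per-stage artifacts plus a machine-readable
summary under a run directory.

On-disk formats: habitat series as CSV with unit-suffixed columns, voxelwise
maps as NIfTI, results as JSON, configuration as YAML.  Readers validate and
reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import calibrate as _calibrate
from . import habitats as _habitats
from . import predict as _predict
from . import synthdata as _synthdata
from .models import VARIANTS

__all__ = [
    "SERIES_COLUMNS",
    "PipelineConfig",
    "read_series",
    "write_series",
    "save_label_map",
    "load_label_map",
    "run_pipeline",
]

logger = logging.getLogger("habitatdyn")

SERIES_COLUMNS = (
    "subject_id", "cohort", "day",
    "vol_HVHC_mm3", "vol_LVHC_mm3", "vol_LVLC_mm3",
)
_VOLUME_COLUMNS = SERIES_COLUMNS[3:]


def write_series(series: Sequence[_habitats.HabitatSeries], path) -> None:
    """Write habitat series to CSV with the canonical schema."""
    rows = []
    for s in series:
        for day, vols in zip(s.days, s.volumes):
            rows.append((s.subject_id, s.cohort, day, *vols))
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def read_series(path) -> list[_habitats.HabitatSeries]:
    """Read and validate habitat series from CSV.

    Days are shifted so each subject's first visit is day 0 (recorded on the
    series flags when a shift was applied).  Negative volumes or missing
    columns are schema errors naming the offending row/column; subjects with
    fewer than five visits are retained but flagged with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"series file {path} is missing column(s) {missing}")
    bad = df[list(_VOLUME_COLUMNS)].lt(0).any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 0-based index
        raise ValueError(f"negative volume(s) in {path} at line(s) {lines}")
    if df[list(SERIES_COLUMNS)].isna().any().any():
        lines = (df.index[df[list(SERIES_COLUMNS)].isna().any(axis=1)] + 2).tolist()
        raise ValueError(f"missing value(s) in {path} at line(s) {lines}")
    out = []
    for subject_id, group in df.groupby("subject_id", sort=False):
        group = group.sort_values("day")
        cohorts = group["cohort"].unique()
        if cohorts.size != 1:
            raise ValueError(f"subject {subject_id} spans cohorts {cohorts.tolist()}")
        days = group["day"].to_numpy(dtype=float)
        shift = days[0]
        s = _habitats.HabitatSeries(
            subject_id=str(subject_id),
            cohort=str(cohorts[0]),
            days=days - shift,
            volumes=group[list(_VOLUME_COLUMNS)].to_numpy(dtype=float),
        )
        if shift != 0:
            s.flags.append(f"days shifted by -{shift}")
        if s.n_visits < 5:
            warnings.warn(
                f"subject {subject_id} has only {s.n_visits} visits (< 5)",
                stacklevel=2,
            )
        out.append(s)
    return out


def save_label_map(label_map: np.ndarray, path, voxel_size_mm: float = 0.5) -> None:
    """Write a 3-D label (or parameter) map as NIfTI with isotropic voxels."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(label_map), affine), str(path))


def load_label_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


@dataclass
class PipelineConfig:
    """Stage toggles, seeds and stage-level settings for a full run.

    Every source of randomness is seeded explicitly from ``seed``; there is
    no wall-clock seeding anywhere, so reruns are byte-identical.
    """

    out_dir: str = "runs/run"
    seed: int = 0
    n_subjects: int = 8
    visits_per_subject: int = 7
    visit_spacing_days: float = 1.5
    noise_cv: float = 0.05
    n_starts: int = 50
    n_b: int = 200
    n_update_visits: int = 2
    clustering_method: str = "kmeans"
    phantom_grid: tuple[int, int, int] = (30, 30, 30)
    run_phantom: bool = True
    run_calibration: bool = True
    run_prediction: bool = True
    true_variant: str = "D"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "phantom_grid" in raw:
            raw["phantom_grid"] = tuple(raw["phantom_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["phantom_grid"] = list(data["phantom_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages and return the run directory.

    Stage order: synthesize -> (phantom cluster + contiguity) -> calibrate all
    variants -> select -> predict (LOO schemes, bootstrap, bootstrap with
    updating) -> compare.  A stage failure halts the run with the stage name;
    artifacts from completed stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed, "stages": []}
    root = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ("cohort", "phantom", "cluster", "calibrate", "predict"),
                 root.spawn(5))}
    summary["stage_seeds"] = seeds
    stage = "synthesize"
    try:
        cohort_cfg = _synthdata.default_cohort_config(
            "control",
            n_subjects=config.n_subjects,
            visits_per_subject=config.visits_per_subject,
            visit_spacing_days=config.visit_spacing_days,
            noise_cv=config.noise_cv,
            seed=seeds["cohort"],
        )
        variant = VARIANTS[config.true_variant]
        series = _synthdata.generate_cohort(cohort_cfg, variant)
        write_series(series, out / "habitat_series.csv")
        summary["stages"].append(stage)
        summary["n_subjects"] = len(series)

        if config.run_phantom:
            stage = "phantom"
            geometry = _synthdata.PhantomGeometry(
                grid_shape=config.phantom_grid,
                core_radius=0.2 * min(config.phantom_grid),
                band_radius=0.33 * min(config.phantom_grid),
                rim_radius=0.45 * min(config.phantom_grid),
            )
            label_map, feature_map = _synthdata.generate_phantom(
                geometry, seed=seeds["phantom"])
            save_label_map(label_map.astype(np.int16), out / "phantom_labels.nii.gz")
            mask = label_map > 0
            matrix = pd.DataFrame(feature_map[mask],
                                  columns=list(_habitats.FEATURE_COLUMNS))
            std, _stats = _habitats.zscore_columns(matrix)
            clusters, _ = _habitats.cluster_voxels(
                std, method=config.clustering_method, seed=seeds["cluster"])
            mapping = _habitats.label_clusters(matrix, clusters)
            contiguity = _habitats.msi_permutation_test(
                label_map, n_permutations=200, seed=seeds["cluster"])
            summary["phantom"] = {
                "cluster_to_habitat": {str(k): v for k, v in mapping.items()},
                "contiguity_score": contiguity["score"],
                "contiguity_null_95th": contiguity["null_95th"],
            }
            summary["stages"].append(stage)

        selected = None
        calibrations: dict[str, list] = {}
        if config.run_calibration:
            stage = "calibrate"
            cal_seed = np.random.SeedSequence(seeds["calibrate"])
            per_subject = []
            for s, ss in zip(series, cal_seed.spawn(len(series))):
                results = _calibrate.fit_all_variants(
                    s, n_starts=config.n_starts, seed=ss)
                best = _calibrate.select_model(results)
                per_subject.append({
                    "subject_id": s.subject_id,
                    "aicc": {r.variant.name: r.aicc for r in results},
                    "selected": best.variant.name,
                    "result": best.to_dict(),
                })
                calibrations[s.subject_id] = results
            with open(out / "calibration.json", "w") as fh:
                json.dump(per_subject, fh, indent=2, default=_json_default)
            names = [p["selected"] for p in per_subject]
            selected = max(set(names), key=names.count)
            summary["selected_variant"] = selected
            summary["selection_counts"] = {v: names.count(v) for v in set(names)}
            summary["stages"].append(stage)

        if config.run_prediction and selected is not None:
            stage = "predict"
            sel_variant = VARIANTS[selected]
            best_by_subject = {
                sid: next(r for r in res if r.variant.name == selected)
                for sid, res in calibrations.items()
            }
            methods: dict[str, list] = {
                f"LOO-{sch}": [] for sch in _predict.LOO_SCHEMES}
            methods["bootstrap"] = []
            methods[f"bootstrap-update-{config.n_update_visits}v"] = []
            pred_seed = np.random.SeedSequence(seeds["predict"])
            for s, ss in zip(series, pred_seed.spawn(len(series))):
                rest = [(best_by_subject[o.subject_id], o)
                        for o in series if o.subject_id != s.subject_id]
                for sch in _predict.LOO_SCHEMES:
                    methods[f"LOO-{sch}"].append(
                        _predict.loo_predict(sch, s, rest))
                bs_seed, up_seed = (int(x.generate_state(1)[0] % (2**31))
                                    for x in ss.spawn(2))
                boot = _predict.bootstrap_predict(
                    [r for r, _ in rest], s.volumes[0], s.days,
                    _predict.BootstrapConfig(n_b=config.n_b, seed=bs_seed),
                    heldout=s,
                )
                methods["bootstrap"].append(boot)
                methods[f"bootstrap-update-{config.n_update_visits}v"].append(
                    _predict.update_with_data(
                        boot, s, config.n_update_visits, seed=up_seed))
            report = _predict.compare_predictions(methods)
            report.to_csv(out / "prediction_comparison.csv", index=False)
            summary["prediction_median_sse"] = {
                m: np.median(np.vstack([r.sse_per_habitat for r in rs]), axis=0).tolist()
                for m, rs in methods.items()
            }
            summary["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    logger.info("pipeline run complete: %s", out)
    return out
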