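"""Habitat identification from pooled voxel features and series extraction.

Voxels from all subjects and visits are pooled into one feature matrix with
columns (ktrans, ve, kep, adc), z-scored per column so each MRI parameter
weighs equally, and partitioned into three clusters (k-means by default,
Ward-linkage agglomerative as the alternative).  Clusters are mapped to the
physiological habitat names by their parameter means: the cluster with the
highest mean K^trans is the high-vascularity high-cellularity (HV-HC) rim;
of the remaining two, the one with the highest mean v_e is the
low-vascularity low-cellularity (LV-LC) core, and the last is the LV-HC band.

Spatial contiguity of a 3-D label map is quantified with a multiregional
spatial interaction (MSI) matrix: counts of 6-connected voxel pairs by label
pair, symmetrized and row-normalized; the contiguity score is the mean
diagonal mass, referenced against a label-permutation null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

__all__ = [
    "FEATURE_COLUMNS",
    "HABITAT_NAMES",
    "HabitatSeries",
    "zscore_columns",
    "inverse_zscore",
    "cluster_voxels",
    "label_clusters",
    "extract_series",
    "msi_matrix",
    "msi_permutation_test",
    "compare_habitat_distributions",
]

#: Fixed feature-column order of the conglomerate matrix.
FEATURE_COLUMNS = ("ktrans", "ve", "kep", "adc")

#: Habitat names in compartment order (C1, C2, C3).
HABITAT_NAMES = ("HV-HC", "LV-HC", "LV-LC")


@dataclass
class HabitatSeries:
    """Per-subject habitat-volume time series, the calibration target.

    ``days`` are shifted so the first visit is day 0.  ``volumes`` has one row
    per visit and columns (HV-HC, LV-HC, LV-LC) in mm^3.
    """

    subject_id: str
    cohort: str
    days: np.ndarray
    volumes: np.ndarray
    true_params: object = None  # ground truth attached by the synthesizer
    true_variant: str | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.ndim != 1 or self.volumes.shape != (self.days.size, 3):
            raise ValueError(
                f"volumes must be (n_visits, 3) matching days; got days "
                f"{self.days.shape}, volumes {self.volumes.shape}"
            )
        if self.days.size < 1:
            raise ValueError("a series needs at least 1 visit")
        if self.days[0] != 0:
            raise ValueError(f"days must be shifted so days[0] = 0, got {self.days[0]}")
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")
        if self.days.size < 5 and "few_visits" not in self.flags:
            self.flags.append("few_visits")

    @property
    def n_visits(self) -> int:
        return self.days.size

    @property
    def total_volumes(self) -> np.ndarray:
        return self.volumes.sum(axis=1)

    def truncate(self, n_visits: int) -> "HabitatSeries":
        """First ``n_visits`` visits only (for data-updating forecasts)."""
        if not 1 <= n_visits <= self.n_visits:
            raise ValueError(f"n_visits must be in [1, {self.n_visits}]")
        if n_visits == 1:
            raise ValueError("cannot build a series from a single visit")
        return HabitatSeries(
            subject_id=self.subject_id,
            cohort=self.cohort,
            days=self.days[:n_visits].copy(),
            volumes=self.volumes[:n_visits].copy(),
            true_params=self.true_params,
            true_variant=self.true_variant,
        )


# ---------------------------------------------------------------------------
# feature-matrix standardization and clustering
# ---------------------------------------------------------------------------

def zscore_columns(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each feature column to zero mean, unit SD.

    Returns the standardized matrix and a stats frame (rows ``mean``/``std``)
    sufficient to invert the transform.  Metadata columns (anything outside
    :data:`FEATURE_COLUMNS`) pass through untouched.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns {missing}")
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to standardize")
    feats = matrix[list(FEATURE_COLUMNS)]
    if feats.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    mean = feats.mean(axis=0)
    std = feats.std(axis=0, ddof=0)
    zero_var = std[std == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance feature column(s): {zero_var}")
    out = matrix.copy()
    out[list(FEATURE_COLUMNS)] = (feats - mean) / std
    stats_df = pd.DataFrame([mean, std], index=["mean", "std"])
    return out, stats_df


def inverse_zscore(standardized: pd.DataFrame, stats_df: pd.DataFrame) -> pd.DataFrame:
    """Undo :func:`zscore_columns` using its stored column statistics."""
    out = standardized.copy()
    out[list(FEATURE_COLUMNS)] = (
        standardized[list(FEATURE_COLUMNS)] * stats_df.loc["std"] + stats_df.loc["mean"]
    )
    return out


def cluster_voxels(
    standardized: pd.DataFrame,
    method: str = "kmeans",
    k: int = 3,
    seed: int | None = None,
    n_init: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition standardized voxels into ``k`` clusters.

    k-means is restarted ``n_init`` times keeping the lowest within-cluster
    sum of squares; the agglomerative alternative uses Ward linkage on
    Euclidean distance.  Returns integer cluster indices (one per row) and the
    cluster centers in z-score space.
    """
    X = np.asarray(standardized[list(FEATURE_COLUMNS)], dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} rows, got {len(X)}")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, tol=1e-6, random_state=seed)
        labels = km.fit_predict(X)
        centers = km.cluster_centers_
    elif method == "agglomerative":
        agg = AgglomerativeClustering(n_clusters=k, linkage="ward")
        labels = agg.fit_predict(X)
        centers = np.vstack([X[labels == i].mean(axis=0) for i in range(k)])
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return labels.astype(int), centers


def label_clusters(matrix: pd.DataFrame, cluster_indices: np.ndarray) -> dict[int, str]:
    """Map the three cluster indices to habitat names by physiology.

    Ranking rule on native-unit cluster means: highest mean K^trans -> HV-HC
    (vascular rim); of the other two, highest mean v_e -> LV-LC (necrotic
    core); remainder -> LV-HC.  Near-ties (within 1e-9 relative) are
    ambiguous and raise.
    """
    idx = np.unique(cluster_indices)
    if idx.size != 3:
        raise ValueError(f"expected exactly 3 clusters, got {idx.size}")
    means = {
        i: matrix[list(FEATURE_COLUMNS)].iloc[cluster_indices == i].mean(axis=0)
        for i in idx
    }

    def _argmax(keys, column):
        vals = {i: means[i][column] for i in keys}
        ordered = sorted(vals, key=vals.get, reverse=True)
        top, second = ordered[0], ordered[1]
        scale = max(abs(vals[top]), abs(vals[second]), 1e-30)
        if abs(vals[top] - vals[second]) <= 1e-9 * scale:
            raise ValueError(
                f"ambiguous habitat labelling: cluster means of {column} tie"
            )
        return top

    hv = _argmax(list(idx), "ktrans")
    rest = [i for i in idx if i != hv]
    lvlc = _argmax(rest, "ve")
    lvhc = next(i for i in rest if i != lvlc)
    return {hv: "HV-HC", lvhc: "LV-HC", lvlc: "LV-LC"}


# ---------------------------------------------------------------------------
# series extraction
# ---------------------------------------------------------------------------

def extract_series(
    label_maps: Sequence[np.ndarray],
    visit_days: Sequence[float],
    voxel_volume: float,
    subject_id: str = "subject",
    cohort: str = "control",
) -> HabitatSeries:
    """Habitat volumes per visit from labelled voxel maps.

    ``label_maps`` hold habitat codes 1, 2, 3 for (HV-HC, LV-HC, LV-LC) and 0
    for background; volume = labelled-voxel count x ``voxel_volume`` (mm^3).
    Days are shifted so the first visit is day 0.  Empty habitats yield a
    volume of 0 and are retained.
    """
    if len(label_maps) != len(visit_days):
        raise ValueError("one visit day per label map is required")
    if any(d is None for d in visit_days):
        raise ValueError("every visit needs a known day")
    days = np.asarray(visit_days, dtype=float)
    vols = np.array(
        [[(np.asarray(m) == h).sum() * voxel_volume for h in (1, 2, 3)] for m in label_maps],
        dtype=float,
    )
    return HabitatSeries(subject_id, cohort, days - days[0], vols)


# ---------------------------------------------------------------------------
# spatial contiguity (MSI)
# ---------------------------------------------------------------------------

def msi_matrix(label_map: np.ndarray) -> tuple[np.ndarray, float]:
    """Multiregional spatial interaction matrix and contiguity score.

    Counts 6-connected voxel pairs by (label, label) over habitat codes
    1..3 (background 0 excluded), symmetrizes, row-normalizes, and scores
    contiguity as the mean diagonal mass over habitats present in the map.
    """
    lab = np.asarray(label_map)
    if lab.ndim != 3:
        raise ValueError("label map must be 3-D")
    if (lab > 0).sum() < 2:
        raise ValueError("need at least two labelled voxels")
    counts = np.zeros((3, 3), dtype=float)
    for axis in range(3):
        a = np.moveaxis(lab, axis, 0)
        u, v = a[:-1].ravel(), a[1:].ravel()
        keep = (u > 0) & (v > 0)
        np.add.at(counts, (u[keep] - 1, v[keep] - 1), 1.0)
    counts = counts + counts.T
    row_sums = counts.sum(axis=1, keepdims=True)
    present = row_sums[:, 0] > 0
    norm = np.zeros_like(counts)
    norm[present] = counts[present] / row_sums[present]
    score = float(np.diag(norm)[present].mean())
    return norm, score


def msi_permutation_test(
    label_map: np.ndarray,
    n_permutations: int = 200,
    seed: int | None = None,
) -> dict:
    """Permutation null for the contiguity score.

    Habitat labels are shuffled among labelled voxels, keeping the tumor mask
    fixed, and the score recomputed ``n_permutations`` times.
    """
    rng = np.random.default_rng(seed)
    lab = np.asarray(label_map).copy()
    mask = lab > 0
    _, observed = msi_matrix(lab)
    values = lab[mask]
    null = np.empty(n_permutations)
    shuffled = lab.copy()
    for i in range(n_permutations):
        shuffled[mask] = rng.permutation(values)
        _, null[i] = msi_matrix(shuffled)
    exceed = float(np.mean(null >= observed))
    return {
        "score": observed,
        "null": null,
        "null_95th": float(np.percentile(null, 95)),
        "p_value": (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations),
        "exceeds_null_95th": observed > np.percentile(null, 95),
        "fraction_null_ge": exceed,
    }


# ---------------------------------------------------------------------------
# habitat distribution statistics
# ---------------------------------------------------------------------------

def compare_habitat_distributions(
    matrix: pd.DataFrame,
    habitat_labels: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sample KS tests and one-way ANOVA per MRI parameter.

    Returns a tidy frame with one row per (parameter, test) and a
    significance flag at level ``alpha``.  Habitats with fewer than two
    voxels are skipped with a flag row.
    """
    habitat_labels = np.asarray(habitat_labels)
    rows = []
    groups = {h: matrix[list(FEATURE_COLUMNS)][habitat_labels == h] for h in HABITAT_NAMES}
    usable = [h for h in HABITAT_NAMES if len(groups[h]) >= 2]
    skipped = [h for h in HABITAT_NAMES if h not in usable]
    for col in FEATURE_COLUMNS:
        for h1, h2 in itertools.combinations(usable, 2):
            stat, p = stats.ks_2samp(groups[h1][col], groups[h2][col])
            rows.append({
                "parameter": col, "test": f"KS {h1} vs {h2}",
                "statistic": stat, "p_value": p, "significant": p < alpha,
            })
        if len(usable) >= 2:
            stat, p = stats.f_oneway(*(groups[h][col] for h in usable))
            rows.append({
                "parameter": col, "test": "ANOVA",
                "statistic": stat, "p_value": p, "significant": p < alpha,
            })
        for h in skipped:
            rows.append({
                "parameter": col, "test": f"skipped {h} (<2 voxels)",
                "statistic": np.nan, "p_value": np.nan, "significant": False,
            })
    return pd.DataFrame(rows)
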