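"""Discrepancy metrics between automatic localizations and benchmark dipoles.

Four metrics quantify how well an automatic method reproduces a benchmark
equivalent-current-dipole (ECD) analysis:

* DLD — Euclidean distance between the point estimate and the ECD.
* MLD — map-weighted RMS distance of the voxels to the ECD location:
  ``sqrt( sum_j (d_j |S_j|)^2 / sum_j |S_j|^2 )``.
* SD  — the same functional with distances measured to the map's own peak
  voxel; a pure spread measure.
* AUC — area under the ROC obtained by thresholding a patient's averaged
  map into active/inactive voxels and scoring the containment of the
  patient's ECDs (positives are the ECDs, scored by the value of their
  nearest voxel; negatives are the ECD-free voxels).  "Active" means
  strictly above the threshold; thresholds sweep all unique map values
  plus sentinels so the ROC endpoints (0,0) and (1,1) are exact, and the
  area is trapezoidal.

MLD and SD are invariant to positive rescaling of the map; AUC is
invariant under strictly increasing transforms of the map values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .headmodel import SourceSpace

__all__ = [
    "MetricRecord",
    "PatientMetricSummary",
    "dld",
    "grid_discrepancy",
    "mld",
    "spatial_dispersion",
    "auc",
    "summarize_patient",
]


@dataclasses.dataclass(frozen=True)
class MetricRecord:
    """Per-spike metric values for one method."""

    patient_id: str
    ied_id: str
    method: str
    dld: float
    mld: float | None = None  # map methods only
    sd: float | None = None  # map methods only

    def __post_init__(self) -> None:
        for name in ("dld", "mld", "sd"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and nonnegative")


@dataclasses.dataclass(frozen=True)
class PatientMetricSummary:
    """Across-spike mean/std of each metric plus the averaged-map AUC."""

    patient_id: str
    method: str
    dld_mean: float
    dld_std: float
    mld_mean: float | None = None
    mld_std: float | None = None
    sd_mean: float | None = None
    sd_std: float | None = None
    auc: float | None = None


def dld(estimated_location: np.ndarray, ecd_location: np.ndarray) -> float:
    """Euclidean distance (mm) between a point estimate and the ECD."""
    a = np.asarray(estimated_location, dtype=float)
    b = np.asarray(ecd_location, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("locations must be finite")
    return float(np.linalg.norm(a - b))


def grid_discrepancy(
    ecd_locations: np.ndarray, space: SourceSpace
) -> tuple[np.ndarray, float]:
    """Distance of each ECD to its nearest grid point, plus the median.

    Quantifies the systematic error a discretised source space imposes on
    the DLD (continuous ECD locations cannot fall exactly on the grid).
    """
    locs = np.atleast_2d(np.asarray(ecd_locations, dtype=float))
    if locs.size == 0:
        raise ValueError("at least one ECD location is required")
    tree = cKDTree(space.points)
    distances, _ = tree.query(locs)
    return distances, float(np.median(distances))


def _weighted_rms_distance(
    values: np.ndarray, reference: np.ndarray, space: SourceSpace
) -> float:
    s = np.abs(np.asarray(values, dtype=float))
    if s.shape[0] != space.n_points:
        raise ValueError("map length must match the source space")
    total = np.sum(s**2)
    if total == 0:
        raise ValueError("map is identically zero")
    d = np.linalg.norm(space.points - np.asarray(reference, dtype=float), axis=1)
    return float(np.sqrt(np.sum((d * s) ** 2) / total))


def mld(values: np.ndarray, ecd_location: np.ndarray, space: SourceSpace) -> float:
    """Map localization discrepancy (mm) of a cortical map w.r.t. an ECD."""
    return _weighted_rms_distance(values, ecd_location, space)


def spatial_dispersion(values: np.ndarray, space: SourceSpace) -> float:
    """Spread (mm) of a cortical map about its own peak voxel."""
    s = np.abs(np.asarray(values, dtype=float))
    peak = int(np.argmax(s))
    return _weighted_rms_distance(s, space.points[peak], space)


def auc(
    values: np.ndarray,
    ecd_locations: np.ndarray,
    space: SourceSpace,
) -> float:
    """ROC area for the active/inactive voxel classification of a map.

    ``values`` is the patient's across-spike averaged map; positives are
    the patient's ECDs (each scored by its nearest voxel's map value),
    negatives are the voxels containing no ECD.
    """
    s = np.asarray(values, dtype=float)
    if s.shape[0] != space.n_points:
        raise ValueError("map length must match the source space")
    locs = np.atleast_2d(np.asarray(ecd_locations, dtype=float))
    if locs.size == 0:
        raise ValueError("at least one ECD location is required")
    tree = cKDTree(space.points)
    _, nearest = tree.query(locs)
    nearest = np.atleast_1d(nearest)
    pos_scores = s[nearest]  # one entry per ECD
    ecd_voxels = np.unique(nearest)
    neg_mask = np.ones(space.n_points, dtype=bool)
    neg_mask[ecd_voxels] = False
    neg_scores = s[neg_mask]
    n_pos = pos_scores.size
    n_neg = neg_scores.size
    if n_neg == 0:
        raise ValueError("every voxel contains an ECD; ROC undefined")

    thresholds = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        tpr[i] = np.count_nonzero(pos_scores > t) / n_pos
        fpr[i] = np.count_nonzero(neg_scores > t) / n_neg
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def summarize_patient(
    records: list[MetricRecord],
    averaged_map: np.ndarray | None,
    ecd_locations: np.ndarray | None,
    space: SourceSpace | None,
) -> PatientMetricSummary:
    """Across-spike mean and sample std (ddof=1) of each metric.

    The AUC is computed from the averaged map against the full ECD set;
    pass ``averaged_map=None`` for point-estimate-only methods.
    """
    if not records:
        raise ValueError("at least one metric record is required")
    pid = records[0].patient_id
    method = records[0].method

    def mean_std(vals: list[float | None]) -> tuple[float | None, float | None]:
        clean = [v for v in vals if v is not None]
        if not clean:
            return None, None
        arr = np.asarray(clean, dtype=float)
        std = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), std

    dld_mean, dld_std = mean_std([r.dld for r in records])
    mld_mean, mld_std = mean_std([r.mld for r in records])
    sd_mean, sd_std = mean_std([r.sd for r in records])
    auc_value = None
    if averaged_map is not None:
        if ecd_locations is None or space is None:
            raise ValueError("AUC needs ECD locations and the source space")
        auc_value = auc(averaged_map, ecd_locations, space)
    return PatientMetricSummary(
        patient_id=pid,
        method=method,
        dld_mean=dld_mean,
        dld_std=dld_std,
        mld_mean=mld_mean,
        mld_std=mld_std,
        sd_mean=sd_mean,
        sd_std=sd_std,
        auc=auc_value,
    )
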