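"""Lobar concordance with the surgical plan and outcome prediction.

The chain implemented here turns per-method localization results into a
binary classifier of post-surgical seizure freedom:

1. each method's result is summarised as a percentage per lobar region
   (fraction of dipoles for point-estimate methods; share of map mass for
   map methods);
2. a patient is *concordant* when a region attaining the maximal
   percentage belongs to the set of lobes treated by resection or
   thermocoagulation (ties count as concordant if any tied region is in
   the plan — the reading consistent with the published classification);
3. outcomes are dichotomised: Engel class I is *good*, classes II-IV
   (including an ambiguous II/III) are *poor*;
4. concordance x outcome gives TP/FP/TN/FN over operated patients, from
   which TPR, TNR, PPV, NPV and F1 are derived.

Percentages not greater than 10% are suppressed from *display* only; the
argmax in step 2 always uses the unfiltered percentages.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree

from .atlas import REGIONS, AtlasLabels
from .headmodel import SourceSpace

__all__ = [
    "LobarRow",
    "LobarTable",
    "ConfusionCounts",
    "PredictionStats",
    "lobar_percentages",
    "classify_patient",
    "confusion_matrix",
    "prediction_stats",
    "engel_is_good",
    "DISPLAY_THRESHOLD",
]

DISPLAY_THRESHOLD = 10.0  # percent; entries <= this are hidden from display

LobarRow = list[tuple[str, float]]  # (region, percent)

_GOOD_CLASSES = {"1", "I"}
_POOR_CLASSES = {"2", "3", "4", "II", "III", "IV", "2/3", "II/III"}


def engel_is_good(engel: str) -> bool:
    """Dichotomise an Engel class: I is good, II-IV (incl. II/III) poor."""
    e = str(engel).strip()
    if e in _GOOD_CLASSES:
        return True
    if e in _POOR_CLASSES:
        return False
    raise ValueError(f"unrecognised Engel class {engel!r}")


@dataclasses.dataclass
class LobarTable:
    """Per (patient, method) lobar percentage lists."""

    rows: dict[tuple[str, str], LobarRow] = dataclasses.field(default_factory=dict)

    def add(self, patient: str, method: str, row: LobarRow) -> None:
        total = sum(p for _, p in row)
        if abs(total - 100.0) > 0.5:
            raise ValueError(
                f"percentages for ({patient}, {method}) sum to {total}, not 100"
            )
        self.rows[(patient, method)] = sorted(row, key=lambda rp: -rp[1])

    def filtered(self, patient: str, method: str) -> LobarRow:
        """Display view: only percentages strictly above 10%."""
        return [
            (r, p)
            for r, p in self.rows[(patient, method)]
            if p > DISPLAY_THRESHOLD
        ]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class PredictionStats:
    """Sensitivity/specificity-style summary of the outcome classifier.

    Fields with a zero denominator are NaN and listed in ``undefined``.
    """

    tpr: float
    tnr: float
    ppv: float
    npv: float
    f1: float
    undefined: frozenset[str] = frozenset()


def lobar_percentages(
    result,
    labels: AtlasLabels,
    space: SourceSpace,
) -> LobarRow:
    """Region percentages of a localization result.

    ``result`` is either an (n, 3) array of dipole locations (each counted
    in the region of its nearest source point) or a per-point map whose
    absolute mass is apportioned to regions.  Regions at zero stay absent.
    """
    arr = np.asarray(result, dtype=float)
    label_arr = labels.as_array()
    if arr.ndim == 2 and arr.shape[1] == 3:
        if arr.shape[0] == 0:
            raise ValueError("no dipole locations given")
        tree = cKDTree(space.points)
        _, nearest = tree.query(arr)
        point_labels = label_arr[np.atleast_1d(nearest)]
        row = [
            (region, 100.0 * np.count_nonzero(point_labels == region) / arr.shape[0])
            for region in REGIONS
        ]
    elif arr.ndim == 1:
        if arr.shape[0] != space.n_points:
            raise ValueError("map length must match the source space")
        mass = np.abs(arr)
        total = mass.sum()
        if total == 0:
            raise ValueError("map is identically zero")
        row = [
            (region, 100.0 * mass[label_arr == region].sum() / total)
            for region in REGIONS
        ]
    else:
        raise ValueError("result must be dipole locations (n, 3) or a map vector")
    return [(r, p) for r, p in row if p > 0]


def classify_patient(
    row: LobarRow,
    plan_lobes: frozenset[str] | set[str],
    engel: str | None,
    operated: bool = True,
) -> str | None:
    """Classify one patient as TP/FP/TN/FN, or None if not operated.

    Concordance: any region attaining the maximal (unfiltered) percentage
    lies in the surgical plan.
    """
    if not operated:
        return None
    if not row:
        raise ValueError("empty lobar row for an operated patient")
    if engel is None:
        raise ValueError("operated patients must carry an Engel class")
    top = max(p for _, p in row)
    top_regions = {r for r, p in row if p >= top - 1e-9}
    concordant = bool(top_regions & set(plan_lobes))
    good = engel_is_good(engel)
    if concordant:
        return "TP" if good else "FP"
    return "FN" if good else "TN"


def confusion_matrix(
    lobar_rows: dict[str, LobarRow],
    patients: dict[str, tuple[frozenset[str], str | None, bool]],
) -> ConfusionCounts:
    """Accumulate the outcome-prediction confusion matrix for one method.

    ``patients`` maps patient id to (plan_lobes, engel, operated);
    non-operated patients are excluded.  Patient order is irrelevant.
    """
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    n_operated = 0
    for pid, (plan, engel, operated) in patients.items():
        if not operated:
            continue
        n_operated += 1
        cell = classify_patient(lobar_rows[pid], plan, engel, operated=True)
        counts[cell] += 1
    if n_operated == 0:
        raise ValueError("at least one operated patient is required")
    return ConfusionCounts(
        tp=counts["TP"], fp=counts["FP"], tn=counts["TN"], fn=counts["FN"]
    )


def prediction_stats(c: ConfusionCounts) -> PredictionStats:
    """TPR, TNR, PPV, NPV and F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    tpr = ratio(c.tp, c.tp + c.fn, "tpr")
    tnr = ratio(c.tn, c.tn + c.fp, "tnr")
    ppv = ratio(c.tp, c.tp + c.fp, "ppv")
    npv = ratio(c.tn, c.tn + c.fn, "npv")
    if math.isnan(tpr) or math.isnan(ppv) or (ppv + tpr) == 0:
        undefined.add("f1")
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * tpr / (ppv + tpr)
    return PredictionStats(
        tpr=tpr, tnr=tnr, ppv=ppv, npv=npv, f1=f1, undefined=frozenset(undefined)
    )
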