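"""Packaged clinical reference tables.

Three delimited-text tables transcribe the published per-patient results
of the 22-patient benchmark cohort this package reproduces:

* ``table1.csv`` — surgical plan lobes, Engel outcome class and operated
  flag per patient (two patients, P9 and P10, were not operated; P16
  underwent thermocoagulation only and carries the treated lobe from its
  stereo-EEG target; P7's Engel class is recorded verbatim as ``2/3``).
* ``table2.csv`` — per-patient averages (and stds) of the four
  localization metrics (DLD, MLD, SD, AUC) per method.
* ``table3.csv`` — per-patient lobar percentages per method, filtered to
  entries strictly above 10%.

Methods are named ``ecd``, ``sesame`` (Bayesian dipole mapping),
``rap_music`` and ``wmne``.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

from .atlas import REGIONS

__all__ = [
    "FixtureIntegrityError",
    "CohortFixtures",
    "load_paper_tables",
    "PATIENT_IDS",
    "METHODS",
    "MAP_METHODS",
]

PATIENT_IDS = tuple(f"P{i}" for i in range(1, 23))
METHODS = ("ecd", "sesame", "rap_music", "wmne")
#: methods producing a cortical map (MLD/SD/AUC are defined for these)
MAP_METHODS = ("sesame", "wmne")
_NON_OPERATED = frozenset({"P9", "P10"})


class FixtureIntegrityError(ValueError):
    """Raised when a packaged table fails its consistency checks."""


@dataclasses.dataclass(frozen=True)
class CohortFixtures:
    """Validated in-memory view of the packaged clinical tables."""

    table1: pd.DataFrame  # index: patient id
    table2: pd.DataFrame  # columns id, method, metric, mean, std
    table3: pd.DataFrame  # columns id, method, region, percent

    def plan_lobes(self, patient: str) -> frozenset[str]:
        raw = self.table1.loc[patient, "plan_lobes"]
        if not isinstance(raw, str) or not raw:
            return frozenset()
        return frozenset(part.strip() for part in raw.split(";"))

    def engel(self, patient: str) -> str | None:
        val = self.table1.loc[patient, "engel"]
        return val if isinstance(val, str) and val else None

    def operated(self, patient: str) -> bool:
        return bool(self.table1.loc[patient, "operated"])

    def metric_series(self, method: str, metric: str) -> pd.Series:
        """Per-patient averages of one metric, in patient order."""
        sel = self.table2[
            (self.table2["method"] == method) & (self.table2["metric"] == metric)
        ]
        series = sel.set_index("id")["mean"].reindex(PATIENT_IDS)
        if series.isna().any():
            raise KeyError(f"no {metric!r} entries for method {method!r}")
        return series

    def lobar_rows(self, method: str) -> dict[str, list[tuple[str, float]]]:
        """Per-patient (region, percent) lists for one method."""
        out: dict[str, list[tuple[str, float]]] = {}
        sel = self.table3[self.table3["method"] == method]
        for pid in PATIENT_IDS:
            rows = sel[sel["id"] == pid]
            out[pid] = list(zip(rows["region"], rows["percent"].astype(float)))
        return out


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("izbench").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"id": str}, keep_default_na=False)


def _validate(t1: pd.DataFrame, t2: pd.DataFrame, t3: pd.DataFrame) -> None:
    if tuple(t1.index) != PATIENT_IDS:
        raise FixtureIntegrityError("table1 must list exactly patients P1..P22")
    non_op = frozenset(t1.index[t1["operated"] == 0])
    if non_op != _NON_OPERATED:
        raise FixtureIntegrityError(f"non-operated patients must be {set(_NON_OPERATED)}")
    for pid, row in t1.iterrows():
        if row["operated"]:
            if not row["plan_lobes"] or not row["engel"]:
                raise FixtureIntegrityError(f"{pid}: operated without plan or Engel class")
            lobes = {s.strip() for s in row["plan_lobes"].split(";")}
            if not lobes <= set(REGIONS):
                raise FixtureIntegrityError(f"{pid}: unknown plan lobes {lobes}")
            if row["engel"] not in {"1", "2", "3", "4", "2/3"}:
                raise FixtureIntegrityError(f"{pid}: unexpected Engel class {row['engel']!r}")
    if t1.loc["P7", "engel"] != "2/3":
        raise FixtureIntegrityError("P7 Engel class must be preserved verbatim as 2/3")

    expected_t2 = {
        ("ecd",): set(),
        ("sesame",): {"dld", "mld", "sd", "auc"},
        ("rap_music",): {"dld"},
        ("wmne",): {"dld", "mld", "sd", "auc"},
    }
    for (method,), metrics in expected_t2.items():
        have = set(t2.loc[t2["method"] == method, "metric"])
        if have != metrics:
            raise FixtureIntegrityError(f"table2 metrics for {method}: {have} != {metrics}")
    means = pd.to_numeric(t2["mean"], errors="coerce")
    if means.isna().any() or (means < 0).any():
        raise FixtureIntegrityError("table2 means must be nonnegative numbers")
    aucs = t2[t2["metric"] == "auc"]["mean"].astype(float)
    if ((aucs < 0) | (aucs > 1)).any():
        raise FixtureIntegrityError("AUC values must lie in [0, 1]")

    if set(t3["method"]) != set(METHODS):
        raise FixtureIntegrityError("table3 must cover all four methods")
    pct = t3["percent"].astype(float)
    if ((pct <= 10) | (pct > 100)).any():
        raise FixtureIntegrityError("table3 percentages must lie in (10, 100]")
    if not set(t3["region"]) <= set(REGIONS):
        raise FixtureIntegrityError("table3 contains unknown region labels")
    counts = t3.groupby(["id", "method"]).size()
    if set(counts.index.get_level_values("id")) != set(PATIENT_IDS):
        raise FixtureIntegrityError("table3 must cover all 22 patients")


def load_paper_tables() -> CohortFixtures:
    """Load and validate the packaged clinical tables."""
    t1 = _read_packaged("table1.csv").set_index("id")
    t2 = _read_packaged("table2.csv")
    t2["mean"] = pd.to_numeric(t2["mean"])
    t2["std"] = pd.to_numeric(t2["std"].replace("", np.nan))
    t3 = _read_packaged("table3.csv")
    t3["percent"] = pd.to_numeric(t3["percent"])
    _validate(t1, t2, t3)
    return CohortFixtures(table1=t1, table2=t2, table3=t3)
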