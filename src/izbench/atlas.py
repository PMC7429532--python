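"""Geometric 10-region lobar atlas for spherical source spaces.

Clinical outcome scoring in epilepsy surgery is done at the level of five
lobar regions per hemisphere: frontal (F), temporal (T), central (C,
pre/postcentral), parietal (P) and occipital (O).  On the spherical
surrogate head the hemisphere is the sign of the lateral (+x = right)
coordinate and the five regions are contiguous angular sectors of the
sagittal angle

    beta = atan2(z, y)   (y anterior, z superior; degrees in (-180, 180])

with fixed thresholds:

    F: beta in [-30, 55)      anterior
    C: beta in [55, 100)      superior-central
    P: beta in [100, 150)     posterior-superior
    O: beta in [150, 180] or [-180, -150)   posterior-inferior
    T: beta in [-150, -30)    inferior-lateral (largest sector)

Points on the midline (x == 0) are assigned to the left hemisphere;
points on the x axis (y == z == 0) fall in the frontal sector (beta = 0).
Labels are strings like ``"R T"``; assignment is deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .headmodel import SourceSpace

__all__ = ["AtlasLabels", "assign_lobes", "REGIONS", "LOBES", "region_points"]

LOBES = ("F", "T", "C", "P", "O")
#: all ten region labels, left hemisphere first
REGIONS = tuple(f"{h} {l}" for h in ("L", "R") for l in LOBES)

_SECTORS = (  # (lobe, beta_low_deg, beta_high_deg), half-open [low, high)
    ("F", -30.0, 55.0),
    ("C", 55.0, 100.0),
    ("P", 100.0, 150.0),
    ("O", 150.0, 210.0),  # wraps through 180
    ("T", 210.0, 330.0),  # i.e. [-150, -30)
)


@dataclasses.dataclass(frozen=True)
class AtlasLabels:
    """One lobar region label per source point."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


def _lobe_of_beta(beta_deg: np.ndarray) -> np.ndarray:
    """Map sagittal angles (degrees) to lobe letters."""
    b = np.mod(beta_deg + 30.0, 360.0)  # rotate so F starts at 0
    out = np.empty(b.shape, dtype=object)
    edges = [85.0, 130.0, 180.0, 240.0, 360.0]  # cumulative sector widths
    lobes = ["F", "C", "P", "O", "T"]
    prev = 0.0
    for edge, lobe in zip(edges, lobes):
        sel = (b >= prev) & (b < edge)
        out[sel] = lobe
        prev = edge
    out[b >= edges[-1]] = "T"  # numerical guard
    return out


def assign_lobes(space: SourceSpace) -> AtlasLabels:
    """Assign each source point its lobar region label."""
    pts = space.points
    beta = np.degrees(np.arctan2(pts[:, 2], pts[:, 1]))
    lobe = _lobe_of_beta(beta)
    hemi = np.where(pts[:, 0] > 0, "R", "L")
    labels = tuple(f"{h} {l}" for h, l in zip(hemi, lobe))
    return AtlasLabels(labels=labels)


def region_points(space: SourceSpace, labels: AtlasLabels, region: str) -> np.ndarray:
    """Indices of the source points belonging to a region."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    arr = labels.as_array()
    return np.flatnonzero(arr == region)
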