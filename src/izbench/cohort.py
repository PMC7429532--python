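"""Synthetic interictal-spike cohorts with known irritative zones.

Each simulated patient has a true irritative-zone (IZ) region in the lobar
atlas; their interictal discharges (IEDs) are single-time-sample sensor
topographies generated by one dominant dipole drawn near a patient-specific
centre inside that region, with white sensor noise at a configurable
signal-to-noise ratio.  A surgical plan and a dichotomised Engel outcome
are drawn with configurable concordance/outcome probabilities so that the
whole localization -> concordance -> outcome-prediction chain can be
exercised end to end, including as an exact oracle
(``concordant_fraction=1, p_good_concordant=1, p_good_discordant=0``).

Default cohort parameters emulate the study conditions this package
benchmarks: 22 patients, 8-100 spikes each, dipole moments of 50-500 nAm,
and plan/outcome probabilities matching the observed concordance rates
(12/20 concordant; good outcome for 8/12 concordant and 5/8 discordant
patients).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .atlas import REGIONS, AtlasLabels, region_points
from .headmodel import Leadfield

__all__ = [
    "IEDRecord",
    "PatientRecord",
    "CohortConfig",
    "simulate_ied_topography",
    "simulate_cohort",
]


@dataclasses.dataclass(frozen=True)
class IEDRecord:
    """Sensor topography at the peak of one interictal spike."""

    topography: np.ndarray  # (n_channels,)
    true_location: np.ndarray | None = None  # mm, synthetic only
    true_moment: np.ndarray | None = None  # nAm, synthetic only
    snr: float = np.inf  # signal power / noise power
    seed: int | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.topography, dtype=float)
        if y.ndim != 1:
            raise ValueError("topography must be a 1-D channel vector")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        object.__setattr__(self, "topography", y)


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: spikes, ground truth, plan and outcome."""

    id: str
    ied_records: tuple[IEDRecord, ...]
    true_iz_region: str | None
    plan_lobes: frozenset[str]
    engel: str | None  # "1".."4", "2/3" or None
    operated: bool

    def __post_init__(self) -> None:
        if len(self.ied_records) < 1:
            raise ValueError("patients must have at least one IED")
        if self.operated and (not self.plan_lobes or self.engel is None):
            raise ValueError("operated patients need plan lobes and an Engel class")


@dataclasses.dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``depth_band`` restricts dipole centres to a cortical-like radial band
    (fractions of the head radius); purely radial moments are magnetically
    silent in a sphere, so moment directions are drawn tangentially.
    """

    n_patients: int = 22
    ied_count_range: tuple[int, int] = (8, 100)
    snr: float = 5.0
    jitter_mm: float = 10.0
    moment_range_nAm: tuple[float, float] = (50.0, 500.0)
    concordant_fraction: float = 12.0 / 20.0
    p_good_concordant: float = 8.0 / 12.0
    p_good_discordant: float = 5.0 / 8.0
    depth_band: tuple[float, float] = (0.45, 0.92)
    seed: int = 0


def simulate_ied_topography(
    leadfield: Leadfield,
    location: np.ndarray,
    moment: np.ndarray,
    snr: float = np.inf,
    seed: int | None = None,
) -> IEDRecord:
    """Forward-project one dipole and add white sensor noise.

    The dipole location is snapped to the nearest source-space point.  The
    noise standard deviation is chosen so that the ratio of mean-square
    signal to mean-square noise equals ``snr``; ``snr=inf`` returns the
    noise-free forward field.
    """
    moment = np.asarray(moment, dtype=float)
    if np.linalg.norm(moment) == 0:
        raise ValueError("dipole moment must be nonzero")
    loc = np.asarray(location, dtype=float)
    d2 = np.sum((leadfield.source_space.points - loc) ** 2, axis=1)
    j = int(np.argmin(d2))
    snapped = leadfield.source_space.points[j]
    y0 = leadfield.topography(j, moment)
    if np.isinf(snr):
        y = y0
    else:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.mean(y0**2) / snr)
        y = y0 + sigma * rng.standard_normal(y0.shape)
    return IEDRecord(
        topography=y,
        true_location=snapped.copy(),
        true_moment=moment.copy(),
        snr=float(snr),
        seed=seed,
    )


def _tangential_direction(rng: np.random.Generator, location: np.ndarray) -> np.ndarray:
    """Random unit vector orthogonal to the radial direction at ``location``."""
    radial = location / np.linalg.norm(location)
    for _ in range(64):
        v = rng.standard_normal(3)
        v -= (v @ radial) * radial
        norm = np.linalg.norm(v)
        if norm > 0.2:
            return v / norm
    raise RuntimeError("failed to draw a tangential direction")  # pragma: no cover


def simulate_cohort(
    config: CohortConfig,
    leadfield: Leadfield,
    labels: AtlasLabels,
    seed: int | None = None,
) -> list[PatientRecord]:
    """Draw a fully seeded synthetic patient cohort.

    All randomness derives from a single root seed (``seed`` argument, or
    ``config.seed``) through a ``SeedSequence`` spawn tree, so individual
    patients are reproducible.
    """
    if config.n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    lo, hi = config.ied_count_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid ied_count_range")
    space = leadfield.source_space
    if config.jitter_mm < 0 or config.jitter_mm > 2 * space.head_radius:
        raise ValueError("jitter_mm must be within the head diameter")
    q_lo, q_hi = config.moment_range_nAm
    if not (0 < q_lo <= q_hi):
        raise ValueError("invalid moment range")

    root = np.random.SeedSequence(config.seed if seed is None else seed)
    patient_seeds = root.spawn(config.n_patients)

    radii = np.linalg.norm(space.points, axis=1)
    band_lo = config.depth_band[0] * space.head_radius
    band_hi = config.depth_band[1] * space.head_radius
    in_band = (radii >= band_lo) & (radii <= band_hi)

    patients: list[PatientRecord] = []
    for p in range(config.n_patients):
        pseq = patient_seeds[p]
        rng = np.random.default_rng(pseq)
        # pick a true IZ region that has candidate points in the depth band
        region_order = rng.permutation(len(REGIONS))
        centre_idx = None
        true_region = None
        for ridx in region_order:
            region = REGIONS[ridx]
            candidates = region_points(space, labels, region)
            candidates = candidates[in_band[candidates]]
            if candidates.size:
                true_region = region
                centre_idx = int(rng.choice(candidates))
                break
        if centre_idx is None:
            raise ValueError("no source points available in the depth band")
        centre = space.points[centre_idx]

        # IED dipoles: region points within jitter_mm of the centre
        region_idx = region_points(space, labels, true_region)
        near = region_idx[
            np.linalg.norm(space.points[region_idx] - centre, axis=1)
            <= config.jitter_mm + 1e-9
        ]
        n_ied = int(rng.integers(lo, hi + 1))
        ied_seeds = pseq.generate_state(n_ied + 8)[8:] % (2**31)
        records = []
        for k in range(n_ied):
            j = int(rng.choice(near))
            loc = space.points[j]
            direction = _tangential_direction(rng, loc)
            magnitude = rng.uniform(q_lo, q_hi)
            rec = simulate_ied_topography(
                leadfield,
                loc,
                magnitude * direction,
                snr=config.snr,
                seed=int(ied_seeds[k]),
            )
            records.append(rec)

        concordant = rng.uniform() < config.concordant_fraction
        if concordant:
            plan = frozenset({true_region})
        else:
            others = [r for r in REGIONS if r != true_region]
            plan = frozenset({others[int(rng.integers(len(others)))]})
        p_good = config.p_good_concordant if concordant else config.p_good_discordant
        good = rng.uniform() < p_good
        engel = "1" if good else str(rng.integers(2, 5))
        patients.append(
            PatientRecord(
                id=f"S{p + 1:02d}",
                ied_records=tuple(records),
                true_iz_region=true_region,
                plan_lobes=plan,
                engel=engel,
                operated=True,
            )
        )
    return patients
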