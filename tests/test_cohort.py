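"""Synthetic spike/cohort generation and the packaged clinical tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import izbench
from izbench.cohort import CohortConfig, simulate_cohort, simulate_ied_topography
from izbench.fixtures import (
    FixtureIntegrityError,
    PATIENT_IDS,
    _validate,
    load_paper_tables,
)


class TestIEDTopography:
    def test_infinite_snr_is_exact_forward_field(self, grid_head):
        space, leadfield, _ = grid_head
        q = np.array([0.0, 120.0, 0.0])
        rec = simulate_ied_topography(leadfield, space.points[50], q, snr=np.inf)
        assert np.array_equal(rec.topography, leadfield.topography(50, q))

    def test_location_snaps_to_nearest_grid_point(self, grid_head):
        space, leadfield, _ = grid_head
        off_grid = space.points[50] + np.array([1.0, -2.0, 0.5])
        rec = simulate_ied_topography(
            leadfield, off_grid, np.array([0.0, 100.0, 0.0]), snr=np.inf
        )
        assert np.array_equal(rec.true_location, space.points[50])

    def test_seed_reproducibility(self, grid_head):
        space, leadfield, _ = grid_head
        q = np.array([0.0, 100.0, 50.0])
        a = simulate_ied_topography(leadfield, space.points[9], q, snr=4.0, seed=3)
        b = simulate_ied_topography(leadfield, space.points[9], q, snr=4.0, seed=3)
        c = simulate_ied_topography(leadfield, space.points[9], q, snr=4.0, seed=4)
        assert np.array_equal(a.topography, b.topography)
        assert not np.array_equal(a.topography, c.topography)

    def test_zero_moment_rejected(self, grid_head):
        space, leadfield, _ = grid_head
        with pytest.raises(ValueError):
            simulate_ied_topography(leadfield, space.points[0], np.zeros(3))

    def test_noise_scaling_matches_requested_snr(self, grid_head, cortical_band_indices):
        """Monte Carlo check of the noise-scaling formula: the realized
        signal-power/noise-power ratio converges to the requested SNR."""
        space, leadfield, _ = grid_head
        j = int(cortical_band_indices[7])
        loc = space.points[j]
        radial = loc / np.linalg.norm(loc)
        v = np.cross(radial, [0.0, 0.0, 1.0])
        q = 200.0 * v / np.linalg.norm(v)
        y0 = leadfield.topography(j, q)
        target = 4.0
        ratios = []
        for seed in range(200):
            rec = simulate_ied_topography(leadfield, loc, q, snr=target, seed=seed)
            noise = rec.topography - y0
            ratios.append(np.mean(y0**2) / np.mean(noise**2))
        assert abs(np.mean(ratios) / target - 1.0) < 0.05


class TestCohortSimulation:
    def test_cohort_is_reproducible_for_fixed_seed(self, grid_head):
        _, leadfield, labels = grid_head
        cfg = CohortConfig(n_patients=3, ied_count_range=(2, 4), seed=11)
        a = simulate_cohort(cfg, leadfield, labels)
        b = simulate_cohort(cfg, leadfield, labels)
        for pa, pb in zip(a, b):
            assert pa.true_iz_region == pb.true_iz_region
            assert pa.plan_lobes == pb.plan_lobes and pa.engel == pb.engel
            for ra, rb in zip(pa.ied_records, pb.ied_records):
                assert np.array_equal(ra.topography, rb.topography)

    def test_zero_jitter_pins_dipoles_to_the_true_region(self, grid_head):
        space, leadfield, labels = grid_head
        cfg = CohortConfig(n_patients=5, ied_count_range=(3, 6), jitter_mm=0.0, seed=2)
        label_arr = labels.as_array()
        for patient in simulate_cohort(cfg, leadfield, labels):
            locs = {tuple(r.true_location) for r in patient.ied_records}
            assert len(locs) == 1  # all spikes at the patient's centre point
            j = np.argmin(
                np.linalg.norm(space.points - patient.ied_records[0].true_location, axis=1)
            )
            assert label_arr[j] == patient.true_iz_region

    def test_dipole_cloud_stays_within_jitter_of_region(self, grid_head):
        space, leadfield, labels = grid_head
        cfg = CohortConfig(n_patients=4, ied_count_range=(5, 8), jitter_mm=15.0, seed=9)
        label_arr = labels.as_array()
        for patient in simulate_cohort(cfg, leadfield, labels):
            for rec in patient.ied_records:
                j = np.argmin(
                    np.linalg.norm(space.points - rec.true_location, axis=1)
                )
                assert label_arr[j] == patient.true_iz_region
                mag = np.linalg.norm(rec.true_moment)
                assert 50.0 <= mag <= 500.0

    def test_oracle_configuration_yields_perfect_ground_truth(self, grid_head):
        _, leadfield, labels = grid_head
        cfg = CohortConfig(
            n_patients=8,
            ied_count_range=(1, 2),
            concordant_fraction=1.0,
            p_good_concordant=1.0,
            p_good_discordant=0.0,
            seed=5,
        )
        for patient in simulate_cohort(cfg, leadfield, labels):
            assert patient.plan_lobes == frozenset({patient.true_iz_region})
            assert patient.engel == "1"

    def test_ied_counts_respect_the_configured_range(self, grid_head):
        _, leadfield, labels = grid_head
        cfg = CohortConfig(n_patients=6, ied_count_range=(8, 100), seed=1)
        counts = [len(p.ied_records) for p in simulate_cohort(cfg, leadfield, labels)]
        assert all(8 <= c <= 100 for c in counts)

    def test_impossible_jitter_rejected(self, grid_head):
        _, leadfield, labels = grid_head
        cfg = CohortConfig(n_patients=1, jitter_mm=500.0)
        with pytest.raises(ValueError):
            simulate_cohort(cfg, leadfield, labels)


class TestClinicalFixtures:
    def test_cohort_structure(self, fixtures):
        assert tuple(fixtures.table1.index) == PATIENT_IDS
        assert not fixtures.operated("P9") and not fixtures.operated("P10")
        assert sum(fixtures.operated(p) for p in PATIENT_IDS) == 20

    def test_spot_values_from_the_published_tables(self, fixtures):
        assert fixtures.metric_series("sesame", "dld")["P21"] == 7.67
        assert fixtures.plan_lobes("P4") == {"L T"}
        assert fixtures.engel("P4") == "4" and fixtures.operated("P4")
        top = max(fixtures.lobar_rows("sesame")["P16"], key=lambda rp: rp[1])
        assert top == ("R T", 84.0)
        assert fixtures.engel("P7") == "2/3"
        assert fixtures.plan_lobes("P16") == {"R T"}

    def test_percentages_strictly_above_display_threshold(self, fixtures):
        pct = fixtures.table3["percent"]
        assert (pct > 10).all() and (pct <= 100).all()

    def test_round_trip_is_value_identical(self, fixtures, tmp_path):
        for name, frame in (
            ("t1", fixtures.table1.reset_index()),
            ("t2", fixtures.table2),
            ("t3", fixtures.table3),
        ):
            path = tmp_path / f"{name}.csv"
            frame.to_csv(path, index=False)
            back = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
            back = back.replace("", np.nan).infer_objects()
            for col in frame.columns:
                a, b = frame[col], back[col]
                if a.dtype.kind == "f":
                    assert np.allclose(a.fillna(-1), b.astype(float).fillna(-1))
                else:
                    assert (a.fillna("") .astype(str) == b.fillna("").astype(str)).all()

    def test_tampered_percentage_fails_validation(self, fixtures):
        t3 = fixtures.table3.copy()
        t3.loc[t3.index[0], "percent"] = 9.0  # below the display threshold
        with pytest.raises(FixtureIntegrityError):
            _validate(fixtures.table1, fixtures.table2, t3)

    def test_missing_patient_fails_validation(self, fixtures):
        t1 = fixtures.table1.drop("P5")
        with pytest.raises(FixtureIntegrityError):
            _validate(t1, fixtures.table2, fixtures.table3)
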