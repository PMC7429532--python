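"""Unit and property tests of the four inverse solvers."""

import warnings

import numpy as np
import pytest

import izbench
from izbench.cohort import simulate_ied_topography
from izbench.solvers import (
    BayesPrior,
    bayes_dipole_map_exact,
    bayes_dipole_map_smc,
    ecd_fit,
    music_scan,
    wmne_map,
)
from conftest import tangential_unit


def make_spike(leadfield, j, magnitude=200.0, snr=np.inf, seed=None, rng_seed=0):
    space = leadfield.source_space
    loc = space.points[j]
    v = tangential_unit(np.random.default_rng(rng_seed), loc)
    return simulate_ied_topography(leadfield, loc, magnitude * v, snr=snr, seed=seed)


class TestECDFit:
    def test_noiseless_recovery_is_submillimetre(self, grid_head, cortical_band_indices):
        space, leadfield, _ = grid_head
        rng = np.random.default_rng(3)
        for k in range(5):
            j = int(rng.choice(cortical_band_indices))
            rec = make_spike(leadfield, j, magnitude=150.0, rng_seed=k)
            fit = ecd_fit(rec, leadfield)
            assert np.linalg.norm(fit.location - space.points[j]) < 1.0
            assert fit.gof > 99.9
            assert fit.accepted

    def test_out_of_range_moment_is_rejected(self, grid_head, cortical_band_indices):
        _, leadfield, _ = grid_head
        rec = make_spike(leadfield, int(cortical_band_indices[4]), magnitude=600.0)
        fit = ecd_fit(rec, leadfield)
        assert fit.moment_magnitude > 500.0
        assert not fit.accepted

    def test_pure_noise_fails_goodness_of_fit(self, grid_head):
        _, leadfield, _ = grid_head
        for seed in range(5):
            noise = np.random.default_rng(seed).standard_normal(204)
            fit = ecd_fit(noise, leadfield)
            assert fit.gof < 80.0
            assert not fit.accepted

    def test_channel_mask_restricts_the_fit(self, grid_head, cortical_band_indices):
        space, leadfield, _ = grid_head
        j = int(cortical_band_indices[11])
        rec = make_spike(leadfield, j, magnitude=150.0)
        strongest = np.argsort(-np.abs(rec.topography))[:60]
        fit = ecd_fit(rec, leadfield, channel_mask=strongest)
        assert np.linalg.norm(fit.location - space.points[j]) < 1.0

    def test_too_few_channels_rejected(self, grid_head):
        _, leadfield, _ = grid_head
        rec = make_spike(leadfield, 100)
        with pytest.raises(ValueError):
            ecd_fit(rec, leadfield, channel_mask=np.arange(5))


class TestBayesMap:
    def test_single_point_space_gives_unit_mass(self, sensors):
        space = izbench.build_volume_source_space(2.0, 5.0, 0.0)
        leadfield = izbench.sphere_leadfield(space, sensors)
        prior = BayesPrior(moment_std=100.0, noise_std=1.0)
        m = bayes_dipole_map_exact(np.ones(204), leadfield, prior)
        assert np.array_equal(m.values, [1.0])
        s = bayes_dipole_map_smc(np.ones(204), leadfield, prior, seed=0)
        assert np.array_equal(s.values, [1.0])

    def test_noiseless_peak_at_generating_point(self, shell_head):
        space, leadfield = shell_head
        rec = make_spike(leadfield, 12, magnitude=200.0)
        prior = BayesPrior(moment_std=250.0, noise_std=0.01 * np.abs(rec.topography).max())
        m = bayes_dipole_map_exact(rec, leadfield, prior)
        assert m.peak_index == 12
        assert m.values[12] > 0.99

    def test_joint_rescaling_invariance(self, shell_head):
        _, leadfield = shell_head
        rec = make_spike(leadfield, 30, snr=3.0, seed=8)
        p1 = BayesPrior(moment_std=100.0, noise_std=50.0)
        p2 = BayesPrior(moment_std=200.0, noise_std=100.0)
        m1 = bayes_dipole_map_exact(rec.topography, leadfield, p1)
        m2 = bayes_dipole_map_exact(2.0 * rec.topography, leadfield, p2)
        assert np.allclose(m1.values, m2.values, atol=1e-12)

    def test_default_prior_follows_data_ratio_convention(self, shell_head):
        _, leadfield = shell_head
        rec = make_spike(leadfield, 5)
        prior = BayesPrior.from_data(rec, leadfield)
        peak = np.abs(rec.topography).max()
        assert prior.moment_std == peak / np.abs(leadfield.matrix).max()
        assert prior.noise_std == pytest.approx(0.2 * peak)

    def test_smc_is_seed_reproducible(self, shell_head):
        _, leadfield = shell_head
        rec = make_spike(leadfield, 40, snr=2.0, seed=1)
        prior = BayesPrior.from_data(rec, leadfield, noise_factor=0.3, n_particles=500)
        a = bayes_dipole_map_smc(rec, leadfield, prior, seed=7)
        b = bayes_dipole_map_smc(rec, leadfield, prior, seed=7)
        c = bayes_dipole_map_smc(rec, leadfield, prior, seed=8)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestMusicScan:
    def test_noiseless_correlation_is_one_at_truth(self, grid_head, cortical_band_indices):
        space, leadfield, _ = grid_head
        j = int(cortical_band_indices[21])
        rec = make_spike(leadfield, j)
        out = music_scan(rec, leadfield)
        assert out.peak_index == j
        assert out.correlation == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_topography_has_zero_correlation(self, shell_head):
        space, leadfield = shell_head
        j = 3
        block = leadfield.blocks()[j]
        rng = np.random.default_rng(0)
        y = rng.standard_normal(leadfield.n_channels)
        y -= block @ np.linalg.lstsq(block, y, rcond=None)[0]  # project out
        out = music_scan(y, leadfield)
        assert out.correlation_map[j] < 1e-9

    def test_zero_topography_rejected(self, shell_head):
        _, leadfield = shell_head
        with pytest.raises(ValueError):
            music_scan(np.zeros(leadfield.n_channels), leadfield)

    def test_noisy_recovery_within_one_grid_spacing(self, grid_head, cortical_band_indices):
        space, leadfield, _ = grid_head
        rng = np.random.default_rng(12)
        hits = 0
        n_trials = 20
        for t in range(n_trials):
            j = int(rng.choice(cortical_band_indices))
            rec = make_spike(leadfield, j, snr=10.0, seed=1000 + t, rng_seed=t)
            est = music_scan(rec, leadfield).location
            hits += np.linalg.norm(est - space.points[j]) <= space.spacing + 1e-9
        assert hits >= int(0.95 * n_trials)

    def test_multisample_window_uses_signal_subspace(self, grid_head, cortical_band_indices):
        space, leadfield, _ = grid_head
        j = int(cortical_band_indices[2])
        rec = make_spike(leadfield, j)
        window = np.outer(rec.topography, [1.0, 0.7, -0.4])
        out = music_scan(window, leadfield)
        assert out.peak_index == j


class TestWMNEMap:
    def test_zero_depth_exponent_matches_classical_minimum_norm(self, shell_head):
        space, leadfield = shell_head
        rec = make_spike(leadfield, 8)
        m = wmne_map(rec, leadfield, depth_exponent=0.0, snr_reg=3.0)
        L = leadfield.matrix
        n = L.shape[0]
        alpha = n / np.trace(L @ L.T)
        j_hat = L.T @ np.linalg.solve(
            L @ L.T + (1.0 / 9.0) / alpha * np.eye(n), rec.topography
        )
        classical = np.linalg.norm(j_hat.reshape(-1, 3), axis=1)
        ratio = m.values / np.maximum(classical, 1e-300)
        keep = classical > 1e-9 * classical.max()
        assert np.allclose(ratio[keep], ratio[keep][0], rtol=1e-9)

    def test_superficial_source_peak_is_nearby(self, grid_head, cortical_band_indices):
        space, leadfield, _ = grid_head
        radii = np.linalg.norm(space.points[cortical_band_indices], axis=1)
        j = int(cortical_band_indices[np.argmax(radii)])
        rec = make_spike(leadfield, j, snr=20.0, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = wmne_map(rec, leadfield)
        assert np.linalg.norm(space.points[m.peak_index] - space.points[j]) <= (
            2.0 * space.spacing + 1e-9
        )

    def test_estimate_is_linear_in_the_data(self, shell_head):
        _, leadfield = shell_head
        rec = make_spike(leadfield, 8)
        m1 = wmne_map(rec.topography, leadfield)
        m2 = wmne_map(2.0 * rec.topography, leadfield)
        assert np.allclose(m2.values, 2.0 * m1.values, rtol=1e-12)
        assert m2.peak_index == m1.peak_index

    def test_invalid_parameters_rejected(self, shell_head):
        _, leadfield = shell_head
        rec = make_spike(leadfield, 8)
        with pytest.raises(ValueError):
            wmne_map(rec, leadfield, depth_exponent=-0.1)
        with pytest.raises(ValueError):
            wmne_map(rec, leadfield, snr_reg=0.0)
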