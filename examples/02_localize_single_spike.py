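"""Localize one simulated spike with all four inverse procedures.

Prints each method's point estimate, its distance from the true generator
(what the DLD measures against a benchmark), and for the map methods the
map spread (SD) and map-to-reference discrepancy (MLD).
"""

import warnings

import numpy as np

import izbench

warnings.simplefilter("ignore")

space = izbench.build_volume_source_space(90.0, 10.0, 12.0)
sensors = izbench.build_sensor_array()
leadfield = izbench.sphere_leadfield(space, sensors)

rng = np.random.default_rng(7)
radii = np.linalg.norm(space.points, axis=1)
j = int(rng.choice(np.flatnonzero((radii > 45) & (radii < 80))))
loc = space.points[j]
radial = loc / np.linalg.norm(loc)
v = rng.standard_normal(3)
v -= (v @ radial) * radial
moment = 250.0 * v / np.linalg.norm(v)
rec = izbench.simulate_ied_topography(leadfield, loc, moment, snr=10.0, seed=1)
print(f"true generator: {np.round(loc, 1)} mm, |q| = {np.linalg.norm(moment):.0f} nAm\n")

# equivalent current dipole fit (the clinical benchmark procedure)
fit = izbench.ecd_fit(rec, leadfield)
print(f"ECD fit      : {np.round(fit.location, 1)} mm, "
      f"err {izbench.dld(fit.location, loc):5.2f} mm, GOF {fit.gof:.1f}%, "
      f"accepted={fit.accepted}")

# Bayesian single-dipole posterior map
prior = izbench.BayesPrior.from_data(rec, leadfield, moment_std=250.0)
pmap = izbench.bayes_dipole_map_exact(rec, leadfield, prior)
peak = space.points[pmap.peak_index]
print(f"Bayes map    : {np.round(peak, 1)} mm, "
      f"err {izbench.dld(peak, loc):5.2f} mm, "
      f"MLD {izbench.mld(pmap.values, fit.location, space):5.2f} mm, "
      f"SD {izbench.spatial_dispersion(pmap.values, space):5.2f} mm")

# single-dipole MUSIC scan
mus = izbench.music_scan(rec, leadfield)
print(f"MUSIC scan   : {np.round(mus.location, 1)} mm, "
      f"err {izbench.dld(mus.location, loc):5.2f} mm, "
      f"subspace correlation {mus.correlation:.4f}")

# depth-weighted minimum-norm intensity map
imap = izbench.wmne_map(rec, leadfield)
wpeak = space.points[imap.peak_index]
print(f"wMNE map     : {np.round(wpeak, 1)} mm, "
      f"err {izbench.dld(wpeak, loc):5.2f} mm, "
      f"SD {izbench.spatial_dispersion(imap.values, space):5.2f} mm")

print("\nThe dipolar methods localize to the generating grid point; the "
      "minimum-norm map is smoother, with a broader spread (larger SD) and "
      "a peak that may sit a neighbouring grid point away.")
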