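"""Build a spherical head model and simulate one interictal spike.

The forward model is a current dipole in a homogeneous conducting sphere
(90 mm radius) observed by 204 planar gradiometers on a helmet shell at
110 mm.  Radial sources are magnetically silent, so the simulated spike
generators are tangential dipoles in the 50-500 nAm range.
"""

import numpy as np

import izbench

space = izbench.build_volume_source_space(head_radius=90.0, spacing=10.0, inner_margin=12.0)
sensors = izbench.build_sensor_array()  # 102 sites x 2 orthogonal gradiometers
leadfield = izbench.sphere_leadfield(space, sensors)
labels = izbench.assign_lobes(space)

print(f"source space: {space.n_points} grid points at {space.spacing:g} mm spacing")
print(f"leadfield: {leadfield.matrix.shape[0]} channels x {leadfield.matrix.shape[1]} columns")

# a right-temporal generator, tangential moment of 200 nAm
j = int(np.flatnonzero(labels.as_array() == "R T")[40])
loc = space.points[j]
radial = loc / np.linalg.norm(loc)
tangential = np.cross(radial, [0.0, 0.0, 1.0])
tangential /= np.linalg.norm(tangential)

rec = izbench.simulate_ied_topography(leadfield, loc, 200.0 * tangential, snr=10.0, seed=0)
print(f"spike generator at {np.round(loc, 1)} mm in region {labels.labels[j]}")
print(f"peak gradiometer amplitude: {np.abs(rec.topography).max():.0f} fT/cm "
      f"(SNR {rec.snr:g}, power ratio)")

silent = np.linalg.norm(leadfield.blocks()[j] @ radial)
print(f"field of the radial moment at the same point: {silent:.2e} fT/cm "
      "(radial sources are silent in a sphere)")
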