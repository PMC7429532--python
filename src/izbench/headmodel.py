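"""Spherical head model, sensor arrays and analytic MEG leadfields.

The forward model is a current dipole inside a homogeneous conducting
sphere (Sarvas closed form).  For MEG this is an excellent approximation
of realistic single-shell conductor models: the magnetic field outside a
spherically symmetric conductor does not depend on the conductivity
profile, and radial sources are magnetically silent.

Conventions
-----------
* Positions in mm, sphere centre at the origin; +x = right, +y = anterior,
  +z = superior (right-handed head frame).
* Dipole moments in nAm.
* Magnetometer channels report the field component along the sensor
  orientation in fT per unit moment; planar gradiometers report the finite
  difference of that component across the baseline, in fT/cm.
"""

from __future__ import annotations

import dataclasses
from enum import Enum

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "SourceSpaceKind",
    "SensorKind",
    "SourceSpace",
    "SensorArray",
    "Leadfield",
    "build_volume_source_space",
    "build_cortical_like_source_space",
    "build_sensor_array",
    "sphere_leadfield",
    "point_gain",
    "dipole_field",
]

#: mu_0 / 4 pi, in T * m / (A * m)
_MU0_OVER_4PI = 1e-7
#: combined unit conversion: positions mm -> m, moments nAm -> Am, field T -> fT
_FIELD_SCALE = _MU0_OVER_4PI * 1e-9 * 1e15  # = 0.1 when distances are in metres


class DegenerateGeometryError(ValueError):
    """Raised when the requested geometry cannot host a forward model."""


class SourceSpaceKind(str, Enum):
    volume = "volume"
    cortical = "cortical"


class SensorKind(str, Enum):
    magnetometer = "magnetometer"
    planar_gradiometer = "planar_gradiometer"


@dataclasses.dataclass(frozen=True)
class SourceSpace:
    """Discretised candidate source locations inside the head sphere."""

    points: np.ndarray  # (N, 3) mm
    kind: SourceSpaceKind
    spacing: float  # mm (nominal for cortical-like spaces)
    head_radius: float  # mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if pts.shape[0] == 0:
            raise DegenerateGeometryError("source space is empty")
        if not np.all(np.isfinite(pts)):
            raise ValueError("source points must be finite")
        radii = np.linalg.norm(pts, axis=1)
        if np.any(radii >= self.head_radius):
            raise DegenerateGeometryError(
                "all source points must lie strictly inside the head sphere"
            )
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclasses.dataclass(frozen=True)
class SensorArray:
    """MEG pickup coils on a shell outside the head sphere.

    For planar gradiometers each channel additionally carries a baseline
    direction (tangential unit vector); the channel output is the field
    component along ``orientations`` differenced across ``baseline`` mm
    along that direction, divided by the baseline in cm.
    """

    positions: np.ndarray  # (M, 3) mm
    orientations: np.ndarray  # (M, 3) unit vectors
    sensor_kind: SensorKind
    baseline: float | None = None  # mm, gradiometers only
    baseline_dirs: np.ndarray | None = None  # (M, 3) unit vectors
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.shape != ori.shape or pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions and orientations must both be (M, 3)")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientations must be unit vectors")
        if self.sensor_kind == SensorKind.planar_gradiometer:
            if self.baseline is None or self.baseline <= 0:
                raise ValueError("gradiometers require a positive baseline")
            if self.baseline_dirs is None:
                raise ValueError("gradiometers require baseline directions")
            bd = np.asarray(self.baseline_dirs, dtype=float)
            if bd.shape != pos.shape:
                raise ValueError("baseline_dirs must be (M, 3)")
            if not np.allclose(np.linalg.norm(bd, axis=1), 1.0, atol=1e-8):
                raise ValueError("baseline_dirs must be unit vectors")
            object.__setattr__(self, "baseline_dirs", bd)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        if self.channel_names is None:
            prefix = "MEG"
            names = tuple(f"{prefix}{i:04d}" for i in range(pos.shape[0]))
            object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return int(self.positions.shape[0])

    def min_radius(self) -> float:
        return float(np.linalg.norm(self.positions, axis=1).min())


@dataclasses.dataclass(frozen=True)
class Leadfield:
    """Forward operator: channels x (3 * n_points), point-major columns."""

    matrix: np.ndarray
    channel_names: tuple[str, ...]
    source_space: SourceSpace
    sensors: SensorArray | None = None

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 3 * self.source_space.n_points:
            raise ValueError("leadfield must be channels x (3 * n_points)")
        if not np.all(np.isfinite(mat)):
            raise ValueError("leadfield entries must be finite")
        object.__setattr__(self, "matrix", mat)

    @property
    def n_channels(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_points(self) -> int:
        return self.source_space.n_points

    def blocks(self) -> np.ndarray:
        """Per-point gain blocks, shape (n_points, n_channels, 3)."""
        n, m = self.matrix.shape
        return self.matrix.reshape(n, m // 3, 3).transpose(1, 0, 2)

    def topography(self, point_index: int, moment: np.ndarray) -> np.ndarray:
        """Noise-free sensor vector of a dipole at a source point."""
        block = self.matrix[:, 3 * point_index : 3 * point_index + 3]
        return block @ np.asarray(moment, dtype=float)


# ---------------------------------------------------------------------------
# source spaces
# ---------------------------------------------------------------------------


def build_volume_source_space(
    head_radius: float, spacing: float, inner_margin: float = 0.0
) -> SourceSpace:
    """Regular cubic grid restricted to ``|p| <= head_radius - inner_margin``.

    Mirrors volumetric source grids used in clinical MEG pipelines
    (typically 5 mm spacing).  Deterministic for fixed arguments.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if inner_margin < 0:
        raise ValueError("inner_margin must be nonnegative")
    if head_radius <= 0:
        raise DegenerateGeometryError("head_radius must be positive")
    rmax = head_radius - inner_margin
    k = int(np.floor(max(rmax, 0.0) / spacing))
    coords = spacing * np.arange(-k, k + 1)
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    norms = np.linalg.norm(pts, axis=1)
    # boundary points (possible when inner_margin = 0) violate the
    # strict-interior invariant and are dropped
    keep = (norms <= rmax + 1e-12) & (norms < head_radius - 1e-12)
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise DegenerateGeometryError(
            f"no grid points fit inside radius {rmax} at spacing {spacing}"
        )
    return SourceSpace(
        points=pts,
        kind=SourceSpaceKind.volume,
        spacing=float(spacing),
        head_radius=float(head_radius),
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors from the golden-angle spiral."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def build_cortical_like_source_space(
    n_points: int,
    head_radius: float,
    shell_radii: tuple[float, float],
    seed: int,
    n_shells: int = 6,
) -> SourceSpace:
    """Quasi-uniform points on nested shells emulating a cortical surface set.

    Real cortical source spaces are irregular point clouds at roughly 5 mm
    spacing; here the cloud is emulated by golden-spiral points on
    ``n_shells`` nested shells spanning ``shell_radii``, each shell rotated
    by a seeded random rotation.  Reproducible for a fixed seed.
    """
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    r_in, r_out = float(shell_radii[0]), float(shell_radii[1])
    if not (0 < r_in <= r_out):
        raise ValueError("shell radii must satisfy 0 < inner <= outer")
    if r_out >= head_radius:
        raise DegenerateGeometryError("outer shell must lie inside the head")
    rng = np.random.default_rng(seed)
    radii = np.linspace(r_in, r_out, n_shells)
    # allocate points to shells proportionally to shell area
    weights = radii**2
    counts = np.floor(n_points * weights / weights.sum()).astype(int)
    counts[-1] += n_points - counts.sum()
    parts = []
    for r, c in zip(radii, counts):
        if c <= 0:
            continue
        dirs = _fibonacci_directions(int(c)) @ _random_rotation(rng).T
        parts.append(r * dirs)
    pts = np.vstack(parts)
    # nominal spacing from the point density on the mid shell
    r_mid = 0.5 * (r_in + r_out)
    spacing = float(np.sqrt(4.0 * np.pi * r_mid**2 / max(n_points, 1)))
    return SourceSpace(
        points=pts,
        kind=SourceSpaceKind.cortical,
        spacing=spacing,
        head_radius=float(head_radius),
    )


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------


def _tangent_frame(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangential directions per unit normal."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (normals.shape[0], 1))
    near_pole = np.abs(normals[:, 2]) > 0.9
    ref[near_pole] = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, normals)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    return e1, e2


def build_sensor_array(
    n_sites: int = 102,
    radius: float = 110.0,
    sensor_kind: SensorKind | str = SensorKind.planar_gradiometer,
    baseline: float = 16.8,
    z_min_frac: float = -0.35,
) -> SensorArray:
    """Helmet-like sensor shell.

    Sites are placed quasi-uniformly on the spherical cap ``z/radius >=
    z_min_frac`` (the helmet does not cover the lower face/neck).  For
    planar gradiometers two orthogonal channels are created per site, with
    radial pickup orientation and orthogonal tangential baselines, mirroring
    a 204-gradiometer whole-head layout.
    """
    kind = SensorKind(sensor_kind)
    # oversample a full Fibonacci sphere, keep the cap, trim to n_sites
    for oversample in (2.2, 3.0, 4.0, 6.0):
        dirs = _fibonacci_directions(int(np.ceil(n_sites * oversample)))
        cap = dirs[dirs[:, 2] >= z_min_frac]
        if cap.shape[0] >= n_sites:
            break
    if cap.shape[0] < n_sites:
        raise DegenerateGeometryError("cannot place that many sites on the cap")
    sites = cap[:n_sites]
    normals = sites / np.linalg.norm(sites, axis=1, keepdims=True)
    positions = radius * normals
    if kind == SensorKind.magnetometer:
        return SensorArray(
            positions=positions,
            orientations=normals,
            sensor_kind=kind,
        )
    e1, e2 = _tangent_frame(normals)
    pos2 = np.repeat(positions, 2, axis=0)
    ori2 = np.repeat(normals, 2, axis=0)
    bdirs = np.empty_like(pos2)
    bdirs[0::2] = e1
    bdirs[1::2] = e2
    names = []
    for i in range(n_sites):
        names += [f"MEG{i:03d}1", f"MEG{i:03d}2"]
    return SensorArray(
        positions=pos2,
        orientations=ori2,
        sensor_kind=kind,
        baseline=baseline,
        baseline_dirs=bdirs,
        channel_names=tuple(names),
    )


# ---------------------------------------------------------------------------
# Sarvas forward model
# ---------------------------------------------------------------------------


def dipole_field(
    sensor_points: np.ndarray,
    source_points: np.ndarray,
) -> np.ndarray:
    """Sarvas gain tensor ``T`` with ``B = T @ q``.

    Parameters are in mm; the returned tensor has shape
    ``(n_sensor_points, n_source_points, 3, 3)`` and maps a dipole moment
    in nAm to the magnetic field vector in fT at each sensor point,
    for a dipole inside a conducting sphere centred at the origin.
    """
    r = np.asarray(sensor_points, dtype=float) * 1e-3  # (M, 3) m
    r0 = np.asarray(source_points, dtype=float) * 1e-3  # (N, 3) m

    rr = r[:, None, :]  # (M, 1, 3)
    r0r = r0[None, :, :]  # (1, N, 3)
    a_vec = rr - r0r  # (M, N, 3)
    a = np.linalg.norm(a_vec, axis=-1)  # (M, N)
    R = np.linalg.norm(r, axis=-1)[:, None]  # (M, 1)
    r0_dot_r = np.einsum("mj,nj->mn", r, r0)
    a_dot_r = np.einsum("mnj,mj->mn", a_vec, r)

    F = a * (R * a + R**2 - r0_dot_r)  # (M, N)
    c1 = a**2 / R + a_dot_r / a + 2.0 * a + 2.0 * R
    c2 = a + 2.0 * R + a_dot_r / a
    grad_F = c1[..., None] * rr - c2[..., None] * r0r  # (M, N, 3)

    # B = k/F^2 * (F (q x r0) - ((q x r0) . r) grad_F)
    #   = k/F^2 * (F I - grad_F r^T) X q   with X q = q x r0 = -r0 x q
    # cross-product matrix for u = q x r0: u = C q with C = [[0, z0, -y0], ...]
    x0, y0, z0 = r0[:, 0], r0[:, 1], r0[:, 2]
    zeros = np.zeros_like(x0)
    C = np.stack(
        [
            np.stack([zeros, z0, -y0], axis=-1),
            np.stack([-z0, zeros, x0], axis=-1),
            np.stack([y0, -x0, zeros], axis=-1),
        ],
        axis=-2,
    )  # (N, 3, 3), u = C @ q

    with np.errstate(divide="ignore", invalid="ignore"):
        inv_F2 = 1.0 / F**2
    # A = F * I - grad_F r^T, per (m, n)
    eye = np.eye(3)
    A = F[..., None, None] * eye - grad_F[..., :, None] * rr[..., None, :]
    T = _FIELD_SCALE * inv_F2[..., None, None] * (A @ C[None, :, :, :])
    # dipole at the sphere centre (or coinciding with a sensor) -> zero field
    bad = ~np.isfinite(T)
    if np.any(bad):
        T = np.where(bad, 0.0, T)
    # exact zero for sources at the origin
    at_origin = np.linalg.norm(r0, axis=1) < 1e-300
    if np.any(at_origin):
        T[:, at_origin] = 0.0
    return T


def _oriented_gain_single(
    points: np.ndarray, orientations: np.ndarray, r0_mm: np.ndarray
) -> np.ndarray:
    """Oriented-field gain of one source at many pickup points, (M, 3).

    Same closed form as :func:`dipole_field` but specialised to a single
    source location; used in the hot loop of continuous dipole fitting.
    """
    r = points * 1e-3
    o = orientations
    r0 = np.asarray(r0_mm, dtype=float) * 1e-3
    if np.dot(r0, r0) < 1e-300:
        return np.zeros((r.shape[0], 3))
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    a_dot_r = np.einsum("mj,mj->m", a_vec, r)
    r0_dot_r = r @ r0
    F = a * (R * a + R**2 - r0_dot_r)
    c1 = a**2 / R + a_dot_r / a + 2.0 * a + 2.0 * R
    c2 = a + 2.0 * R + a_dot_r / a
    # w = k/F^2 (F o - (gradF . o) r); gain = w @ C with C q = q x r0
    grad_dot_o = c1 * np.einsum("mj,mj->m", r, o) - c2 * (o @ r0)
    w = (_FIELD_SCALE / F**2)[:, None] * (F[:, None] * o - grad_dot_o[:, None] * r)
    x0, y0, z0 = r0
    C = np.array([[0.0, z0, -y0], [-z0, 0.0, x0], [y0, -x0, 0.0]])
    return w @ C


def single_point_gain(sensors: SensorArray, location: np.ndarray) -> np.ndarray:
    """Channel gain block (n_channels, 3) at one continuous location."""
    loc = np.asarray(location, dtype=float)
    if sensors.sensor_kind == SensorKind.magnetometer:
        return _oriented_gain_single(sensors.positions, sensors.orientations, loc)
    half = 0.5 * sensors.baseline * sensors.baseline_dirs
    b_plus = _oriented_gain_single(
        sensors.positions + half, sensors.orientations, loc
    )
    b_minus = _oriented_gain_single(
        sensors.positions - half, sensors.orientations, loc
    )
    return (b_plus - b_minus) / (sensors.baseline / 10.0)


def point_gain(sensors: SensorArray, locations: np.ndarray) -> np.ndarray:
    """Channel gain blocks at arbitrary source locations.

    Returns an array of shape ``(n_locations, n_channels, 3)`` giving each
    channel's response to unit x/y/z moments (nAm) at each location (mm).
    """
    loc = np.atleast_2d(np.asarray(locations, dtype=float))
    if sensors.sensor_kind == SensorKind.magnetometer:
        T = dipole_field(sensors.positions, loc)  # (M, N, 3, 3)
        gain = np.einsum("mj,mnjk->mnk", sensors.orientations, T)
        return gain.transpose(1, 0, 2)  # (N, M, 3), fT / nAm
    half = 0.5 * sensors.baseline * sensors.baseline_dirs
    T_plus = dipole_field(sensors.positions + half, loc)
    T_minus = dipole_field(sensors.positions - half, loc)
    b_plus = np.einsum("mj,mnjk->mnk", sensors.orientations, T_plus)
    b_minus = np.einsum("mj,mnjk->mnk", sensors.orientations, T_minus)
    baseline_cm = sensors.baseline / 10.0
    gain = (b_plus - b_minus) / baseline_cm  # fT/cm per nAm
    return gain.transpose(1, 0, 2)


def sphere_leadfield(
    space: SourceSpace,
    sensors: SensorArray,
    chunk: int = 512,
) -> Leadfield:
    """Assemble the leadfield of a source space under the sphere model."""
    if sensors.min_radius() <= space.head_radius:
        raise DegenerateGeometryError("all sensors must lie outside the head sphere")
    n_pts = space.n_points
    mat = np.empty((sensors.n_channels, 3 * n_pts))
    for start in range(0, n_pts, chunk):
        stop = min(start + chunk, n_pts)
        gain = point_gain(sensors, space.points[start:stop])  # (k, M, 3)
        mat[:, 3 * start : 3 * stop] = gain.transpose(1, 0, 2).reshape(
            sensors.n_channels, -1
        )
    return Leadfield(
        matrix=mat,
        channel_names=sensors.channel_names,
        source_space=space,
        sensors=sensors,
    )
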