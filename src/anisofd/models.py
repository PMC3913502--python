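"""Volume-conduction model fixtures.

* A smooth analytic probe problem with a known exact potential, a smooth
  full conductivity tensor and a hand-derived closed-form right-hand side.
* The 4-shell anisotropic spherical head model embedded in a fictitious
  box of air, with optional highly conductive clip insertions.
* The diffusion-tensor to conductivity-tensor transform for white matter.
* Quasi-uniform geodesic sensor montages and trilinear sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import (AIR_CONDUCTIVITY, RegularGrid, ScalarVolume,
                   SphereModelSpec, TensorField)

__all__ = [
    "ProbeSolution",
    "SensorMontage",
    "build_smooth_probe",
    "build_sphere_model",
    "skull_tensor_at",
    "insert_clip",
    "default_clip_boxes",
    "dti_to_conductivity",
    "synthetic_dti_field",
    "geodesic_sensors",
    "sample_sensors",
]


# ---------------------------------------------------------------------------
# smooth analytic probe
# ---------------------------------------------------------------------------

@dataclass
class ProbeSolution:
    """Exact potential, tensor field and analytic RHS on a cube [-a, a]^3.

    The potential is the product of the six face factors,

        u = (x - a)(x + a)(y - a)(y + a)(z - a)(z + a),

    which vanishes on all box faces.  The tensor has diagonal components
    6, 5, 4 times ``(2 + x^2 + y^2 + z^2)`` and all off-diagonal components
    equal to ``sin(x^2 + y^2 + z^2 - 3)``.  The right-hand side is
    ``div(sigma grad u)`` differentiated analytically once and hard-coded.
    """

    grid: RegularGrid
    half_edge: float
    potential: ScalarVolume
    sigma: TensorField
    rhs: ScalarVolume

    def system_rhs(self) -> ScalarVolume:
        """RHS with zeros on the box faces, matching the homogeneous
        Dirichlet identity rows of the assembled operator."""
        f = self.rhs.values.copy()
        mask = ~self.grid.interior_mask()
        f[mask] = 0.0
        return ScalarVolume(self.grid, f)


def probe_potential(x, y, z, a: float):
    return (x - a) * (x + a) * (y - a) * (y + a) * (z - a) * (z + a)


def probe_tensor_components(x, y, z):
    s = x * x + y * y + z * z
    q = 2.0 + s
    off = np.sin(s - 3.0)
    return 6.0 * q, 5.0 * q, 4.0 * q, off


def probe_rhs(x, y, z, a: float):
    """Closed-form ``div(sigma grad u)`` for the probe fields."""
    a2 = a * a
    X = x * x - a2
    Y = y * y - a2
    Z = z * z - a2
    s = x * x + y * y + z * z
    q = 2.0 + s
    c = np.cos(s - 3.0)
    sn = np.sin(s - 3.0)
    # d/dx(sxx du/dx) + d/dy(syy du/dy) + d/dz(szz du/dz)
    f = (2.0 * Y * Z * 6.0 * (2.0 * x * x + q)
         + 2.0 * X * Z * 5.0 * (2.0 * y * y + q)
         + 2.0 * X * Y * 4.0 * (2.0 * z * z + q))
    # six mixed terms, paired: d/dx(s du/dy) + d/dy(s du/dx), etc.
    f += 4.0 * c * (x * y * (X + Y) * Z
                    + x * z * (X + Z) * Y
                    + y * z * (Y + Z) * X)
    f += 8.0 * sn * (x * y * Z + x * z * Y + y * z * X)
    return f


def build_smooth_probe(grid: RegularGrid, a: Optional[float] = None) -> ProbeSolution:
    """Evaluate the probe potential, tensor and RHS on a cube grid.

    The grid must span ``[-a, a]^3``; when ``a`` is omitted it is inferred
    from the grid extent.
    """
    extents = [(grid.axis_coords(ax)[0], grid.axis_coords(ax)[-1]) for ax in range(3)]
    if a is None:
        a = extents[0][1]
    for lo, hi in extents:
        if not (np.isclose(lo, -a, atol=1e-12 + 1e-9 * abs(a))
                and np.isclose(hi, a, atol=1e-12 + 1e-9 * abs(a))):
            raise ValueError(f"grid does not span [-{a}, {a}]^3")
    x, y, z = grid.meshgrid()
    u = probe_potential(x, y, z, a)
    sxx, syy, szz, off = probe_tensor_components(x, y, z)
    sigma = TensorField(grid, sxx, syy, szz, off, off.copy(), off.copy())
    f = probe_rhs(x, y, z, a)
    return ProbeSolution(grid, a, ScalarVolume(grid, u), sigma, ScalarVolume(grid, f))


# ---------------------------------------------------------------------------
# 4-shell sphere with anisotropic skull
# ---------------------------------------------------------------------------

def skull_tensor_at(point, centre, sigma_radial: float,
                    sigma_tangential: float) -> np.ndarray:
    """Anisotropic skull tensor at a point: radial/tangential diagonal form
    rotated into global coordinates.

    Equals ``R diag(st, st, sr) R^T`` with the third local axis along the
    radial direction; eigenvalues are exactly ``{sr, st, st}``.
    """
    d = np.asarray(point, dtype=float) - np.asarray(centre, dtype=float)
    r = np.linalg.norm(d)
    if r == 0.0:
        raise ValueError("radial direction undefined at the sphere centre")
    rhat = d / r
    return sigma_tangential * np.eye(3) + (sigma_radial - sigma_tangential) * np.outer(rhat, rhat)


def build_sphere_model(spec: SphereModelSpec, grid: RegularGrid) -> TensorField:
    """Assign per-node tensors by radius for the 4-shell model.

    Shells are half-open (a node exactly on an outer radius belongs to the
    inner shell); nodes beyond the scalp radius get isotropic air.  The
    sphere must leave at least one air node of margin to every box face.
    """
    r_scalp, r_skull, r_csf, r_brain = spec.shell_radii
    c_scalp, _c_skull_printed, c_csf, c_brain = spec.shell_conductivities

    centre = np.asarray(spec.centre)
    for ax in range(3):
        coords = grid.axis_coords(ax)
        if (centre[ax] - r_scalp <= coords[1]) or (centre[ax] + r_scalp >= coords[-2]):
            raise ValueError("sphere does not fit inside the grid with an air margin")

    x, y, z = grid.meshgrid()
    dx, dy, dz = x - centre[0], y - centre[1], z - centre[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)

    iso = np.full(grid.shape, spec.air_conductivity)
    iso[r <= r_scalp] = c_scalp
    iso[r <= r_csf] = c_csf
    iso[r <= r_brain] = c_brain

    sxx = iso.copy()
    syy = iso.copy()
    szz = iso.copy()
    sxy = np.zeros(grid.shape)
    sxz = np.zeros(grid.shape)
    syz = np.zeros(grid.shape)

    skull = (r > r_csf) & (r <= r_skull)
    if skull.any():
        sr = spec.skull_sigma_radial
        st = spec.skull_sigma_tangential
        rs = r[skull]
        ux, uy, uz = dx[skull] / rs, dy[skull] / rs, dz[skull] / rs
        diff = sr - st
        sxx[skull] = st + diff * ux * ux
        syy[skull] = st + diff * uy * uy
        szz[skull] = st + diff * uz * uz
        sxy[skull] = diff * ux * uy
        sxz[skull] = diff * ux * uz
        syz[skull] = diff * uy * uz

    return TensorField(grid, sxx, syy, szz, sxy, sxz, syz)


# ---------------------------------------------------------------------------
# clip insertion
# ---------------------------------------------------------------------------

def default_clip_boxes(centre, height: float = 0.012, width: float = 0.012,
                       bar_thickness: float = 0.002,
                       bar_depth: float = 0.004) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Pi-shaped clip as a union of three axis-aligned boxes.

    Default dimensions: 12 x 12 x 12 mm envelope with 2 x 4 mm bar
    cross-sections (one top bar along y, two vertical legs along z).
    """
    cx, cy, cz = (float(v) for v in np.asarray(centre, dtype=float))
    top = (np.array([cx, cy, cz + height / 2 - bar_thickness / 2]),
           np.array([bar_depth, width, bar_thickness]))
    left = (np.array([cx, cy - width / 2 + bar_thickness / 2, cz - bar_thickness / 2]),
            np.array([bar_depth, bar_thickness, height - bar_thickness]))
    right = (np.array([cx, cy + width / 2 - bar_thickness / 2, cz - bar_thickness / 2]),
             np.array([bar_depth, bar_thickness, height - bar_thickness]))
    return [top, left, right]


def insert_clip(sigma: TensorField, box_centre, box_dims,
                conductivity: float = 2.5e6,
                boxes: Optional[Iterable] = None) -> TensorField:
    """Set nodes inside an axis-aligned box (or a union of boxes) to an
    isotropic conductivity; all other nodes are unchanged.

    ``boxes`` overrides the single box with a list of ``(centre, dims)``
    pairs (e.g. from :func:`default_clip_boxes`).

    A box thinner than one grid spacing along an axis (but of positive
    extent) is widened to half a spacing so that it still captures the
    nearest node plane; zero-extent boxes select nothing.
    """
    grid = sigma.grid
    if boxes is None:
        boxes = [(np.asarray(box_centre, dtype=float),
                  np.asarray(box_dims, dtype=float))]
    x, y, z = grid.meshgrid()
    out = sigma.copy()
    for centre, dims in boxes:
        centre = np.asarray(centre, dtype=float)
        dims = np.asarray(dims, dtype=float)
        if np.any(dims <= 0.0):  # zero-volume box selects nothing
            continue
        # the +eps keeps a node plane exactly h/2 away (centre midway
        # between planes) inside the selection despite float rounding
        half = np.maximum(dims / 2.0, grid.spacing / 2.0) + 1e-9 * grid.spacing
        lo, hi = centre - half, centre + half
        for ax, c in enumerate(grid.origin):
            if hi[ax] < grid.axis_coords(ax)[0] - 1e-15 or \
               lo[ax] > grid.axis_coords(ax)[-1] + 1e-15:
                raise ValueError("clip box lies outside the grid")
        mask = ((x >= lo[0]) & (x <= hi[0]) &
                (y >= lo[1]) & (y <= hi[1]) &
                (z >= lo[2]) & (z <= hi[2]))
        out.sxx[mask] = conductivity
        out.syy[mask] = conductivity
        out.szz[mask] = conductivity
        out.sxy[mask] = 0.0
        out.sxz[mask] = 0.0
        out.syz[mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# DTI -> conductivity
# ---------------------------------------------------------------------------

def dti_to_conductivity(D: TensorField, sigma_iso: float) -> TensorField:
    """White-matter conductivity tensor ``3 sigma_iso D / tr(D)``.

    The output trace is exactly ``3 sigma_iso`` at every node and the
    eigenvectors (principal diffusion directions) are preserved.
    """
    tr = D.sxx + D.syy + D.szz
    bad = np.argwhere(tr <= 0.0)
    if bad.size:
        raise ValueError(
            f"diffusion tensor has non-positive trace at node {tuple(bad[0])}"
        )
    scale = 3.0 * sigma_iso / tr
    return TensorField(D.grid, D.sxx * scale, D.syy * scale, D.szz * scale,
                       D.sxy * scale, D.sxz * scale, D.syz * scale)


def synthetic_dti_field(grid: RegularGrid, seed: int = 0,
                        mean_diffusivity: float = 7e-10,
                        anisotropy: float = 3.0) -> TensorField:
    """Random smooth positive-definite diffusion-tensor volume for testing.

    Eigenvalues are drawn around ``mean_diffusivity`` with the largest about
    ``anisotropy`` times the smallest; orientations are random rotations.
    """
    rng = np.random.default_rng(seed)
    shape = grid.shape
    lam = mean_diffusivity * np.stack([
        np.full(shape, anisotropy),
        1.0 + rng.random(shape),
        1.0 + rng.random(shape),
    ], axis=-1)
    # random rotation per node via QR of gaussian matrices
    g = rng.standard_normal(shape + (3, 3))
    q, rr = np.linalg.qr(g)
    q = q * np.sign(np.einsum("...ii->...i", rr))[..., None, :]
    t = np.einsum("...ij,...j,...kj->...ik", q, lam, q)
    return TensorField.from_tensors(grid, t)


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

@dataclass
class SensorMontage:
    positions: np.ndarray  # (n, 3) metres
    labels: List[str]
    radius: float
    centre: Tuple[float, float, float]


def _icosahedron() -> Tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ])
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    verts = list(map(tuple, verts))
    index = {v: i for i, v in enumerate(verts)}
    cache = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
            m = tuple(m / np.linalg.norm(m))
            if m not in index:
                index[m] = len(verts)
                verts.append(m)
            cache[key] = index[m]
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.array(verts), np.array(new_faces)


def geodesic_sensors(n_sensors: int, radius: float,
                     centre=(0.0, 0.0, 0.0)) -> SensorMontage:
    """Quasi-uniform sensors from subdivided-icosahedron vertices.

    The subdivision level with vertex count (12, 42, 162, 642, ...) nearest
    to ``n_sensors`` is used.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    verts, faces = _icosahedron()
    best = verts
    for _ in range(5):
        if abs(len(best) - n_sensors) == 0:
            break
        verts, faces = _subdivide(verts, faces)
        if abs(len(verts) - n_sensors) < abs(len(best) - n_sensors):
            best = verts
        else:
            break
    pos = best * radius + np.asarray(centre, dtype=float)
    labels = [f"E{i + 1}" for i in range(len(best))]
    return SensorMontage(pos, labels, radius, tuple(float(c) for c in centre))


def sample_sensors(u: ScalarVolume, montage: SensorMontage,
                   average_reference: bool = False) -> np.ndarray:
    """Trilinear interpolation of a potential volume at the sensor positions."""
    grid = u.grid
    idx = np.array([grid.coord_to_index(p) for p in montage.positions]).T
    if np.any(idx < 0) or np.any(idx > (np.array(grid.shape) - 1)[:, None]):
        raise ValueError("sensor position outside the grid")
    vals = map_coordinates(u.values, idx, order=1, mode="nearest")
    if average_reference:
        vals = vals - vals.mean()
    return vals
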