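"""Regular grids, scalar/tensor volumes and model/solver specifications.

The computational domain is a node-centered uniform rectangular grid.
Linearization order is fixed package-wide: x fastest-varying, i.e. the flat
index of node ``(i, j, k)`` is ``i + n_x*(j + n_y*k)`` (Fortran ravel of
arrays indexed ``[i, j, k]``).  The 19-diagonal operator layout and the
sine-transform preconditioner both rely on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RegularGrid",
    "ScalarVolume",
    "TensorField",
    "SphereModelSpec",
    "SolverConfig",
    "make_cube_grid",
]

#: default conductivity of the air cladding of the fictitious box (S/m)
AIR_CONDUCTIVITY = 1e-10

SCHEMES = ("A", "B", "C", "D", "E")
PRECONDITIONERS = ("none", "jacobi", "fourier", "fourier_jacobi")


@dataclass(frozen=True)
class RegularGrid:
    """Node-centered uniform 3D grid.

    Parameters
    ----------
    n_x, n_y, n_z
        Number of nodes per axis (``>= 3``).
    h_x, h_y, h_z
        Grid spacings in metres (``> 0``).
    origin
        Physical coordinate of node ``(0, 0, 0)`` in metres.
    """

    n_x: int
    n_y: int
    n_z: int
    h_x: float
    h_y: float
    h_z: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if min(self.n_x, self.n_y, self.n_z) < 3:
            raise ValueError("grid needs at least 3 nodes per axis")
        if min(self.h_x, self.h_y, self.h_z) <= 0.0:
            raise ValueError("grid spacings must be positive")
        object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))
        if len(self.origin) != 3:
            raise ValueError("origin must be a 3-vector")

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def n_nodes(self) -> int:
        return self.n_x * self.n_y * self.n_z

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.h_x, self.h_y, self.h_z])

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        h = self.spacing[axis]
        return self.origin[axis] + h * np.arange(n)

    def meshgrid(self):
        """Return ``(x, y, z)`` coordinate volumes of shape ``self.shape``."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )

    def index_to_coord(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * self.spacing

    def coord_to_index(self, coord) -> np.ndarray:
        """Continuous (fractional) index of a physical coordinate."""
        return (np.asarray(coord, dtype=float) - np.asarray(self.origin)) / self.spacing

    def nearest_node(self, coord) -> tuple:
        idx = np.rint(self.coord_to_index(coord)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError(f"coordinate {coord} outside the grid")
        return tuple(int(v) for v in idx)

    def ravel_index(self, i: int, j: int, k: int) -> int:
        return i + self.n_x * (j + self.n_y * k)

    def interior_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[1:-1, 1:-1, 1:-1] = True
        return m

    @property
    def cell_volume(self) -> float:
        return self.h_x * self.h_y * self.h_z


def make_cube_grid(edge_length: float, n: int) -> RegularGrid:
    """Cubic grid of ``n`` nodes per axis spanning ``[-L/2, L/2]^3``.

    The fictitious computational box is centred at the coordinate origin and
    the spacing is ``edge_length / (n - 1)``.
    """
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    if n < 3:
        raise ValueError("n must be at least 3")
    h = edge_length / (n - 1)
    half = edge_length / 2.0
    return RegularGrid(n, n, n, h, h, h, origin=(-half, -half, -half))


@dataclass
class ScalarVolume:
    """One real value per grid node."""

    grid: RegularGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: RegularGrid) -> "ScalarVolume":
        return cls(grid, np.zeros(grid.shape))

    def ravel(self) -> np.ndarray:
        """Flat view in the package linearization order (x fastest)."""
        return self.values.ravel(order="F")

    @classmethod
    def from_flat(cls, grid: RegularGrid, flat: np.ndarray) -> "ScalarVolume":
        return cls(grid, np.asarray(flat).reshape(grid.shape, order="F"))


@dataclass
class TensorField:
    """Per-node symmetric 3x3 conductivity tensor, six component volumes (S/m)."""

    grid: RegularGrid
    sxx: np.ndarray
    syy: np.ndarray
    szz: np.ndarray
    sxy: np.ndarray
    sxz: np.ndarray
    syz: np.ndarray

    def __post_init__(self):
        for name in ("sxx", "syy", "szz", "sxy", "sxz", "syz"):
            arr = np.ascontiguousarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"component {name} has shape {arr.shape}, "
                                 f"expected {self.grid.shape}")
            setattr(self, name, arr)

    # -- constructors ---------------------------------------------------

    @classmethod
    def isotropic(cls, grid: RegularGrid, value) -> "TensorField":
        v = np.broadcast_to(np.asarray(value, dtype=float), grid.shape).copy()
        z = np.zeros(grid.shape)
        return cls(grid, v, v.copy(), v.copy(), z, z.copy(), z.copy())

    @classmethod
    def from_tensors(cls, grid: RegularGrid, tensors: np.ndarray) -> "TensorField":
        """Build from an ``(*grid.shape, 3, 3)`` array of symmetric tensors."""
        t = np.asarray(tensors, dtype=float)
        if t.shape != grid.shape + (3, 3):
            raise ValueError("tensors must have shape grid.shape + (3, 3)")
        return cls(grid, t[..., 0, 0], t[..., 1, 1], t[..., 2, 2],
                   t[..., 0, 1], t[..., 0, 2], t[..., 1, 2])

    # -- views ----------------------------------------------------------

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def as_tensors(self) -> np.ndarray:
        """``(*grid.shape, 3, 3)`` symmetric tensor array."""
        t = np.empty(self.grid.shape + (3, 3))
        t[..., 0, 0] = self.sxx
        t[..., 1, 1] = self.syy
        t[..., 2, 2] = self.szz
        t[..., 0, 1] = t[..., 1, 0] = self.sxy
        t[..., 0, 2] = t[..., 2, 0] = self.sxz
        t[..., 1, 2] = t[..., 2, 1] = self.syz
        return t

    def tensor_at(self, i: int, j: int, k: int) -> np.ndarray:
        return np.array([
            [self.sxx[i, j, k], self.sxy[i, j, k], self.sxz[i, j, k]],
            [self.sxy[i, j, k], self.syy[i, j, k], self.syz[i, j, k]],
            [self.sxz[i, j, k], self.syz[i, j, k], self.szz[i, j, k]],
        ])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.as_tensors()).min())

    def assert_positive_definite(self) -> None:
        """Raise if any node tensor has a non-positive eigenvalue."""
        eig = np.linalg.eigvalsh(self.as_tensors())
        if not np.all(eig[..., 0] > 0.0):
            bad = np.argwhere(eig[..., 0] <= 0.0)[0][:3]
            raise ValueError(
                f"conductivity tensor not positive definite at node {tuple(bad)}"
            )

    def copy(self) -> "TensorField":
        return TensorField(self.grid, self.sxx.copy(), self.syy.copy(),
                           self.szz.copy(), self.sxy.copy(), self.sxz.copy(),
                           self.syz.copy())


@dataclass(frozen=True)
class SphereModelSpec:
    """4-shell spherical head model with an anisotropic skull layer.

    Defaults are the printed model: shell outer radii 0.084 m (scalp),
    0.065 m (skull), 0.05 m (CSF), 0.03 m (brain); conductivities 0.44,
    0.018, 1.79 and 0.250 S/m.  The skull layer is anisotropic with
    tangential conduction ``skull_tangential_ratio`` times the radial one.
    By default the reference skull value 0.018 S/m is the *radial*
    conductivity and the tangential one is ``ratio`` times larger
    (tangentially dominant cranial-plate conduction).  With
    ``reference_is_radial=False`` the reference is the tangential value and
    the radial one is ``ratio`` times smaller instead.
    """

    shell_radii: tuple = (0.084, 0.065, 0.05, 0.03)
    shell_conductivities: tuple = (0.44, 0.018, 1.79, 0.250)
    skull_reference_conductivity: float = 0.018
    skull_tangential_ratio: float = 10.0
    air_conductivity: float = AIR_CONDUCTIVITY
    centre: tuple = (0.0, 0.0, 0.0)
    reference_is_radial: bool = True

    def __post_init__(self):
        radii = tuple(float(r) for r in self.shell_radii)
        if len(radii) != 4 or any(a <= b for a, b in zip(radii, radii[1:])):
            raise ValueError("shell_radii must be four strictly decreasing values")
        if any(c <= 0 for c in self.shell_conductivities):
            raise ValueError("conductivities must be positive")
        if self.skull_reference_conductivity <= 0 or self.air_conductivity <= 0:
            raise ValueError("conductivities must be positive")
        if self.skull_tangential_ratio < 1.0:
            raise ValueError("skull_tangential_ratio must be >= 1")
        object.__setattr__(self, "shell_radii", radii)
        object.__setattr__(self, "shell_conductivities",
                           tuple(float(c) for c in self.shell_conductivities))
        object.__setattr__(self, "centre", tuple(float(c) for c in self.centre))

    @property
    def skull_sigma_radial(self) -> float:
        if self.reference_is_radial:
            return self.skull_reference_conductivity
        return self.skull_reference_conductivity / self.skull_tangential_ratio

    @property
    def skull_sigma_tangential(self) -> float:
        if self.reference_is_radial:
            return self.skull_reference_conductivity * self.skull_tangential_ratio
        return self.skull_reference_conductivity


@dataclass
class SolverConfig:
    """Scheme / preconditioner / stopping configuration for one solve."""

    scheme: str = "A"
    preconditioner: str = "fourier_jacobi"
    tolerance: float = 1e-5
    max_iterations: int = 1000
    fourier_coefficient: object = "auto"   # "auto" or a positive float
    fj_composition: str = "sequential"     # "sequential" | "symmetric"
    b_split_halved: bool = False           # use (sigma +- |sigma|)/2 in scheme B
    fallback_to_bicgstab: bool = False

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}, expected one of {SCHEMES}")
        if self.preconditioner not in PRECONDITIONERS:
            raise ValueError(f"unknown preconditioner {self.preconditioner!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.fj_composition not in ("symmetric", "sequential"):
            raise ValueError("fj_composition must be 'symmetric' or 'sequential'")
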