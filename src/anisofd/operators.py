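"""19-point-stencil assembly of the anisotropic diffusion operator.

The operator discretizes ``div(sigma grad u)`` on a uniform node-centered
grid.  Second derivatives use the conservative three-point finite-volume
scheme with arithmetic face averages

    d/dx (sxx du/dx) ~ [s_{0+}(u_+ - u_0) - s_{0-}(u_0 - u_-)] / h^2,
    s_{km} = (s_k + s_m) / 2,

and the six mixed-derivative terms use one of five second-order schemes
(tags ``A``..``E``), expressed on the 9-node plane stencil

        7   3   6            labels in the (a, b) plane:
        4   0   2            2=+a, 4=-a, 3=+b, 1=-b,
        8   1   5            6=(+a,+b), 5=(+a,-b), 7=(-a,+b), 8=(-a,-b)

Scheme A averages the four one-sided conservative differences, B is the
sign-split (upwind-type) variant satisfying a discrete maximum principle,
C replaces node coefficients by two-node edge averages, D is the classical
four-corner formula with the flux coefficient taken at the +-a neighbours,
and E uses the same face-averaged coefficients as the second-derivative
scheme for both diagonal and off-diagonal terms (which is what makes it
robust on piecewise-constant anisotropic media).

The outer boundary of the fictitious box carries homogeneous Dirichlet
rows (identity); the physical no-flux condition is realized implicitly by
the low-conductivity air cladding.  The sign convention makes the
homogeneous isotropic operator the *negative*-definite 7-point Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .grid import RegularGrid, ScalarVolume, TensorField, SCHEMES

__all__ = [
    "DiscreteOperator",
    "SourceField",
    "assemble_operator",
    "stencil_coefficients",
    "apply_operator",
    "scheme_B_split",
    "build_dipole_rhs",
]

Offset = Tuple[int, int, int]

# 9-node plane stencil: label -> (shift along axis a, shift along axis b)
_PLANE_OFFSETS: Dict[str, Tuple[int, int]] = {
    "0": (0, 0),
    "2": (1, 0), "4": (-1, 0), "3": (0, 1), "1": (0, -1),
    "6": (1, 1), "5": (1, -1), "7": (-1, 1), "8": (-1, -1),
}

# label remapping under the a <-> b role swap (transposed mixed term)
_SWAP = {"0": "0", "2": "3", "3": "2", "4": "1", "1": "4",
         "6": "6", "5": "7", "7": "5", "8": "8"}

# Each mixed-derivative scheme as a list of (sign, coefficient label,
# (u_plus label, u_minus label)) contributions; the whole sum is scaled by
# 1/(4 h_a h_b).  Coefficient labels: "k" = sigma at node k, "km" = average
# of nodes k and m, "+k"/"-k" = sign-split value at node k.
_MIXED_TERMS: Dict[str, List[Tuple[int, str, Tuple[str, str]]]] = {
    "A": [
        (+1, "2", ("6", "2")), (-1, "0", ("3", "0")),
        (+1, "0", ("0", "1")), (-1, "4", ("4", "8")),
        (+1, "2", ("2", "5")), (-1, "0", ("0", "1")),
        (+1, "0", ("3", "0")), (-1, "4", ("7", "4")),
    ],
    "B": [
        (+1, "+2", ("6", "2")), (-1, "+0", ("3", "0")),
        (+1, "+0", ("0", "1")), (-1, "+4", ("4", "8")),
        (+1, "-2", ("2", "5")), (-1, "-0", ("0", "1")),
        (+1, "-0", ("3", "0")), (-1, "-4", ("7", "4")),
    ],
    "C": [
        (+1, "26", ("6", "2")), (-1, "03", ("3", "0")),
        (+1, "01", ("0", "1")), (-1, "48", ("4", "8")),
        (+1, "25", ("2", "5")), (-1, "01", ("0", "1")),
        (+1, "03", ("3", "0")), (-1, "47", ("7", "4")),
    ],
    "D": [
        (+1, "2", ("6", "5")), (-1, "4", ("7", "8")),
    ],
    "E": [
        (+1, "02", ("6", "5")), (+1, "02", ("3", "1")),
        (-1, "04", ("3", "1")), (-1, "04", ("7", "8")),
    ],
}


def scheme_B_split(sigma, halved: bool = False):
    """Sign splitting ``sigma+- = sigma +- |sigma|`` used by scheme B.

    Returns ``(sigma_plus, sigma_minus)`` with ``sigma_plus >= 0 >=
    sigma_minus`` and ``sigma_plus + sigma_minus = 2 sigma`` (or ``sigma``
    when ``halved`` requests the conventional 1/2-factor variant).
    """
    s = np.asarray(sigma, dtype=float)
    a = np.abs(s)
    plus, minus = s + a, s - a
    if halved:
        plus, minus = plus / 2.0, minus / 2.0
    if np.isscalar(sigma) or np.ndim(sigma) == 0:
        return float(plus), float(minus)
    return plus, minus


def _shift(arr: np.ndarray, off: Offset) -> np.ndarray:
    """``result[n] = arr[n + off]`` (wrapped values only reach boundary rows,
    which are overwritten by Dirichlet identities)."""
    return np.roll(arr, (-off[0], -off[1], -off[2]), axis=(0, 1, 2))


def _mixed_plane_coeffs(comp: np.ndarray, axis_a: int, axis_b: int,
                        scheme: str, halved_split: bool,
                        transposed: bool) -> Dict[Offset, np.ndarray]:
    """Coefficient arrays of one mixed term ``d/da (s_ab d/db u)`` (or its
    transpose) on the full grid, *excluding* the 1/(4 h_a h_b) factor."""

    def label_to_offset(lab: str) -> Offset:
        if transposed:
            lab = _SWAP[lab]
        da, db = _PLANE_OFFSETS[lab]
        off = [0, 0, 0]
        off[axis_a], off[axis_b] = da, db
        return tuple(off)

    cache: Dict[str, np.ndarray] = {}

    def coeff(lab: str) -> np.ndarray:
        if lab not in cache:
            if lab[0] in "+-":
                plus, minus = scheme_B_split(_shift(comp, label_to_offset(lab[1:])),
                                             halved=halved_split)
                cache["+" + lab[1:]] = plus
                cache["-" + lab[1:]] = minus
            elif len(lab) == 2:
                cache[lab] = 0.5 * (_shift(comp, label_to_offset(lab[0]))
                                    + _shift(comp, label_to_offset(lab[1])))
            else:
                cache[lab] = _shift(comp, label_to_offset(lab))
        return cache[lab]

    out: Dict[Offset, np.ndarray] = {}
    for sign, clab, (up, um) in _MIXED_TERMS[scheme]:
        c = sign * coeff(clab)
        for lab, s in ((up, 1.0), (um, -1.0)):
            off = label_to_offset(lab)
            if off in out:
                out[off] = out[off] + s * c
            else:
                out[off] = s * c
    return out


def stencil_coefficients(sigma: TensorField, scheme: str = "A",
                         halved_split: bool = False) -> Dict[Offset, np.ndarray]:
    """Full-grid stencil coefficient arrays, one per 19-point offset.

    ``coeffs[off][i, j, k]`` multiplies ``u[(i, j, k) + off]`` in the row of
    node ``(i, j, k)``; only interior rows of these arrays are meaningful.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}, expected one of {SCHEMES}")
    grid = sigma.grid
    h = grid.spacing
    coeffs: Dict[Offset, np.ndarray] = {}

    def add(off: Offset, arr) -> None:
        if off in coeffs:
            coeffs[off] = coeffs[off] + arr
        else:
            coeffs[off] = np.array(arr, dtype=float)

    # second derivatives: conservative face-averaged three-point scheme
    diag_comps = (sigma.sxx, sigma.syy, sigma.szz)
    for ax in range(3):
        comp = diag_comps[ax]
        e = [0, 0, 0]
        e[ax] = 1
        e = tuple(e)
        em = tuple(-v for v in e)
        s_plus = 0.5 * (comp + _shift(comp, e))
        s_minus = 0.5 * (comp + _shift(comp, em))
        inv_h2 = 1.0 / h[ax] ** 2
        add(e, s_plus * inv_h2)
        add(em, s_minus * inv_h2)
        add((0, 0, 0), -(s_plus + s_minus) * inv_h2)

    # mixed derivatives: both orientations per plane
    planes = ((0, 1, sigma.sxy), (0, 2, sigma.sxz), (1, 2, sigma.syz))
    for axis_a, axis_b, comp in planes:
        g = 1.0 / (4.0 * h[axis_a] * h[axis_b])
        for transposed in (False, True):
            part = _mixed_plane_coeffs(comp, axis_a, axis_b, scheme,
                                       halved_split, transposed)
            for off, arr in part.items():
                add(off, g * arr)

    return coeffs


@dataclass
class DiscreteOperator:
    """The assembled 19-diagonal system matrix with its stencil data."""

    grid: RegularGrid
    scheme: str
    coefficients: Dict[Offset, np.ndarray]
    _matrix: Optional[sp.csr_matrix] = field(default=None, repr=False)
    _matrix_T: Optional[sp.csr_matrix] = field(default=None, repr=False)

    @property
    def shape(self) -> Tuple[int, int]:
        n = self.grid.n_nodes
        return (n, n)

    @property
    def matrix(self) -> sp.csr_matrix:
        if self._matrix is None:
            self._matrix = self._assemble_sparse()
        return self._matrix

    @property
    def matrix_T(self) -> sp.csr_matrix:
        if self._matrix_T is None:
            self._matrix_T = self.matrix.T.tocsr()
        return self._matrix_T

    def _assemble_sparse(self) -> sp.csr_matrix:
        grid = self.grid
        nx, ny, nz = grid.shape
        n = grid.n_nodes
        interior = grid.interior_mask()
        flat_interior = np.flatnonzero(interior.ravel(order="F")).astype(np.int64)

        rows, cols, vals = [], [], []
        for (dx, dy, dz), arr in self.coefficients.items():
            flat_off = dx + nx * (dy + ny * dz)
            v = arr.ravel(order="F")[flat_interior]
            nzm = v != 0.0
            rows.append(flat_interior[nzm])
            cols.append(flat_interior[nzm] + flat_off)
            vals.append(v[nzm])

        # homogeneous Dirichlet identity rows on the six box faces
        boundary = np.flatnonzero(~interior.ravel(order="F")).astype(np.int64)
        rows.append(boundary)
        cols.append(boundary)
        vals.append(np.ones(boundary.size))

        A = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        A.sum_duplicates()
        return A

    def apply(self, u) -> np.ndarray:
        """Matrix-free application to a volume or flat vector (x fastest)."""
        if isinstance(u, ScalarVolume):
            vol = u.values
        else:
            flat = np.asarray(u, dtype=float)
            if flat.shape != (self.grid.n_nodes,):
                raise ValueError("operand shape does not match the grid")
            vol = flat.reshape(self.grid.shape, order="F")
        if vol.shape != self.grid.shape:
            raise ValueError("operand shape does not match the grid")

        out = np.zeros_like(vol)
        core = (slice(1, -1),) * 3
        for off, arr in self.coefficients.items():
            out[core] += arr[core] * _shift(vol, off)[core]
        # Dirichlet identity rows
        for ax in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = 0
            hi[ax] = -1
            out[tuple(lo)] = vol[tuple(lo)]
            out[tuple(hi)] = vol[tuple(hi)]
        if isinstance(u, ScalarVolume):
            return out
        return out.ravel(order="F")

    def diagonal(self) -> np.ndarray:
        """Flat main diagonal (interior stencil centres, boundary ones)."""
        d = self.coefficients[(0, 0, 0)].copy()
        mask = ~self.grid.interior_mask()
        d[mask] = 1.0
        return d.ravel(order="F")

    def export_coo_text(self, path) -> None:
        """Write the matrix as 'row col value' triplets (0-based)."""
        A = self.matrix.tocoo()
        data = np.column_stack([A.row, A.col, A.data])
        np.savetxt(path, data, fmt=["%d", "%d", "%.17g"],
                   header=f"{A.shape[0]} {A.shape[1]} {A.nnz}")


def assemble_operator(sigma: TensorField, grid: Optional[RegularGrid] = None,
                      scheme: str = "A", halved_split: bool = False,
                      check_positive_definite: bool = False) -> DiscreteOperator:
    """Assemble the 19-diagonal operator for a conductivity tensor field."""
    if grid is not None and grid is not sigma.grid and grid != sigma.grid:
        raise ValueError("grid does not match the tensor field's grid")
    if check_positive_definite:
        sigma.assert_positive_definite()
    coeffs = stencil_coefficients(sigma, scheme, halved_split=halved_split)
    return DiscreteOperator(sigma.grid, scheme, coeffs)


def apply_operator(A: DiscreteOperator, u: ScalarVolume) -> ScalarVolume:
    """Matrix-free ``A @ u`` returning a volume."""
    return ScalarVolume(A.grid, A.apply(u))


@dataclass
class SourceField:
    """Right-hand side volume with bookkeeping of injected monopoles."""

    volume: ScalarVolume
    monopoles: list  # list of ((i, j, k), current)

    @property
    def grid(self) -> RegularGrid:
        return self.volume.grid

    def ravel(self) -> np.ndarray:
        return self.volume.ravel()

    def total_current(self) -> float:
        """Integral of the source density over the volume (A)."""
        return float(self.volume.values.sum() * self.grid.cell_volume)


def build_dipole_rhs(grid: RegularGrid, position, orientation,
                     separation: float, current: float = 1.0) -> SourceField:
    """Source-sink monopole pair deposited on the two nearest grid nodes.

    The source and sink densities are ``+current/h^3`` and ``-current/h^3``
    so that the discrete volume integral of the field is exactly zero.
    """
    pos = np.asarray(position, dtype=float)
    direction = np.asarray(orientation, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0.0:
        raise ValueError("orientation must be a nonzero vector")
    direction = direction / nrm

    p_plus = pos + direction * separation / 2.0
    p_minus = pos - direction * separation / 2.0
    node_plus = grid.nearest_node(p_plus)
    node_minus = grid.nearest_node(p_minus)
    if node_plus == node_minus:
        raise ValueError(
            "dipole endpoints snap to the same grid node (degenerate dipole)"
        )

    f = np.zeros(grid.shape)
    density = current / grid.cell_volume
    f[node_plus] += density
    f[node_minus] -= density
    return SourceField(ScalarVolume(grid, f),
                       [(node_plus, current), (node_minus, -current)])
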