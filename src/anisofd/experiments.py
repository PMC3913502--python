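"""Reproducible performance studies: order of accuracy, iteration-count
grids over scheme x preconditioner x resolution, skull-anisotropy sweep and
an extreme-heterogeneity stress test.

All studies are deterministic: the solve path contains no randomness and
fixtures are fully specified by their parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import (RegularGrid, SolverConfig, SphereModelSpec,
                   make_cube_grid)
from .models import (build_smooth_probe, build_sphere_model, default_clip_boxes,
                     insert_clip)
from .operators import assemble_operator, build_dipole_rhs, SourceField
from .preconditioners import make_preconditioner
from .solvers import SolveResult, bicg_solve

__all__ = [
    "ExperimentRecord",
    "solve_probe",
    "solve_sphere",
    "convergence_order_study",
    "iteration_grid",
    "anisotropy_sweep",
    "heterogeneity_stress",
]

# Box edge (m) of the fictitious domain for the spherical head model.
# The printed value 0.1 m cannot contain a 0.084 m scalp radius (diameter
# 0.168 m); 0.2 m is the smallest round edge leaving an air margin.
HEAD_BOX_EDGE = 0.2
#: mid-outer-shell radius used for equatorial dipole placement (m)
MID_SCALP_RADIUS = 0.5 * (0.084 + 0.065)
#: default dipole pole separation (m) and current (A)
DIPOLE_SEPARATION = 0.01
DIPOLE_CURRENT = 1e-6


@dataclass
class ExperimentRecord:
    model: str
    scheme: str
    preconditioner: str
    n: int
    tolerance: float
    iterations: int
    converged: bool
    final_residual: float
    rel_l2_error: Optional[float] = None
    max_error: Optional[float] = None
    breakdown: Optional[str] = None

    def as_dict(self) -> dict:
        return asdict(self)


def _records_frame(records: Iterable[ExperimentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


# ---------------------------------------------------------------------------
# single-solve helpers
# ---------------------------------------------------------------------------

def solve_probe(n: int, scheme: str = "A", preconditioner: str = "fourier_jacobi",
                tolerance: float = 1e-5, a: float = 1.0,
                max_iterations: int = 2000) -> Tuple[SolveResult, float, float]:
    """Solve the probe problem; returns (result, rel L2 error, max error)."""
    grid = make_cube_grid(2.0 * a, n)
    probe = build_smooth_probe(grid, a)
    A = assemble_operator(probe.sigma, scheme=scheme)
    cfg = SolverConfig(scheme=scheme, preconditioner=preconditioner,
                       tolerance=tolerance, max_iterations=max_iterations)
    P = make_preconditioner(preconditioner, A=A, grid=grid, sigma=probe.sigma)
    result = bicg_solve(A, probe.system_rhs(), P, cfg)
    exact = probe.potential.values
    diff = result.potential.values - exact
    rel_l2 = float(np.linalg.norm(diff) / np.linalg.norm(exact))
    return result, rel_l2, float(np.abs(diff).max())


def _sphere_operator(n: int, scheme: str, spec: Optional[SphereModelSpec] = None,
                     with_clip: bool = False, clip_conductivity: float = 2.5e6):
    spec = spec if spec is not None else SphereModelSpec()
    grid = make_cube_grid(HEAD_BOX_EDGE, n)
    sigma = build_sphere_model(spec, grid)
    if with_clip:
        # clip centred in the skull shell above the vertex
        clip_centre = (0.0, 0.0, 0.5 * (0.065 + 0.05))
        sigma = insert_clip(sigma, None, None, conductivity=clip_conductivity,
                            boxes=default_clip_boxes(clip_centre))
    A = assemble_operator(sigma, scheme=scheme)
    return grid, sigma, A


def equatorial_dipole(grid: RegularGrid, radius: float = MID_SCALP_RADIUS,
                      axis: int = 0, orientation_axis: int = 1,
                      sign: float = 1.0) -> SourceField:
    pos = np.zeros(3)
    pos[axis] = sign * radius
    orient = np.zeros(3)
    orient[orientation_axis] = 1.0
    return build_dipole_rhs(grid, pos, orient, DIPOLE_SEPARATION, DIPOLE_CURRENT)


def solve_sphere(n: int, scheme: str = "E", preconditioner: str = "fourier_jacobi",
                 tolerance: float = 1e-5, spec: Optional[SphereModelSpec] = None,
                 with_clip: bool = False, max_iterations: int = 2000,
                 rhs: Optional[SourceField] = None) -> SolveResult:
    grid, sigma, A = _sphere_operator(n, scheme, spec, with_clip)
    if rhs is None:
        rhs = equatorial_dipole(grid)
    cfg = SolverConfig(scheme=scheme, preconditioner=preconditioner,
                       tolerance=tolerance, max_iterations=max_iterations)
    P = make_preconditioner(preconditioner, A=A, grid=grid, sigma=sigma)
    return bicg_solve(A, rhs, P, cfg)


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def convergence_order_study(scheme: str = "A", grids: Sequence[int] = (16, 32, 64),
                            tolerance: float = 1e-10, a: float = 1.0) -> pd.DataFrame:
    """Observed order of accuracy of the solved probe versus the exact field.

    Requires at least three grid sizes nested by a factor of two.  The solve
    tolerance is kept well below the discretization error so that the error
    ratio reflects the truncation order.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise ValueError("need at least two grid sizes")
    for n0, n1 in zip(grids, grids[1:]):
        if n1 != 2 * n0:
            raise ValueError("grid sizes must be nested by a factor of 2")

    rows = []
    prev_err = None
    for n in grids:
        result, rel_l2, max_err = solve_probe(n, scheme=scheme,
                                              preconditioner="fourier_jacobi",
                                              tolerance=tolerance, a=a)
        if not result.converged:
            raise RuntimeError(
                f"order study aborted: no convergence at n={n} "
                f"(residual {result.final_residual:.3e})"
            )
        order = np.log2(prev_err / rel_l2) if prev_err is not None else np.nan
        rows.append({"scheme": scheme, "n": n, "iterations": result.iterations,
                     "rel_l2_error": rel_l2, "max_error": max_err,
                     "observed_order": order})
        prev_err = rel_l2
    return pd.DataFrame(rows)


def iteration_grid(model: str = "probe",
                   schemes: Sequence[str] = ("A", "B", "C", "D", "E"),
                   preconditioners: Sequence[str] = ("fourier_jacobi",),
                   grids: Sequence[int] = (32, 64),
                   tolerance: float = 1e-5,
                   max_iterations: int = 2000) -> pd.DataFrame:
    """One solve per (scheme, preconditioner, resolution) combination."""
    records: List[ExperimentRecord] = []
    for n in grids:
        for scheme in schemes:
            if model == "probe":
                grid = make_cube_grid(2.0, n)
                probe = build_smooth_probe(grid)
                sigma, rhs = probe.sigma, probe.system_rhs()
            elif model == "sphere":
                grid, sigma, _ = _sphere_operator(n, scheme)
                rhs = equatorial_dipole(grid)
            else:
                raise ValueError(f"unknown model {model!r}")
            A = assemble_operator(sigma, scheme=scheme)
            for prec in preconditioners:
                cfg = SolverConfig(scheme=scheme, preconditioner=prec,
                                   tolerance=tolerance,
                                   max_iterations=max_iterations)
                P = make_preconditioner(prec, A=A, grid=grid, sigma=sigma)
                res = bicg_solve(A, rhs, P, cfg)
                rec = ExperimentRecord(model, scheme, prec, n, tolerance,
                                       res.iterations, res.converged,
                                       res.final_residual,
                                       breakdown=res.breakdown)
                if model == "probe":
                    exact = probe.potential.values
                    diff = res.potential.values - exact
                    rec.rel_l2_error = float(np.linalg.norm(diff)
                                             / np.linalg.norm(exact))
                    rec.max_error = float(np.abs(diff).max())
                records.append(rec)
            del A
    return _records_frame(records)


def anisotropy_sweep(ratios: Sequence[float] = (1.0, 10.0, 50.0), n: int = 64,
                     scheme: str = "E", tolerance: float = 1e-5,
                     max_iterations: int = 2000) -> pd.DataFrame:
    """FJ-BiCG iteration counts versus skull tangential:radial ratio.

    Counts are averaged over six equatorial/polar dipoles (two per axis at
    mid-outer-shell radius, tangentially oriented).
    """
    rows = []
    for ratio in ratios:
        if ratio < 1.0:
            raise ValueError("ratios must be >= 1")
        spec = SphereModelSpec(skull_tangential_ratio=ratio)
        grid, sigma, A = _sphere_operator(n, scheme, spec)
        P = make_preconditioner("fourier_jacobi", A=A, grid=grid, sigma=sigma)
        cfg = SolverConfig(scheme=scheme, preconditioner="fourier_jacobi",
                           tolerance=tolerance, max_iterations=max_iterations)
        counts = []
        all_converged = True
        for axis in range(3):
            for sign in (1.0, -1.0):
                rhs = equatorial_dipole(grid, axis=axis,
                                        orientation_axis=(axis + 1) % 3,
                                        sign=sign)
                res = bicg_solve(A, rhs, P, cfg)
                counts.append(res.iterations)
                all_converged &= res.converged
        rows.append({"ratio": ratio, "n": n, "scheme": scheme,
                     "mean_iterations": float(np.mean(counts)),
                     "max_iterations": int(np.max(counts)),
                     "all_converged": all_converged})
        del A, P
    return pd.DataFrame(rows)


def heterogeneity_stress(contrast_target: float = 1e16, n: int = 64,
                         schemes: Sequence[str] = ("A", "E"),
                         tolerance: float = 1e-5,
                         max_iterations: int = 2000) -> pd.DataFrame:
    """Sphere + titanium clip + air model at extreme conductivity contrast."""
    spec = SphereModelSpec()
    records: List[ExperimentRecord] = []
    for scheme in schemes:
        grid, sigma, A = _sphere_operator(n, scheme, spec, with_clip=True)
        contrast = float(sigma.sxx.max() / sigma.sxx.min())
        if contrast < contrast_target:
            raise ValueError(
                f"model contrast {contrast:.2e} below target {contrast_target:.2e}"
            )
        rhs = equatorial_dipole(grid)
        P = make_preconditioner("fourier_jacobi", A=A, grid=grid, sigma=sigma)
        cfg = SolverConfig(scheme=scheme, preconditioner="fourier_jacobi",
                           tolerance=tolerance, max_iterations=max_iterations)
        res = bicg_solve(A, rhs, P, cfg)
        records.append(ExperimentRecord("sphere+clip", scheme, "fourier_jacobi",
                                        n, tolerance, res.iterations,
                                        res.converged, res.final_residual,
                                        breakdown=res.breakdown))
        del A, P
    df = _records_frame(records)
    df["contrast"] = contrast
    return df
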