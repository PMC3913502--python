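"""Preconditioned BiCG / BiCGStab drivers with true-residual stopping.

The recurrence residual is monitored every iteration; once it reaches the
tolerance the true residual ``||f - A u|| / ||f||`` is recomputed and only
that value can declare convergence.  The final reported residual is always
the recomputed true residual, never the recurrence one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .grid import RegularGrid, ScalarVolume, SolverConfig
from .operators import DiscreteOperator, SourceField
from .preconditioners import IdentityPreconditioner, Preconditioner

__all__ = ["SolveResult", "bicg_solve", "bicgstab_solve"]

# relative scale below which a rho/alpha denominator counts as breakdown
_BREAKDOWN_EPS = 1e-30


@dataclass
class SolveResult:
    potential: ScalarVolume
    iterations: int
    residual_history: List[float]
    converged: bool
    final_residual: float
    breakdown: Optional[str] = None
    method: str = "bicg"

    def __post_init__(self):
        assert self.iterations == len(self.residual_history)


def _as_rhs_vector(f) -> np.ndarray:
    if isinstance(f, SourceField):
        return f.ravel()
    if isinstance(f, ScalarVolume):
        return f.ravel()
    return np.asarray(f, dtype=float).ravel()


class _System:
    """Matvec plumbing shared by the two drivers.

    Dirichlet boundary rows are identity, so the boundary values are
    eliminated up front (``u_boundary = f_boundary``) and the Krylov
    iteration runs in the subspace of vectors vanishing on the boundary.
    That subspace is invariant under ``A``; its adjoint is ``Aᵀ`` followed
    by zeroing the boundary entries.  Without the restriction the shadow
    BiCG sequence picks up boundary components on which the residual
    polynomial is unbounded and overflows.
    """

    def __init__(self, A: DiscreteOperator, need_transpose: bool):
        self._A = A.matrix
        self._AT = A.matrix_T if need_transpose else None
        self.grid = A.grid
        self.boundary = ~A.grid.interior_mask().ravel(order="F")

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self._A @ x

    def rmatvec(self, x: np.ndarray) -> np.ndarray:
        y = self._AT @ x
        y[self.boundary] = 0.0
        return y

    def eliminate_boundary(self, b: np.ndarray):
        """Initial guess carrying the boundary data and its residual."""
        u0 = np.zeros_like(b)
        r0 = b.copy()
        if np.any(b[self.boundary]):
            u0[self.boundary] = b[self.boundary]
            r0 = b - self.matvec(u0)
        r0[self.boundary] = 0.0
        return u0, r0


def _finish(grid: RegularGrid, u, iterations, history, converged, final_res,
            breakdown, method) -> SolveResult:
    return SolveResult(
        potential=ScalarVolume.from_flat(grid, u),
        iterations=iterations,
        residual_history=list(history),
        converged=converged,
        final_residual=final_res,
        breakdown=breakdown,
        method=method,
    )


def bicg_solve(A: DiscreteOperator, f, P: Optional[Preconditioner] = None,
               cfg: Optional[SolverConfig] = None) -> SolveResult:
    """Preconditioned BiCG from a zero initial guess.

    Stops when the recomputed true relative residual drops below
    ``cfg.tolerance`` or after ``cfg.max_iterations`` iterations (the latter
    returns a non-converged result, it does not raise).  A rho- or
    alpha-breakdown is recorded in ``result.breakdown``; with
    ``cfg.fallback_to_bicgstab`` the solve is retried with BiCGStab.
    """
    cfg = cfg if cfg is not None else SolverConfig()
    P = P if P is not None else IdentityPreconditioner()
    sys_ = _System(A, need_transpose=True)
    b = _as_rhs_vector(f)
    n = b.size
    if n != A.grid.n_nodes:
        raise ValueError("right-hand side does not match the grid")

    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return _finish(A.grid, np.zeros(n), 0, [], True, 0.0, None, "bicg")

    u, r = sys_.eliminate_boundary(b)
    rt = r.copy()  # shadow residual, rt0 = r0
    p = np.zeros(n)
    pt = np.zeros(n)
    rho_prev = 1.0
    history: List[float] = []
    breakdown = None

    if np.linalg.norm(r) / bnorm <= cfg.tolerance:
        true_rel = float(np.linalg.norm(b - sys_.matvec(u)) / bnorm)
        if true_rel <= cfg.tolerance:
            return _finish(A.grid, u, 0, [], True, true_rel, None, "bicg")

    for it in range(1, cfg.max_iterations + 1):
        z = P.apply(r)
        zt = P.apply_transpose(rt)
        rho = float(zt @ r)
        if abs(rho) < _BREAKDOWN_EPS * max(np.linalg.norm(zt) * np.linalg.norm(r), 1e-300):
            breakdown = f"rho breakdown at iteration {it}"
            break
        if it == 1:
            p[:] = z
            pt[:] = zt
        else:
            beta = rho / rho_prev
            p[:] = z + beta * p
            pt[:] = zt + beta * pt
        q = sys_.matvec(p)
        qt = sys_.rmatvec(pt)
        denom = float(pt @ q)
        if abs(denom) < _BREAKDOWN_EPS * max(np.linalg.norm(pt) * np.linalg.norm(q), 1e-300):
            breakdown = f"alpha breakdown at iteration {it}"
            break
        alpha = rho / denom
        u += alpha * p
        r -= alpha * q
        rt -= alpha * qt
        rho_prev = rho

        rel = float(np.linalg.norm(r) / bnorm)
        if not np.isfinite(rel):
            raise FloatingPointError(f"non-finite iterate at BiCG iteration {it}")
        history.append(rel)
        if rel <= cfg.tolerance:
            true_rel = float(np.linalg.norm(b - sys_.matvec(u)) / bnorm)
            history[-1] = true_rel
            if true_rel <= cfg.tolerance:
                return _finish(A.grid, u, it, history, True, true_rel, None, "bicg")

    if breakdown is not None and cfg.fallback_to_bicgstab:
        result = bicgstab_solve(A, f, P, cfg)
        result.breakdown = breakdown + " (fell back to BiCGStab)"
        return result

    true_rel = float(np.linalg.norm(b - sys_.matvec(u)) / bnorm)
    return _finish(A.grid, u, len(history), history,
                   true_rel <= cfg.tolerance, true_rel, breakdown, "bicg")


def bicgstab_solve(A: DiscreteOperator, f, P: Optional[Preconditioner] = None,
                   cfg: Optional[SolverConfig] = None) -> SolveResult:
    """Preconditioned BiCGStab from a zero initial guess (same contract)."""
    cfg = cfg if cfg is not None else SolverConfig()
    P = P if P is not None else IdentityPreconditioner()
    sys_ = _System(A, need_transpose=False)
    b = _as_rhs_vector(f)
    n = b.size
    if n != A.grid.n_nodes:
        raise ValueError("right-hand side does not match the grid")

    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return _finish(A.grid, np.zeros(n), 0, [], True, 0.0, None, "bicgstab")

    u, r = sys_.eliminate_boundary(b)
    rt = r.copy()
    p = np.zeros(n)
    v = np.zeros(n)
    rho_prev = alpha = omega = 1.0
    history: List[float] = []
    breakdown = None

    if np.linalg.norm(r) / bnorm <= cfg.tolerance:
        true_rel = float(np.linalg.norm(b - sys_.matvec(u)) / bnorm)
        if true_rel <= cfg.tolerance:
            return _finish(A.grid, u, 0, [], True, true_rel, None, "bicgstab")

    for it in range(1, cfg.max_iterations + 1):
        rho = float(rt @ r)
        if abs(rho) < _BREAKDOWN_EPS * max(np.linalg.norm(rt) * np.linalg.norm(r), 1e-300):
            breakdown = f"rho breakdown at iteration {it}"
            break
        if it == 1:
            p[:] = r
        else:
            beta = (rho / rho_prev) * (alpha / omega)
            p[:] = r + beta * (p - omega * v)
        phat = P.apply(p)
        v = sys_.matvec(phat)
        denom = float(rt @ v)
        if abs(denom) < _BREAKDOWN_EPS * max(np.linalg.norm(rt) * np.linalg.norm(v), 1e-300):
            breakdown = f"alpha breakdown at iteration {it}"
            break
        alpha = rho / denom
        s = r - alpha * v
        if np.linalg.norm(s) / bnorm <= cfg.tolerance:
            u += alpha * phat
            true_rel = float(np.linalg.norm(b - sys_.matvec(u)) / bnorm)
            history.append(true_rel)
            if true_rel <= cfg.tolerance:
                return _finish(A.grid, u, it, history, True, true_rel, None, "bicgstab")
            r = b - sys_.matvec(u)
            rho_prev = rho
            continue
        shat = P.apply(s)
        t = sys_.matvec(shat)
        tt = float(t @ t)
        if tt == 0.0:
            breakdown = f"omega breakdown at iteration {it}"
            break
        omega = float(t @ s) / tt
        u += alpha * phat + omega * shat
        r = s - omega * t
        rho_prev = rho

        rel = float(np.linalg.norm(r) / bnorm)
        if not np.isfinite(rel):
            raise FloatingPointError(f"non-finite iterate at BiCGStab iteration {it}")
        history.append(rel)
        if rel <= cfg.tolerance:
            true_rel = float(np.linalg.norm(b - sys_.matvec(u)) / bnorm)
            history[-1] = true_rel
            if true_rel <= cfg.tolerance:
                return _finish(A.grid, u, it, history, True, true_rel, None, "bicgstab")
        if abs(omega) < _BREAKDOWN_EPS:
            breakdown = f"omega breakdown at iteration {it}"
            break

    true_rel = float(np.linalg.norm(b - sys_.matvec(u)) / bnorm)
    return _finish(A.grid, u, len(history), history,
                   true_rel <= cfg.tolerance, true_rel, breakdown, "bicgstab")
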