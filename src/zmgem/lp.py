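"""Thin LP layer: steady-state flux problems solved with HiGHS via scipy.

All constraint-based operations reduce to

    optimize  c.v   subject to   S.v = 0,  lb <= v <= ub

plus optional extra linear rows (e.g. a fraction-of-optimum constraint).
Solutions are audited after the solve: |S.v| must be within tolerance and v
within bounds, so a silently wrong solver answer cannot propagate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

STEADY_STATE_TOL = 1e-6
BOUND_TOL = 1e-7

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"
STATUS_FAILED = "failed"

_SCIPY_STATUS = {
    0: STATUS_OPTIMAL,
    1: STATUS_FAILED,  # iteration limit
    2: STATUS_INFEASIBLE,
    3: STATUS_UNBOUNDED,
    4: STATUS_FAILED,
}


class SolverError(RuntimeError):
    """Numerical failure or post-solve audit failure; never silent zeros."""


@dataclass
class LPSolution:
    status: str
    objective: Optional[float]
    x: Optional[np.ndarray]


def solve_flux_lp(
    S: sparse.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    maximize: bool = True,
    A_extra: Optional[sparse.spmatrix] = None,
    b_extra_lower: Optional[np.ndarray] = None,
    audit: bool = True,
) -> LPSolution:
    """Solve max/min c.v s.t. S.v=0, lb<=v<=ub (+ optional A.v >= b rows)."""
    sign = -1.0 if maximize else 1.0
    A_ub = None
    b_ub = None
    if A_extra is not None:
        # rows are lower bounds A.v >= b  ->  -A.v <= -b
        A_ub = -sparse.csr_matrix(A_extra)
        b_ub = -np.asarray(b_extra_lower, dtype=float)
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=sparse.csr_matrix(S),
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _SCIPY_STATUS.get(res.status, STATUS_FAILED)
    if status == STATUS_FAILED:
        raise SolverError(f"LP solver failed: {res.message}")
    if status != STATUS_OPTIMAL:
        return LPSolution(status, None, None)
    x = np.asarray(res.x)
    if audit:
        audit_solution(S, lb, ub, x)
    return LPSolution(STATUS_OPTIMAL, float(sign * res.fun), x)


def audit_solution(
    S: sparse.spmatrix, lb: np.ndarray, ub: np.ndarray, v: np.ndarray
) -> None:
    """Independent post-solve check of steady state and box bounds."""
    resid = np.abs(S @ v)
    if resid.size and resid.max() > STEADY_STATE_TOL:
        raise SolverError(
            f"steady-state residual {resid.max():.3e} exceeds {STEADY_STATE_TOL}"
        )
    if np.any(v < lb - BOUND_TOL) or np.any(v > ub + BOUND_TOL):
        worst = max(np.max(lb - v, initial=0.0), np.max(v - ub, initial=0.0))
        raise SolverError(f"bound violation {worst:.3e} in LP solution")
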