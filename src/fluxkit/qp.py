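"""Convex quadratic programming by a primal active-set method.

Solves problems of the form

    minimise    ½ xᵀ P x + qᵀ x
    subject to  A x = b,   lb ≤ x ≤ ub

with P symmetric positive semidefinite.  This covers the quadratic
formulations used here (metabolic-adjustment distances, where P is a
positive diagonal on the flux variables), at the modest problem sizes of
knockout screens on curated networks.

The method maintains a *linearly independent* working set of bound
constraints held at equality, solves the reduced Karush–Kuhn–Tucker system
for a step direction, takes the longest feasible step, and adds or drops
bounds until the multiplier signs certify optimality.  Keeping the working
set independent of the equality rows makes the multipliers unique, so the
sign test is decisive even at degenerate vertices.  A feasible starting
point comes from a phase-one LP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = ["QPResult", "solve_qp"]

_TOL = 1e-9


@dataclass
class QPResult:
    status: str  # optimal | infeasible | unbounded | numeric_failure
    x: np.ndarray | None = None
    objective: float | None = None


def _feasible_start(A, b, lb, ub) -> np.ndarray | None:
    bounds = list(zip(lb, ub))
    res = linprog(np.zeros(len(lb)), A_eq=A if A.size else None,
                  b_eq=b if A.size else None, bounds=bounds, method="highs")
    if res.status == 0:
        return np.clip(res.x, lb, ub)
    return None


def _independent_working_set(A: np.ndarray, candidates: list[int],
                             n: int) -> list[int]:
    """Largest prefix-greedy subset of bound constraints keeping
    ``[A; e_i for i in W]`` full row rank."""
    m = A.shape[0]
    rank = np.linalg.matrix_rank(A) if m else 0
    working: list[int] = []
    stacked = A.copy() if m else np.zeros((0, n))
    for i in candidates:
        if rank + len(working) >= n:
            break
        trial = np.vstack([stacked, np.eye(n)[i][None, :]])
        r = np.linalg.matrix_rank(trial)
        if r == rank + len(working) + 1:
            stacked = trial
            working.append(i)
    return working


def solve_qp(
    P: np.ndarray,
    q: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    max_iter: int | None = None,
) -> QPResult:
    """Minimise ``½xᵀPx + qᵀx`` s.t. ``Ax = b``, ``lb ≤ x ≤ ub``."""
    n = len(q)
    P = np.asarray(P, dtype=float)
    q = np.asarray(q, dtype=float)
    A = np.asarray(A, dtype=float).reshape(-1, n)
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m = A.shape[0]
    if max_iter is None:
        max_iter = 100 * (n + 1)

    x = _feasible_start(A, b, lb, ub)
    if x is None:
        return QPResult("infeasible")

    # working set of bound constraints, kept independent of the rows of A;
    # variables with lb == ub go in first so they are never dropped
    fixed = np.isclose(lb, ub, rtol=0, atol=0)
    at_bound = [i for i in range(n)
                if fixed[i] or abs(x[i] - lb[i]) < _TOL or abs(x[i] - ub[i]) < _TOL]
    at_bound.sort(key=lambda i: (not fixed[i], i))
    working_list = _independent_working_set(A, at_bound, n)
    side = {i: ("lb" if fixed[i] or abs(x[i] - lb[i]) < _TOL else "ub")
            for i in working_list}

    def scale():
        return 1.0 + float(np.abs(x).max(initial=1.0))

    for _ in range(max_iter):
        working = sorted(side)
        free = np.array([i for i in range(n) if i not in side], dtype=int)
        g = P @ x + q
        nf = len(free)

        p = np.zeros(n)
        if nf:
            K = np.zeros((nf + m, nf + m))
            K[:nf, :nf] = P[np.ix_(free, free)]
            K[:nf, nf:] = A[:, free].T
            K[nf:, :nf] = A[:, free]
            rhs = np.concatenate([-g[free], np.zeros(m)])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
                if np.linalg.norm(K @ sol - rhs) > 1e-6 * (1 + np.linalg.norm(rhs)):
                    # inconsistent reduced system: linear descent with zero
                    # curvature and no finite minimiser
                    return QPResult("unbounded")
            p[free] = sol[:nf]

        if nf == 0 or np.max(np.abs(p)) <= _TOL * scale():
            # stationary on the working set: unique multipliers from the
            # full-column-rank system [Aᵀ E_Wᵀ] [λ; μ] = g
            cols = []
            if m:
                cols.append(A.T)
            for i in working:
                cols.append(np.eye(n)[:, i][:, None])
            if cols:
                M = np.hstack(cols)
                mult, *_ = np.linalg.lstsq(M, g, rcond=None)
                mu = mult[m:]
            else:
                mu = np.zeros(0)
            worst_i, worst_v = -1, -1e-7
            for k, i in enumerate(working):
                if fixed[i]:
                    continue
                signed = mu[k] if side[i] == "lb" else -mu[k]
                if signed < worst_v:
                    worst_v, worst_i = signed, i
            if worst_i < 0:
                obj = 0.5 * x @ P @ x + q @ x
                return QPResult("optimal", x, float(obj))
            del side[worst_i]
            continue

        # longest feasible step along p
        alpha, block, block_side = 1.0, -1, ""
        for i in free:
            if p[i] > _TOL and np.isfinite(ub[i]):
                a = (ub[i] - x[i]) / p[i]
                if a < alpha:
                    alpha, block, block_side = a, i, "ub"
            elif p[i] < -_TOL and np.isfinite(lb[i]):
                a = (lb[i] - x[i]) / p[i]
                if a < alpha:
                    alpha, block, block_side = a, i, "lb"
        curvature = p @ P @ p
        if alpha >= 1.0 and curvature <= _TOL and g @ p < -_TOL * scale():
            return QPResult("unbounded")
        x = x + max(alpha, 0.0) * p
        if block >= 0:
            x[block] = lb[block] if block_side == "lb" else ub[block]
            side[block] = block_side
    return QPResult("numeric_failure")
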