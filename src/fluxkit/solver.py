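"""Solver-independent optimisation problems: build once, edit in place, re-solve.

The central object is the :class:`ProblemHandle`: a mutable handle on a
built optimisation problem supporting a small set of permitted edits
(variable bounds, objective, row limits) between solves.  Batch analyses —
knockout screens, flux variability — build one handle and apply only the
small per-iteration changes, instead of reconstructing the problem for
every optimisation.  The contract is result-equivalence: a sequence of
edits followed by solves must yield the same objectives as building a fresh
problem per edit.

One reference backend ships, built on SciPy's HiGHS interfaces for linear
and mixed-integer problems and on :mod:`fluxkit.qp` for convex quadratic
ones.  Other solvers can be plugged in by implementing the same two-class
surface (``Backend.build`` → handle with the edit/solve methods) and
declaring capability flags from {"LP", "QP", "MILP"}.

Conventions: constraints are range rows ``row_lb ≤ A x ≤ row_ub`` (equality
when the two coincide); a quadratic objective contributes ``xᵀQx`` with Q
symmetric PSD; returned row duals are sensitivities of the optimal
objective to shifting a row's limits, and variable duals (reduced costs)
the sensitivity to shifting a variable's bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, milp

from .errors import CapabilityError, UsageError
from .qp import solve_qp

__all__ = [
    "ProblemSpec",
    "ProblemHandle",
    "SolverSolution",
    "ReferenceBackend",
    "default_backend",
]

CONTINUOUS = "C"
BINARY = "B"

_STATUS_MAP = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded",
               4: "numeric_failure"}


@dataclass
class ProblemSpec:
    """Complete description of an LP/QP/MILP in range-constraint form."""

    n_vars: int
    var_lb: np.ndarray
    var_ub: np.ndarray
    linear_obj: np.ndarray
    sense: str = "max"  # "max" | "min"
    var_kind: np.ndarray | None = None  # per-var CONTINUOUS/BINARY; None = all continuous
    quadratic_obj: sp.spmatrix | np.ndarray | None = None  # contributes x^T Q x
    obj_const: float = 0.0
    A: sp.spmatrix | None = None
    row_lb: np.ndarray | None = None
    row_ub: np.ndarray | None = None

    def __post_init__(self):
        n = self.n_vars
        self.var_lb = np.asarray(self.var_lb, dtype=float)
        self.var_ub = np.asarray(self.var_ub, dtype=float)
        self.linear_obj = np.asarray(self.linear_obj, dtype=float)
        for name, v in (("var_lb", self.var_lb), ("var_ub", self.var_ub),
                        ("linear_obj", self.linear_obj)):
            if v.shape != (n,):
                raise UsageError(f"{name} must have length {n}")
        if self.sense not in ("max", "min"):
            raise UsageError(f"sense must be 'max' or 'min', got {self.sense!r}")
        if np.any(self.var_lb > self.var_ub):
            raise UsageError("var_lb > var_ub")
        if self.var_kind is None:
            self.var_kind = np.full(n, CONTINUOUS, dtype="U1")
        else:
            self.var_kind = np.asarray(self.var_kind, dtype="U1")
            if self.var_kind.shape != (n,):
                raise UsageError("var_kind must have length n_vars")
        if self.A is None:
            self.A = sp.csr_matrix((0, n))
            self.row_lb = np.zeros(0)
            self.row_ub = np.zeros(0)
        else:
            self.A = sp.csr_matrix(self.A)
            if self.A.shape[1] != n:
                raise UsageError("constraint matrix column count != n_vars")
            self.row_lb = np.asarray(self.row_lb, dtype=float)
            self.row_ub = np.asarray(self.row_ub, dtype=float)
            if self.row_lb.shape != (self.A.shape[0],) or \
                    self.row_ub.shape != (self.A.shape[0],):
                raise UsageError("row limits must match constraint row count")
            if np.any(self.row_lb > self.row_ub):
                raise UsageError("row_lb > row_ub")
        if self.quadratic_obj is not None:
            Q = np.asarray(self.quadratic_obj.todense()
                           if sp.issparse(self.quadratic_obj)
                           else self.quadratic_obj, dtype=float)
            if Q.shape != (n, n):
                raise UsageError("quadratic_obj must be n_vars x n_vars")
            self.quadratic_obj = Q

    @property
    def needs_qp(self) -> bool:
        return self.quadratic_obj is not None

    @property
    def needs_milp(self) -> bool:
        return bool(np.any(self.var_kind == BINARY))


@dataclass
class SolverSolution:
    """Outcome of one solve; primal/dual data only when optimal."""

    status: str  # optimal | infeasible | unbounded | limit | numeric_failure
    objective: float | None = None
    x: np.ndarray | None = None
    row_duals: np.ndarray | None = None
    var_duals: np.ndarray | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class ProblemHandle:
    """Mutable handle on a built problem (reference-backend implementation).

    Permitted edits: :meth:`set_var_bounds`, :meth:`set_objective`,
    :meth:`set_row_limits`.  The handle remains solvable after any permitted
    edit; repeated solves without edits return identical results.
    """

    def __init__(self, spec: ProblemSpec):
        self.n_vars = spec.n_vars
        self.var_lb = spec.var_lb.copy()
        self.var_ub = spec.var_ub.copy()
        self.var_kind = spec.var_kind.copy()
        self.sense = spec.sense
        self.linear_obj = spec.linear_obj.copy()
        self.quadratic_obj = (None if spec.quadratic_obj is None
                              else np.array(spec.quadratic_obj, copy=True))
        self.obj_const = spec.obj_const
        self.A = sp.csr_matrix(spec.A, copy=True)
        self.row_lb = spec.row_lb.copy()
        self.row_ub = spec.row_ub.copy()

    # -- permitted edits --------------------------------------------------

    def _check_indices(self, indices: Sequence[int], upper: int, what: str) -> np.ndarray:
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= upper):
            raise UsageError(f"{what} index out of range")
        return idx

    def set_var_bounds(self, indices: Sequence[int],
                       lb: Sequence[float] | float,
                       ub: Sequence[float] | float) -> None:
        idx = self._check_indices(indices, self.n_vars, "variable")
        lb = np.broadcast_to(np.asarray(lb, dtype=float), idx.shape)
        ub = np.broadcast_to(np.asarray(ub, dtype=float), idx.shape)
        if np.any(lb > ub):
            raise UsageError("lb > ub in set_var_bounds")
        self.var_lb[idx] = lb
        self.var_ub[idx] = ub

    def set_objective(self, coef: Sequence[float], sense: str | None = None) -> None:
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.n_vars,):
            raise UsageError(
                f"objective length {coef.shape} != n_vars {self.n_vars}")
        if sense is not None:
            if sense not in ("max", "min"):
                raise UsageError("sense must be 'max' or 'min'")
            self.sense = sense
        self.linear_obj = coef.copy()

    def set_row_limits(self, rows: Sequence[int],
                       lower: Sequence[float] | float,
                       upper: Sequence[float] | float) -> None:
        idx = self._check_indices(rows, self.A.shape[0], "row")
        lower = np.broadcast_to(np.asarray(lower, dtype=float), idx.shape)
        upper = np.broadcast_to(np.asarray(upper, dtype=float), idx.shape)
        if np.any(lower > upper):
            raise UsageError("lower > upper in set_row_limits")
        self.row_lb[idx] = lower
        self.row_ub[idx] = upper

    # -- solving ----------------------------------------------------------

    def solve(self) -> SolverSolution:
        try:
            if np.any(self.var_kind == BINARY):
                return self._solve_milp()
            if self.quadratic_obj is not None:
                return self._solve_qp()
            return self._solve_lp()
        except (ValueError, np.linalg.LinAlgError) as exc:  # backend failure
            return SolverSolution(status="numeric_failure",
                                  objective=None, x=None)

    def _solve_lp(self) -> SolverSolution:
        sign = -1.0 if self.sense == "max" else 1.0
        eq_mask = self.row_lb == self.row_ub
        A_eq = self.A[eq_mask] if eq_mask.any() else None
        b_eq = self.row_lb[eq_mask] if eq_mask.any() else None

        ub_rows = np.nonzero(~eq_mask & np.isfinite(self.row_ub))[0]
        lb_rows = np.nonzero(~eq_mask & np.isfinite(self.row_lb))[0]
        blocks, rhs = [], []
        if ub_rows.size:
            blocks.append(self.A[ub_rows])
            rhs.append(self.row_ub[ub_rows])
        if lb_rows.size:
            blocks.append(-self.A[lb_rows])
            rhs.append(-self.row_lb[lb_rows])
        A_ub = sp.vstack(blocks).tocsr() if blocks else None
        b_ub = np.concatenate(rhs) if rhs else None

        res = linprog(sign * self.linear_obj, A_ub=A_ub, b_ub=b_ub,
                      A_eq=A_eq, b_eq=b_eq,
                      bounds=np.column_stack([self.var_lb, self.var_ub]),
                      method="highs")
        status = _STATUS_MAP.get(res.status, "numeric_failure")
        if status != "optimal":
            return SolverSolution(status=status)

        objective = sign * res.fun + self.obj_const

        row_duals = np.zeros(self.A.shape[0])
        if eq_mask.any():
            row_duals[np.nonzero(eq_mask)[0]] = res.eqlin.marginals
        if ub_rows.size or lb_rows.size:
            marg = res.ineqlin.marginals
            k = 0
            for i in ub_rows:
                row_duals[i] += marg[k]
                k += 1
            for i in lb_rows:
                row_duals[i] -= marg[k]
                k += 1
        var_duals = res.lower.marginals + res.upper.marginals
        # marginals are for the minimisation form; report for stated sense
        return SolverSolution(status="optimal", objective=float(objective),
                              x=res.x.copy(),
                              row_duals=sign * row_duals,
                              var_duals=sign * var_duals)

    def _solve_milp(self) -> SolverSolution:
        if self.quadratic_obj is not None:
            raise UsageError("quadratic objective with binary variables "
                             "is not supported by the reference backend")
        sign = -1.0 if self.sense == "max" else 1.0
        integrality = (self.var_kind == BINARY).astype(int)
        constraints = []
        if self.A.shape[0]:
            constraints.append(LinearConstraint(self.A, self.row_lb, self.row_ub))
        from scipy.optimize import Bounds

        res = milp(sign * self.linear_obj, constraints=constraints,
                   integrality=integrality,
                   bounds=Bounds(self.var_lb, self.var_ub))
        status = _STATUS_MAP.get(res.status, "numeric_failure")
        if status != "optimal":
            return SolverSolution(status=status)
        return SolverSolution(status="optimal",
                              objective=float(sign * res.fun + self.obj_const),
                              x=res.x.copy())

    def _solve_qp(self) -> SolverSolution:
        if self.sense != "min":
            raise UsageError("quadratic objectives must be minimised "
                             "(a maximised convex form is unbounded)")
        n = self.n_vars
        m = self.A.shape[0]
        eq_mask = self.row_lb == self.row_ub
        range_rows = np.nonzero(~eq_mask)[0]
        ns = range_rows.size  # one slack per genuine range row

        P = np.zeros((n + ns, n + ns))
        P[:n, :n] = 2.0 * self.quadratic_obj
        q = np.concatenate([self.linear_obj, np.zeros(ns)])
        lb = np.concatenate([self.var_lb, self.row_lb[range_rows]])
        ub = np.concatenate([self.var_ub, self.row_ub[range_rows]])

        A_dense = self.A.toarray() if m else np.zeros((0, n))
        A_aug = np.zeros((m, n + ns))
        A_aug[:, :n] = A_dense
        for k, i in enumerate(range_rows):
            A_aug[i, n + k] = -1.0
        b = np.where(eq_mask, self.row_lb, 0.0) if m else np.zeros(0)

        res = solve_qp(P, q, A_aug, b, lb, ub)
        if res.status != "optimal":
            return SolverSolution(status=res.status)
        x = res.x[:n]
        objective = x @ self.quadratic_obj @ x + self.linear_obj @ x + self.obj_const
        return SolverSolution(status="optimal", objective=float(objective),
                              x=x.copy())


class ReferenceBackend:
    """The bundled backend; capability flags advertise what it can solve."""

    def __init__(self, capabilities: frozenset[str] | set[str] = frozenset({"LP", "QP", "MILP"})):
        unknown = set(capabilities) - {"LP", "QP", "MILP"}
        if unknown:
            raise UsageError(f"unknown capabilities: {sorted(unknown)}")
        self.capabilities = frozenset(capabilities)

    def build(self, spec: ProblemSpec) -> ProblemHandle:
        if spec.needs_qp and "QP" not in self.capabilities:
            raise CapabilityError("backend lacks QP capability "
                                  "(required by the quadratic objective)")
        if spec.needs_milp and "MILP" not in self.capabilities:
            raise CapabilityError("backend lacks MILP capability "
                                  "(required by binary variables)")
        if "LP" not in self.capabilities:
            raise CapabilityError("backend lacks LP capability")
        return ProblemHandle(spec)


_BACKENDS = {"reference": ReferenceBackend}


def default_backend() -> ReferenceBackend:
    return ReferenceBackend()


def get_backend(name: str) -> ReferenceBackend:
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise UsageError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}") from None


def build_problem(spec: ProblemSpec, backend=None) -> ProblemHandle:
    """Build a mutable handle for ``spec`` on ``backend`` (reference default)."""
    if backend is None:
        backend = default_backend()
    return backend.build(spec)
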