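"""Constraint-based analysis algorithms as formal optimisation problems.

Each builder maps a :class:`~fluxkit.model.MetabolicModel` (plus, where the
algorithm needs one, a wild-type reference flux distribution) to an
:class:`AlgorithmProblem`: a built solver handle together with the variable
layout needed to extract per-reaction fluxes from a solution.  Adding an
algorithm means writing one builder and registering it by name; the batch
analyses in :mod:`fluxkit.analyses` pick it up without modification.

Shipped algorithms
------------------
``fba``
    maximise the model objective c·v subject to S·v = 0 and flux bounds.
``mtf``
    among (near-)optimal FBA solutions, minimise the total absolute flux
    Σ|v| — a parsimonious flux distribution.
``moma``
    minimise the squared Euclidean distance Σ (v − w)² to a wild-type flux
    vector w (quadratic program); models minimal metabolic re-adjustment
    after a perturbation.
``lmoma``
    the linear (L1) variant: minimise Σ |v − w|.
``room``
    minimise the *number* of fluxes that change significantly versus the
    wild type, using binary change indicators (mixed-integer program);
    significance thresholds are relative (delta) and absolute (epsilon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .errors import UsageError
from .model import MetabolicModel
from .solver import (BINARY, CONTINUOUS, ProblemHandle, ProblemSpec,
                     ReferenceBackend, SolverSolution, default_backend)

__all__ = [
    "AlgorithmProblem",
    "OptSolution",
    "build_fba",
    "build_mtf",
    "build_moma",
    "build_lmoma",
    "build_room",
    "optimize",
    "register_algorithm",
    "get_algorithm",
    "list_algorithms",
    "ROOM_DELTA",
    "ROOM_EPSILON",
]

#: Fluxes smaller than this in magnitude are reported as exactly zero.
_FLUX_ZERO_TOL = 1e-9

#: ROOM significance thresholds from the original on/off formulation:
#: a flux has "changed" when it leaves the band w ± (delta·|w| + epsilon).
ROOM_DELTA = 0.03
ROOM_EPSILON = 0.001


def _eps_opt(z: float) -> float:
    """Slack used when pinning an objective value in a follow-up problem."""
    return 1e-6 * max(1.0, abs(z))


@dataclass
class OptSolution:
    """Result of one algorithm run, mapped back to reaction space."""

    algorithm: str
    status: str
    objective: float | None  # algorithm-specific meaning (distance, count, ...)
    fluxes: np.ndarray | None  # one value per model reaction
    biomass: float | None  # model objective evaluated at the fluxes
    reactions: list[str] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux_series(self):
        import pandas as pd

        return pd.Series(self.fluxes, index=self.reactions, name="flux")


class AlgorithmProblem:
    """A built problem plus its variable layout.

    The first ``n_reactions`` problem variables are always the reaction
    fluxes; auxiliary variables follow.  Knockouts are applied by forcing
    flux-variable bounds to zero; :meth:`reset` restores the bounds the
    problem was built with.
    """

    def __init__(self, name: str, model: MetabolicModel, handle: ProblemHandle):
        self.name = name
        self.model = model
        self.handle = handle
        self.n_reactions = model.n_reactions
        self._lb0 = handle.var_lb[: self.n_reactions].copy()
        self._ub0 = handle.var_ub[: self.n_reactions].copy()

    # -- knockout bookkeeping (used by the batch analyses) ----------------

    def apply_knockout(self, rxn_indices) -> None:
        idx = np.asarray(rxn_indices, dtype=int)
        if idx.size:
            self.handle.set_var_bounds(idx, 0.0, 0.0)

    def set_reaction_bounds(self, rxn_indices, lb, ub) -> None:
        self.handle.set_var_bounds(np.asarray(rxn_indices, dtype=int), lb, ub)

    def reset(self) -> None:
        idx = np.arange(self.n_reactions)
        self.handle.var_lb[idx] = self._lb0
        self.handle.var_ub[idx] = self._ub0

    # -- solving ----------------------------------------------------------

    def extract_fluxes(self, solution: SolverSolution) -> np.ndarray:
        v = solution.x[: self.n_reactions].copy()
        v[np.abs(v) < _FLUX_ZERO_TOL] = 0.0
        return v

    def solve(self) -> OptSolution:
        sol = self.handle.solve()
        if not sol.optimal:
            return OptSolution(self.name, sol.status, None, None, None,
                               list(self.model.reactions))
        v = self.extract_fluxes(sol)
        biomass = float(self.model.objective_coef @ v)
        return OptSolution(self.name, "optimal", float(sol.objective), v,
                           biomass, list(self.model.reactions))


def optimize(problem: AlgorithmProblem) -> OptSolution:
    """Solve a built algorithm problem; solver failures become statuses."""
    return problem.solve()


# ---------------------------------------------------------------------------
# FBA


def build_fba(model: MetabolicModel, backend: ReferenceBackend | None = None
              ) -> AlgorithmProblem:
    """maximise c·v  s.t.  S·v = 0,  lb ≤ v ≤ ub."""
    backend = backend or default_backend()
    m, n = model.n_metabolites, model.n_reactions
    spec = ProblemSpec(
        n_vars=n,
        var_lb=model.lower_bound,
        var_ub=model.upper_bound,
        linear_obj=model.objective_coef,
        sense="max",
        A=model.S,
        row_lb=np.zeros(m),
        row_ub=np.zeros(m),
    )
    return AlgorithmProblem("fba", model, backend.build(spec))


# ---------------------------------------------------------------------------
# mtf — minimise total absolute flux at (near-)optimal objective


class MTFProblem(AlgorithmProblem):
    """Two-stage problem: FBA for the optimum, then the L1-minimal optimum.

    The flux variables carry box bounds; auxiliaries p, q ≥ 0 with
    v − p + q = 0 linearise |v| = p + q at the optimum of min Σ(p + q).
    The attained FBA objective is pinned from below through a dedicated
    constraint row, with a small slack for numerical robustness.
    """

    def __init__(self, name, model, handle, fba_problem: AlgorithmProblem,
                 z_row: int, z_opt: float | None):
        super().__init__(name, model, handle)
        self.fba = fba_problem
        self.z_row = z_row
        self.z_opt = z_opt  # None: recompute at each solve (knockout screens)

    def apply_knockout(self, rxn_indices) -> None:
        super().apply_knockout(rxn_indices)
        self.fba.apply_knockout(rxn_indices)

    def set_reaction_bounds(self, rxn_indices, lb, ub) -> None:
        super().set_reaction_bounds(rxn_indices, lb, ub)
        self.fba.set_reaction_bounds(rxn_indices, lb, ub)

    def reset(self) -> None:
        super().reset()
        self.fba.reset()

    def solve(self) -> OptSolution:
        if self.z_opt is not None:
            z = self.z_opt
        else:
            fba_sol = self.fba.handle.solve()
            if not fba_sol.optimal:
                return OptSolution(self.name, fba_sol.status, None, None, None,
                                   list(self.model.reactions))
            z = float(fba_sol.objective)
        self.handle.set_row_limits([self.z_row], z - _eps_opt(z), np.inf)
        return super().solve()


def build_mtf(model: MetabolicModel, z_opt: float | None = None,
              backend: ReferenceBackend | None = None) -> AlgorithmProblem:
    """minimise Σ(p + q)  s.t.  S·v = 0,  v = p − q,  c·v ≥ z_opt − ε.

    With ``z_opt=None`` the FBA optimum is recomputed under the current
    bounds at every solve, which is what a knockout screen needs.
    """
    backend = backend or default_backend()
    m, n = model.n_metabolites, model.n_reactions
    I = sp.identity(n, format="csr")
    Z = sp.csr_matrix((m, n))
    # rows: [S 0 0] v = 0 ; [I -I I] (v - p + q) = 0 ; [c 0 0] >= z - eps
    A = sp.vstack([
        sp.hstack([model.S, Z, Z]),
        sp.hstack([I, -I, I]),
        sp.hstack([sp.csr_matrix(model.objective_coef), sp.csr_matrix((1, 2 * n))]),
    ]).tocsr()
    row_lb = np.concatenate([np.zeros(m + n), [-np.inf]])
    row_ub = np.concatenate([np.zeros(m + n), [np.inf]])
    spec = ProblemSpec(
        n_vars=3 * n,
        var_lb=np.concatenate([model.lower_bound, np.zeros(2 * n)]),
        var_ub=np.concatenate([model.upper_bound, np.full(2 * n, np.inf)]),
        linear_obj=np.concatenate([np.zeros(n), np.ones(2 * n)]),
        sense="min",
        A=A,
        row_lb=row_lb,
        row_ub=row_ub,
    )
    handle = backend.build(spec)
    fba = build_fba(model, backend)
    problem = MTFProblem("mtf", model, handle, fba, z_row=m + n, z_opt=z_opt)
    if z_opt is not None:
        handle.set_row_limits([m + n], z_opt - _eps_opt(z_opt), np.inf)
    return problem


# ---------------------------------------------------------------------------
# MOMA — quadratic minimisation of metabolic adjustment


def _check_wt(model: MetabolicModel, wt_flux) -> np.ndarray:
    w = np.asarray(wt_flux, dtype=float)
    if w.shape != (model.n_reactions,):
        raise UsageError(
            f"wild-type flux vector has length {w.shape}, expected "
            f"{model.n_reactions}")
    return w


def build_moma(model: MetabolicModel, wt_flux,
               backend: ReferenceBackend | None = None) -> AlgorithmProblem:
    """minimise Σ (v − w)²  s.t.  S·v = 0,  lb ≤ v ≤ ub  (quadratic)."""
    backend = backend or default_backend()
    w = _check_wt(model, wt_flux)
    m, n = model.n_metabolites, model.n_reactions
    spec = ProblemSpec(
        n_vars=n,
        var_lb=model.lower_bound,
        var_ub=model.upper_bound,
        linear_obj=-2.0 * w,
        sense="min",
        quadratic_obj=np.eye(n),
        obj_const=float(w @ w),
        A=model.S,
        row_lb=np.zeros(m),
        row_ub=np.zeros(m),
    )
    return AlgorithmProblem("moma", model, backend.build(spec))


def build_lmoma(model: MetabolicModel, wt_flux,
                backend: ReferenceBackend | None = None) -> AlgorithmProblem:
    """minimise Σ (d⁺ + d⁻)  s.t.  S·v = 0,  v − d⁺ + d⁻ = w,  d± ≥ 0."""
    backend = backend or default_backend()
    w = _check_wt(model, wt_flux)
    m, n = model.n_metabolites, model.n_reactions
    I = sp.identity(n, format="csr")
    Z = sp.csr_matrix((m, n))
    A = sp.vstack([
        sp.hstack([model.S, Z, Z]),
        sp.hstack([I, -I, I]),
    ]).tocsr()
    row_limits = np.concatenate([np.zeros(m), w])
    spec = ProblemSpec(
        n_vars=3 * n,
        var_lb=np.concatenate([model.lower_bound, np.zeros(2 * n)]),
        var_ub=np.concatenate([model.upper_bound, np.full(2 * n, np.inf)]),
        linear_obj=np.concatenate([np.zeros(n), np.ones(2 * n)]),
        sense="min",
        A=A,
        row_lb=row_limits,
        row_ub=row_limits,
    )
    return AlgorithmProblem("lmoma", model, backend.build(spec))


def build_room(model: MetabolicModel, wt_flux,
               delta: float = ROOM_DELTA, epsilon: float = ROOM_EPSILON,
               relaxed: bool = False,
               backend: ReferenceBackend | None = None) -> AlgorithmProblem:
    """minimise Σ yⱼ  (yⱼ binary)  s.t.  S·v = 0 and the big-M band rows.

    yⱼ = 0 confines vⱼ to the wild-type band [wⱼ − δ|wⱼ| − ε, wⱼ + δ|wⱼ| + ε];
    yⱼ = 1 releases it to its box bounds.  The big-M coefficients are built
    from the bounds at build time, so later bound edits must only *tighten*
    (as knockouts do) for the formulation to stay exact.

    ``relaxed=True`` solves the LP relaxation (y ∈ [0, 1]) instead; its
    objective lower-bounds the true change count.
    """
    backend = backend or default_backend()
    w = _check_wt(model, wt_flux)
    m, n = model.n_metabolites, model.n_reactions
    w_u = w + delta * np.abs(w) + epsilon
    w_l = w - delta * np.abs(w) - epsilon
    lb, ub = model.lower_bound, model.upper_bound

    Zm = sp.csr_matrix((m, n))
    I = sp.identity(n, format="csr")
    upper_block = sp.hstack([I, sp.diags(-(ub - w_u))])  # v - (ub-wu) y <= wu
    lower_block = sp.hstack([I, sp.diags(-(lb - w_l))])  # v - (lb-wl) y >= wl
    A = sp.vstack([sp.hstack([model.S, Zm]), upper_block, lower_block]).tocsr()
    row_lb = np.concatenate([np.zeros(m), np.full(n, -np.inf), w_l])
    row_ub = np.concatenate([np.zeros(m), w_u, np.full(n, np.inf)])

    kind = np.array([CONTINUOUS] * n +
                    [CONTINUOUS if relaxed else BINARY] * n)
    spec = ProblemSpec(
        n_vars=2 * n,
        var_lb=np.concatenate([lb, np.zeros(n)]),
        var_ub=np.concatenate([ub, np.ones(n)]),
        linear_obj=np.concatenate([np.zeros(n), np.ones(n)]),
        sense="min",
        var_kind=kind,
        A=A,
        row_lb=row_lb,
        row_ub=row_ub,
    )
    return AlgorithmProblem("room", model, backend.build(spec))


# ---------------------------------------------------------------------------
# Registry — the extension point for new algorithms

Builder = Callable[..., AlgorithmProblem]

_REGISTRY: dict[str, dict] = {}


def register_algorithm(name: str, builder: Builder,
                       needs_reference: bool = False) -> None:
    """Make ``builder`` available to the batch analyses under ``name``.

    ``needs_reference=True`` declares that the builder's second positional
    argument is a wild-type flux vector, which the analyses compute once
    (parsimonious by default) and reuse for every knockout set.
    """
    _REGISTRY[name] = {"builder": builder, "needs_reference": needs_reference}


def get_algorithm(name: str) -> dict:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UsageError(
            f"unknown algorithm {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def list_algorithms() -> list[str]:
    return sorted(_REGISTRY)


register_algorithm("fba", build_fba)
register_algorithm("mtf", build_mtf)
register_algorithm("moma", build_moma, needs_reference=True)
register_algorithm("lmoma", build_lmoma, needs_reference=True)
register_algorithm("room", build_room, needs_reference=True)
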