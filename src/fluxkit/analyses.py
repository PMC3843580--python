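"""High-level batch analyses: knockout screens, flux variability, robustness
and phenotypic phase planes.

Every analysis builds its optimisation problem once and then applies only
the small per-iteration edits (variable bounds, objective) to the shared
handle, restoring them afterwards.  ``reuse_problem=False`` switches the
knockout screens to building a fresh problem per set; results must agree —
that equivalence is the architectural contract and is tested.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import algorithms as alg
from .errors import UsageError
from .gpr import affected_reactions
from .model import MetabolicModel
from .solver import ReferenceBackend, default_backend

__all__ = [
    "DeletionRecord",
    "DeletionResult",
    "FVAResult",
    "RobustnessPoint",
    "PhPPResult",
    "gene_deletion",
    "flux_deletion",
    "flux_variability",
    "robustness",
    "phenotypic_phase_plane",
    "LETHAL_FRACTION",
]

#: A knockout is called lethal when the mutant's biomass falls below this
#: fraction of the wild-type optimum (separates numerical zero from growth).
LETHAL_FRACTION = 0.01


@dataclass
class DeletionRecord:
    knockout: tuple[str, ...]  # gene or reaction ids; () = wild type
    status: str
    objective: float | None  # algorithm objective (z, distance, count, ...)
    biomass: float | None
    affected: tuple[str, ...]  # reactions disabled by this set
    lethal: bool


@dataclass
class DeletionResult:
    algorithm: str
    kind: str  # "gene" | "reaction"
    wild_type_biomass: float
    lethal_fraction: float
    records: list[DeletionRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def lethal_sets(self) -> list[tuple[str, ...]]:
        return [r.knockout for r in self.records if r.lethal and r.knockout]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "knockout": [",".join(r.knockout) for r in self.records],
            "status": [r.status for r in self.records],
            "objective": [r.objective for r in self.records],
            "biomass": [r.biomass for r in self.records],
            "affected": [",".join(r.affected) for r in self.records],
            "lethal": [r.lethal for r in self.records],
        })


@dataclass
class FVAResult:
    status: str  # wild-type FBA status; per-reaction data only when optimal
    gamma: float
    wild_type_objective: float | None
    reactions: list[str] = field(default_factory=list)
    min_flux: np.ndarray | None = None
    max_flux: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "reaction": self.reactions,
            "min": self.min_flux,
            "max": self.max_flux,
            "gamma": self.gamma,
        })


@dataclass
class RobustnessPoint:
    control_flux: float
    status: str
    objective: float | None


@dataclass
class PhPPResult:
    rxn_a: str
    rxn_b: str
    grid_a: list[float]
    grid_b: list[float]
    objective: np.ndarray  # shape (len(grid_a), len(grid_b)); NaN = infeasible
    dual_a: np.ndarray
    dual_b: np.ndarray
    phase: np.ndarray  # integer labels; -1 = infeasible

    @property
    def n_phases(self) -> int:
        return len({p for p in self.phase.ravel() if p >= 0})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, va in enumerate(self.grid_a):
            for j, vb in enumerate(self.grid_b):
                rows.append({
                    self.rxn_a: va, self.rxn_b: vb,
                    "objective": self.objective[i, j],
                    "dual_a": self.dual_a[i, j], "dual_b": self.dual_b[i, j],
                    "phase": int(self.phase[i, j]),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def _wild_type_reference(model: MetabolicModel, backend) -> tuple[float, np.ndarray]:
    """Wild-type biomass (FBA) and the parsimonious reference flux vector."""
    fba_sol = alg.optimize(alg.build_fba(model, backend))
    if not fba_sol.optimal:
        raise UsageError(
            f"wild-type FBA is {fba_sol.status}; cannot run a knockout screen")
    mtf_sol = alg.optimize(alg.build_mtf(model, z_opt=fba_sol.biomass,
                                         backend=backend))
    if not mtf_sol.optimal:
        raise UsageError(f"wild-type parsimonious solve is {mtf_sol.status}")
    return fba_sol.biomass, mtf_sol.fluxes


def _build_for(model: MetabolicModel, algorithm: str, backend,
               wt_flux: np.ndarray | None, **params) -> alg.AlgorithmProblem:
    entry = alg.get_algorithm(algorithm)
    if entry["needs_reference"]:
        return entry["builder"](model, wt_flux, backend=backend, **params)
    return entry["builder"](model, backend=backend, **params)


def _is_lethal(status: str, biomass: float | None,
               wt_biomass: float, lethal_fraction: float) -> bool:
    if status != "optimal":
        return True
    return biomass < lethal_fraction * wt_biomass


def _deletion_screen(
    model: MetabolicModel,
    sets: list[tuple[str, ...]],
    affected_per_set: list[tuple[str, ...]],
    kind: str,
    algorithm: str,
    backend,
    lethal_fraction: float,
    reuse_problem: bool,
    **params,
) -> DeletionResult:
    wt_biomass, wt_flux = _wild_type_reference(model, backend)

    result = DeletionResult(algorithm=algorithm, kind=kind,
                            wild_type_biomass=wt_biomass,
                            lethal_fraction=lethal_fraction)
    rxn_index = {r: j for j, r in enumerate(model.reactions)}

    problem = None
    if reuse_problem:
        problem = _build_for(model, algorithm, backend, wt_flux, **params)

    for ko, affected in zip([()] + sets, [()] + affected_per_set):
        if not reuse_problem:
            problem = _build_for(model, algorithm, backend, wt_flux, **params)
        idx = [rxn_index[r] for r in affected]
        problem.apply_knockout(idx)
        sol = problem.solve()
        problem.reset()
        result.records.append(DeletionRecord(
            knockout=tuple(ko),
            status=sol.status,
            objective=sol.objective,
            biomass=sol.biomass,
            affected=tuple(affected),
            lethal=bool(ko) and _is_lethal(sol.status, sol.biomass,
                                           wt_biomass, lethal_fraction),
        ))
    return result


def gene_deletion(
    model: MetabolicModel,
    combinations: int = 1,
    algorithm: str = "fba",
    gene_subset: Sequence[str] | None = None,
    backend: ReferenceBackend | None = None,
    lethal_fraction: float = LETHAL_FRACTION,
    reuse_problem: bool = True,
    **params,
) -> DeletionResult:
    """Simulate all k-wise gene knockouts.

    Enumerates every size-``combinations`` subset of the model's genes (or
    of ``gene_subset``) in lexicographic order; for each, the reactions
    disabled by the gene-reaction rules are forced to zero flux on the
    shared problem, the algorithm is solved, and the bounds restored.  The
    wild type is recorded first.
    """
    backend = backend or default_backend()
    if combinations < 1:
        raise UsageError("combinations must be >= 1")
    genes = sorted(gene_subset) if gene_subset is not None else sorted(model.genes)
    unknown = set(genes) - set(model.genes)
    if gene_subset is not None and unknown:
        # tolerated: rules treat absent genes as never knock-outable
        pass
    if combinations > len(genes):
        raise UsageError(
            f"combinations={combinations} exceeds the {len(genes)} genes available")
    sets = [tuple(c) for c in itertools.combinations(genes, combinations)]
    affected = [tuple(affected_reactions(model, s)) for s in sets]
    return _deletion_screen(model, sets, affected, "gene", algorithm, backend,
                            lethal_fraction, reuse_problem, **params)


def flux_deletion(
    model: MetabolicModel,
    reaction_sets: Sequence[str] | Sequence[tuple[str, ...]] | None = None,
    algorithm: str = "fba",
    backend: ReferenceBackend | None = None,
    lethal_fraction: float = LETHAL_FRACTION,
    reuse_problem: bool = True,
    **params,
) -> DeletionResult:
    """Knock out reactions directly (no gene logic involved).

    ``reaction_sets`` may be tuples of reaction ids; a plain list of ids (or
    ``None``) means all single-reaction deletions.
    """
    backend = backend or default_backend()
    if reaction_sets is None:
        norm = [(r,) for r in model.reactions]
    else:
        norm = [(s,) if isinstance(s, str) else tuple(s) for s in reaction_sets]
    for s in norm:
        for r in s:
            model.reaction_index(r)  # raises on unknown ids
    return _deletion_screen(model, norm, norm, "reaction", algorithm, backend,
                            lethal_fraction, reuse_problem, **params)


def flux_variability(
    model: MetabolicModel,
    gamma: float = 1.0,
    reactions: Sequence[str] | None = None,
    backend: ReferenceBackend | None = None,
) -> FVAResult:
    """Per-reaction flux ranges with the objective pinned near its optimum.

    First FBA fixes the optimum z*; a constraint row then enforces
    c·v ≥ γ·z* − ε, and each reaction in turn is minimised and maximised on
    the same handle (two solves per reaction).
    """
    backend = backend or default_backend()
    if not (0 < gamma <= 1):
        raise UsageError("gamma must be in (0, 1]")
    subset = list(reactions) if reactions is not None else list(model.reactions)
    idx = [model.reaction_index(r) for r in subset]

    fba_sol = alg.optimize(alg.build_fba(model, backend))
    if not fba_sol.optimal:
        return FVAResult(status=fba_sol.status, gamma=gamma,
                         wild_type_objective=None)
    z = fba_sol.biomass

    # FBA problem plus one pinned-objective row
    import scipy.sparse as sp

    from .solver import ProblemSpec

    m, n = model.n_metabolites, model.n_reactions
    A = sp.vstack([model.S, sp.csr_matrix(model.objective_coef)]).tocsr()
    pin = gamma * z - 1e-6 * max(1.0, abs(z))
    spec = ProblemSpec(
        n_vars=n, var_lb=model.lower_bound, var_ub=model.upper_bound,
        linear_obj=np.zeros(n), sense="min", A=A,
        row_lb=np.concatenate([np.zeros(m), [pin]]),
        row_ub=np.concatenate([np.zeros(m), [np.inf]]),
    )
    handle = backend.build(spec)

    lo = np.empty(len(idx))
    hi = np.empty(len(idx))
    unit = np.zeros(n)
    for k, j in enumerate(idx):
        unit[j] = 1.0
        handle.set_objective(unit, sense="min")
        smin = handle.solve()
        handle.set_objective(unit, sense="max")
        smax = handle.solve()
        unit[j] = 0.0
        lo[k] = smin.objective if smin.optimal else np.nan
        hi[k] = smax.objective if smax.optimal else np.nan
    return FVAResult(status="optimal", gamma=gamma, wild_type_objective=z,
                     reactions=subset, min_flux=lo, max_flux=hi)


def robustness(
    model: MetabolicModel,
    control_rxn: str,
    n_points: int = 20,
    flux_range: tuple[float, float] | None = None,
    backend: ReferenceBackend | None = None,
) -> list[RobustnessPoint]:
    """Objective as a function of one pinned control flux.

    The control reaction is fixed (lb = ub) at ``n_points`` equally spaced
    values over ``flux_range`` (default: its own bounds) and FBA solved at
    each; infeasible points are recorded with an absent objective and the
    scan continues.
    """
    backend = backend or default_backend()
    if n_points < 2:
        raise UsageError("n_points must be >= 2")
    j = model.reaction_index(control_rxn)
    lo, hi = flux_range if flux_range is not None else (
        model.lower_bound[j], model.upper_bound[j])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise UsageError("flux_range must be finite (give one explicitly)")

    problem = alg.build_fba(model, backend)
    points: list[RobustnessPoint] = []
    for value in np.linspace(lo, hi, n_points):
        problem.handle.set_var_bounds([j], value, value)
        sol = problem.solve()
        points.append(RobustnessPoint(
            control_flux=float(value), status=sol.status,
            objective=sol.biomass if sol.optimal else None))
    problem.reset()
    return points


def phenotypic_phase_plane(
    model: MetabolicModel,
    rxn_a: str,
    rxn_b: str,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    backend: ReferenceBackend | None = None,
    dual_round: float = 1e-6,
) -> PhPPResult:
    """FBA over a grid of two pinned fluxes, with shadow-price phases.

    At each grid point both control fluxes are fixed and FBA solved; the
    recorded duals are the sensitivities of the optimal objective to the two
    pinned values.  Grid points whose rounded dual pair coincides share a
    phase: shadow prices are constant within a phenotypic phase and jump at
    its boundary.
    """
    backend = backend or default_backend()
    if not len(grid_a) or not len(grid_b):
        raise UsageError("grids must be non-empty")
    ja = model.reaction_index(rxn_a)
    jb = model.reaction_index(rxn_b)

    problem = alg.build_fba(model, backend)
    na, nb = len(grid_a), len(grid_b)
    objective = np.full((na, nb), np.nan)
    dual_a = np.full((na, nb), np.nan)
    dual_b = np.full((na, nb), np.nan)
    phase = np.full((na, nb), -1, dtype=int)
    labels: dict[tuple[float, float], int] = {}

    for i, va in enumerate(grid_a):
        for k, vb in enumerate(grid_b):
            problem.handle.set_var_bounds([ja], va, va)
            problem.handle.set_var_bounds([jb], vb, vb)
            sol = problem.handle.solve()
            if sol.optimal:
                objective[i, k] = sol.objective
                da = float(sol.var_duals[ja])
                db = float(sol.var_duals[jb])
                dual_a[i, k], dual_b[i, k] = da, db
                key = (round(da / dual_round) * dual_round,
                       round(db / dual_round) * dual_round)
                phase[i, k] = labels.setdefault(key, len(labels))
    problem.reset()
    return PhPPResult(rxn_a=rxn_a, rxn_b=rxn_b,
                      grid_a=[float(v) for v in grid_a],
                      grid_b=[float(v) for v in grid_b],
                      objective=objective, dual_a=dual_a, dual_b=dual_b,
                      phase=phase)
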