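"""In-memory representation of a constraint-based metabolic network.

A :class:`MetabolicModel` bundles the stoichiometric matrix S (metabolites ×
reactions), per-reaction flux bounds and objective coefficients, and the
gene–reaction association rules.  Flux bounds are in mmol·gDW⁻¹·h⁻¹ by
convention but numerically unitless.

Models are value-semantic: every manipulation operation returns a modified
copy and never mutates its input, so batch analyses can hand models around
freely.  The mutable fast path lives in :mod:`fluxkit.solver`.

Conventions
-----------
* A reaction is *reversible* iff its lower bound is negative; the flag is
  derived, never stored, so it can never disagree with the bounds.
* Exchange reactions are the columns with a single nonzero stoichiometric
  entry; negative flux means uptake, positive flux secretion (BiGG
  convention), so uptake limits are set via lower bounds.
* Compartments are encoded as an ``[x]`` suffix on the metabolite identifier
  (``glc[e]``); there is no separate compartment table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import BoundError, IdentifierConflictError, LookupError_, UsageError
from .gpr import EMPTY, GPRRule, parse_gpr

__all__ = [
    "MetabolicModel",
    "ValidationFinding",
    "ValidationReport",
    "DEFAULT_UB",
    "add_reaction",
    "change_bounds",
    "change_objective",
    "find_exchange_reactions",
    "change_uptake",
    "validate_model",
]

#: Default magnitude for open flux bounds (common COBRA convention).
DEFAULT_UB = 1000.0


@dataclass(frozen=True)
class ValidationFinding:
    level: str  # "error" | "warning"
    code: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[ValidationFinding, ...]

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.level == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.level == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __iter__(self):
        return iter(self.findings)


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds, objective and GPR rules.

    Parameters mirror the stored fields; ``genes`` is always recomputed as
    the ordered union of genes appearing in any rule, so it cannot drift out
    of sync with the rules.
    """

    model_id: str
    metabolites: list[str]
    reactions: list[str]
    S: sp.csc_matrix
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    objective_coef: np.ndarray
    gpr: list[GPRRule]
    subsystem: list[str] = field(default_factory=list)
    reaction_names: list[str] = field(default_factory=list)
    metabolite_names: list[str] = field(default_factory=list)
    extras: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        self.objective_coef = np.asarray(self.objective_coef, dtype=float)
        if not self.subsystem:
            self.subsystem = [""] * len(self.reactions)
        if not self.reaction_names:
            self.reaction_names = list(self.reactions)
        if not self.metabolite_names:
            self.metabolite_names = list(self.metabolites)
        self._check_invariants()

    # -- structural invariants -------------------------------------------

    def _check_invariants(self) -> None:
        n, m = len(self.reactions), len(self.metabolites)
        if self.S.shape != (m, n):
            raise UsageError(
                f"S has shape {self.S.shape}, expected ({m}, {n})")
        for name, vec in (("lower_bound", self.lower_bound),
                          ("upper_bound", self.upper_bound),
                          ("objective_coef", self.objective_coef)):
            if vec.shape != (n,):
                raise UsageError(f"{name} has length {vec.shape}, expected {n}")
        if len(self.gpr) != n or len(self.subsystem) != n:
            raise UsageError("per-reaction lists must match reaction count")
        for label, ids in (("reaction", self.reactions),
                           ("metabolite", self.metabolites)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for i in ids:
                    if i in seen:
                        dup = i
                        break
                    seen.add(i)
                raise IdentifierConflictError(f"duplicate {label} id {dup!r}")
        bad = np.nonzero(self.lower_bound > self.upper_bound)[0]
        if bad.size:
            raise BoundError(
                f"lower bound exceeds upper bound for {self.reactions[bad[0]]!r}")

    # -- derived views ----------------------------------------------------

    @property
    def genes(self) -> list[str]:
        """Ordered union of genes referenced by any rule (first-seen order)."""
        seen: dict[str, None] = {}
        for rule in self.gpr:
            for g in sorted(rule.genes()):
                seen.setdefault(g, None)
        return list(seen)

    @property
    def reversible(self) -> np.ndarray:
        """Per-reaction reversibility, derived as ``lower_bound < 0``."""
        return self.lower_bound < 0

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reactions.index(rxn_id)
        except ValueError:
            raise LookupError_(f"unknown reaction {rxn_id!r}") from None

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            lower_bound=self.lower_bound.copy(),
            upper_bound=self.upper_bound.copy(),
            objective_coef=self.objective_coef.copy(),
            gpr=list(self.gpr),
            subsystem=list(self.subsystem),
            reaction_names=list(self.reaction_names),
            metabolite_names=list(self.metabolite_names),
            extras={k: list(v) for k, v in self.extras.items()},
        )

    def __repr__(self) -> str:
        return (f"MetabolicModel({self.model_id!r}, "
                f"{self.n_metabolites} metabolites x {self.n_reactions} reactions, "
                f"{len(self.genes)} genes)")

    # convenience method forms of the module-level operations
    def add_reaction(self, *args, **kwargs) -> "MetabolicModel":
        return add_reaction(self, *args, **kwargs)

    def change_bounds(self, *args, **kwargs) -> "MetabolicModel":
        return change_bounds(self, *args, **kwargs)

    def change_objective(self, *args, **kwargs) -> "MetabolicModel":
        return change_objective(self, *args, **kwargs)

    def change_uptake(self, *args, **kwargs) -> "MetabolicModel":
        return change_uptake(self, *args, **kwargs)

    def find_exchange_reactions(self) -> list[str]:
        return find_exchange_reactions(self)

    def validate(self) -> ValidationReport:
        return validate_model(self)


def add_reaction(
    model: MetabolicModel,
    rxn_id: str,
    stoich: Mapping[str, float],
    lb: float = 0.0,
    ub: float = DEFAULT_UB,
    obj: float = 0.0,
    gpr_text: str = "",
    name: str | None = None,
    subsystem: str = "",
) -> MetabolicModel:
    """Return a copy of ``model`` with one reaction column appended.

    Metabolites in ``stoich`` that the model does not yet contain are
    appended as new rows; genes in ``gpr_text`` extend the gene list.
    """
    if rxn_id in model.reactions:
        raise IdentifierConflictError(f"reaction {rxn_id!r} already exists")
    if lb > ub:
        raise BoundError(f"lb {lb} > ub {ub} for {rxn_id!r}")
    rule = parse_gpr(gpr_text)

    new = model.copy()
    new_mets = [m for m in stoich if m not in model.metabolites]
    new.metabolites.extend(new_mets)
    new.metabolite_names.extend(new_mets)

    m = len(new.metabolites)
    col = sp.lil_matrix((m, 1))
    for met, coef in stoich.items():
        if coef != 0:
            col[new.metabolites.index(met), 0] = coef
    S = model.S
    if new_mets:
        S = sp.vstack([S, sp.csc_matrix((len(new_mets), S.shape[1]))])
    new.S = sp.hstack([S, col.tocsc()]).tocsc()

    new.reactions.append(rxn_id)
    new.reaction_names.append(name if name is not None else rxn_id)
    new.lower_bound = np.append(new.lower_bound, float(lb))
    new.upper_bound = np.append(new.upper_bound, float(ub))
    new.objective_coef = np.append(new.objective_coef, float(obj))
    new.gpr.append(rule)
    new.subsystem.append(subsystem)
    for key in new.extras:
        new.extras[key].append("")
    new._check_invariants()
    return new


def change_bounds(
    model: MetabolicModel,
    rxn_ids: Sequence[str],
    lb: Sequence[float] | float | None = None,
    ub: Sequence[float] | float | None = None,
) -> MetabolicModel:
    """Return a copy with the named reactions' bounds replaced.

    ``lb``/``ub`` may be scalars (broadcast) or sequences aligned with
    ``rxn_ids``; ``None`` leaves that side untouched.
    """
    idx = [model.reaction_index(r) for r in rxn_ids]
    new = model.copy()

    def as_vec(x):
        if x is None:
            return None
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 0:
            arr = np.full(len(idx), float(arr))
        if arr.shape != (len(idx),):
            raise UsageError("bounds length must match rxn_ids")
        return arr

    lbv, ubv = as_vec(lb), as_vec(ub)
    if lbv is not None:
        new.lower_bound[idx] = lbv
    if ubv is not None:
        new.upper_bound[idx] = ubv
    bad = np.nonzero(new.lower_bound[idx] > new.upper_bound[idx])[0]
    if bad.size:
        raise BoundError(
            f"lb > ub for reaction {rxn_ids[bad[0]]!r} after change")
    return new


def change_objective(
    model: MetabolicModel, coef_map: Mapping[str, float]
) -> MetabolicModel:
    """Return a copy whose objective equals ``coef_map``, zero elsewhere."""
    idx = [model.reaction_index(r) for r in coef_map]
    new = model.copy()
    new.objective_coef = np.zeros(model.n_reactions)
    new.objective_coef[idx] = [float(v) for v in coef_map.values()]
    return new


def find_exchange_reactions(model: MetabolicModel) -> list[str]:
    """Reactions whose column has exactly one nonzero stoichiometric entry.

    These are the boundary (exchange/demand/sink) reactions through which
    the model communicates with its environment.
    """
    nnz_per_col = np.diff(model.S.tocsc().indptr)
    return [r for r, k in zip(model.reactions, nnz_per_col) if k == 1]


def change_uptake(
    model: MetabolicModel, uptake_map: Mapping[str, float]
) -> MetabolicModel:
    """Define the growth environment through exchange lower bounds.

    Listed exchange reactions get the given lower bound (negative = uptake
    allowed); every exchange *not* listed is closed (lb = 0).  Non-exchange
    reactions are untouched.  This deliberately closes unlisted exchanges so
    a call fully specifies the medium.
    """
    exchanges = find_exchange_reactions(model)
    for key in uptake_map:
        if key not in exchanges:
            raise UsageError(f"{key!r} is not an exchange reaction")
    new = model.copy()
    for rxn in exchanges:
        j = model.reaction_index(rxn)
        new.lower_bound[j] = float(uptake_map.get(rxn, 0.0))
    bad = np.nonzero(new.lower_bound > new.upper_bound)[0]
    if bad.size:
        raise BoundError(f"lb > ub for {new.reactions[bad[0]]!r} after uptake change")
    return new


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Collect findings (never raises, never mutates).

    Errors: crossed bounds, duplicate identifiers.  Warnings: dead-end
    metabolites (rows whose entries all share one sign, in reactions that
    cannot run in reverse) and all-zero reaction columns.
    """
    findings: list[ValidationFinding] = []
    for label, ids in (("reaction", model.reactions),
                       ("metabolite", model.metabolites)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                findings.append(ValidationFinding(
                    "error", "duplicate-id", f"duplicate {label} id {i!r}"))
            seen.add(i)
    for j in np.nonzero(model.lower_bound > model.upper_bound)[0]:
        findings.append(ValidationFinding(
            "error", "crossed-bounds",
            f"lb > ub for reaction {model.reactions[j]!r}"))

    # dead ends: a metabolite that can only ever be produced or only consumed
    S = model.S.tocsr()
    rev = model.reversible
    for i, met in enumerate(model.metabolites):
        row = S.getrow(i)
        if row.nnz == 0:
            findings.append(ValidationFinding(
                "warning", "orphan-metabolite",
                f"metabolite {met!r} appears in no reaction"))
            continue
        signs = set()
        for j, coef in zip(row.indices, row.data):
            if rev[j]:
                signs.update({1, -1})
            else:
                signs.add(1 if coef > 0 else -1)
        if len(signs) == 1:
            side = "produced" if 1 in signs else "consumed"
            findings.append(ValidationFinding(
                "warning", "dead-end",
                f"metabolite {met!r} is only ever {side}"))
    nnz_per_col = np.diff(model.S.tocsc().indptr)
    for j in np.nonzero(nnz_per_col == 0)[0]:
        findings.append(ValidationFinding(
            "warning", "empty-column",
            f"reaction {model.reactions[j]!r} has no stoichiometry"))
    return ValidationReport(tuple(findings))
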