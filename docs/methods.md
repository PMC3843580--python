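# Methods

## Model representation

A `MetabolicModel` holds the sparse stoichiometric matrix S (metabolites ×
reactions), per-reaction lower/upper flux bounds, linear objective
coefficients, optional subsystem labels and one GPR rule per reaction.
Invariants are enforced on construction and after every manipulation:
consistent dimensions, unique identifiers, `lb ≤ ub`, and a gene list that
is always the union of genes appearing in the rules.

Two representation choices depart from the common practice of storing
everything redundantly:

* **Reversibility is derived, not stored.** A reaction is reversible iff
  its lower bound is negative. Storing a separate flag invites silent
  flag/bound disagreement; deriving it makes the inconsistency
  unrepresentable. The TSV writer chooses the equation arrow (`<==>` vs
  `-->`) from the derived flag, so files cannot disagree with themselves
  either.
* **Models are value-semantic.** Every manipulation (`add_reaction`,
  `change_bounds`, `change_objective`, `change_uptake`) returns a modified
  copy. Batch analyses can therefore cache and share models freely; the
  mutable fast path exists only inside the solver layer, where it is the
  point.

Compartments are an `[x]` suffix on the metabolite identifier (`glc[e]`),
the convention of BiGG-style reaction lists; there is no separate
compartment table, which keeps the TSV round trip lossless.

`change_uptake` treats its argument as the *complete* medium definition:
exchange reactions not listed are closed (lb = 0). This is a deliberate
choice — the alternative (leave unlisted exchanges open) makes growth
medium composition depend on call history, which is how silent modelling
errors happen.

## GPR rules

Rules are boolean expression trees (AND/OR/literal; no NOT, which does not
occur in GPR conventions). The grammar accepts `and`/`or` case-insensitively
and the synonyms `&`/`|`; AND binds tighter than OR, matching both
conventional boolean precedence and COBRA-style rule files. The canonical
rendering is fully parenthesised lower-case text, and parse∘render is the
identity on trees (property-tested). Genes in a knockout set that the model
does not contain are ignored (logged at debug level) so that gene lists
from external annotation pipelines can be screened directly.

## Solver layer

`ProblemSpec` describes an optimisation problem in range-constraint form
(`row_lb ≤ A x ≤ row_ub`, equality when the limits coincide, plus variable
bounds, a linear objective, an optional quadratic term xᵀQx and optional
binary variables). `Backend.build(spec)` returns a `ProblemHandle` whose
only permitted mutations are `set_var_bounds`, `set_objective` and
`set_row_limits`, followed by `solve()`.

The central contract is **batch equivalence**: any sequence of permitted
edits with a solve after each must produce the same statuses and objectives
(within 1e−7) as building a fresh problem per edit. All high-level screens
rely on this; it is asserted directly in the tests both at the solver level
(random edit sequences) and end-to-end (shared-handle vs rebuilt knockout
screens). The contract deliberately fixes *results*, not speed: whether a
backend exploits warm starts is its own affair and must never change
returned objectives.

The shipped reference backend advertises capabilities {LP, QP, MILP}:

* LP via `scipy.optimize.linprog` (HiGHS). Range rows are split into
  equality and one-sided rows internally; the returned row duals are
  recombined sensitivities of the optimal objective to shifting a row's
  limits, and variable duals are reduced costs. Strong duality of the
  returned multipliers is property-tested.
* MILP via `scipy.optimize.milp` (HiGHS branch-and-bound). No duals.
* QP via a built-in primal active-set method (`fluxkit.qp`) for convex
  problems: a phase-one LP finds a feasible vertex, then bound constraints
  are added/dropped against a working set kept linearly independent of the
  equality rows, so the KKT multipliers are unique and their signs are a
  decisive optimality certificate (this matters at degenerate vertices,
  which phase-one LPs routinely produce). Termination is finite for the
  strictly convex quadratics used here; the solver is cross-checked against
  an independent SLSQP formulation in the tests.

Backends with fewer capabilities raise a `CapabilityError` naming the
missing feature at build time (e.g. MOMA on an LP-only backend), never a
wrong answer at solve time.

Tolerances: the backend solves at its native feasibility tolerance
(HiGHS defaults, ~1e−9); all API-level equivalence assertions use 1e−6 to
1e−7 as stated per contract. Fluxes below 1e−9 in magnitude are reported as
exactly 0, which keeps downstream flux classification stable.

## Algorithms

Each builder maps a model (plus, where needed, a wild-type reference flux
vector w) to a problem whose first n variables are the reaction fluxes:

* **fba** — max c·v s.t. S·v = 0, bounds.
* **mtf** — auxiliaries p, q ≥ 0 with v − p + q = 0; min Σ(p+q) with the
  FBA optimum pinned from below by a constraint row c·v ≥ z − ε, where
  ε = 1e−6·max(1, |z|). The inequality-with-slack (rather than strict
  equality) is a numerical-robustness choice: pinning an LP optimum exactly
  makes the follow-up problem infeasible whenever the solver's attained
  optimum is a rounding away from z. The consequence is that "total flux
  40" on the chain fixture is attained as 40·(1 − 1e−6); tests and the
  acceptance script treat the documented analytic values as met at relative
  1e−5.
* **moma** — min Σ(v − w)², a QP with Q = I; the reported objective is the
  squared Euclidean distance (the constant wᵀw is carried in the problem so
  solver and reported objectives agree).
* **lmoma** — the plain L1 variant via d⁺, d⁻ ≥ 0, v − d⁺ + d⁻ = w,
  min Σ(d⁺+d⁻). Biomass is *not* additionally constrained; the distance
  criterion alone decides the mutant state. This is the simplest
  well-defined linear adjustment model and is documented as such.
* **room** — binary y_j per reaction with big-M rows confining v_j to the
  wild-type band w_j ± (δ|w_j| + ε) when y_j = 0; min Σy. Defaults
  δ = 0.03, ε = 0.001 follow the original regulatory on/off formulation.
  The big-M coefficients are computed from the bounds at build time, so the
  formulation stays exact under later bound edits only if those edits
  *tighten* (knockouts do; a widening edit requires a rebuild). A relaxed
  mode (y ∈ [0,1]) exists but must be requested explicitly; its objective
  is a lower bound on the true change count.

Flux-vector degeneracy policy: all contracts are on objective values. A
returned flux vector is *an* optimum, not *the* optimum, and tests never
compare flux vectors across solvers or formulations.

New algorithms register by name (`register_algorithm`); the knockout
screens look builders up in the registry, so an externally registered
algorithm is immediately available to `gene_deletion` with no changes
there. Builders that declare `needs_reference=True` receive the wild-type
reference vector as their second argument.

**Wild-type reference.** MOMA/lmoma/ROOM need a wild-type flux vector; raw
FBA optima are massively degenerate, so the default reference is the
parsimonious (mtf) solution, computed once per screen and reused for every
knockout set. Users can pass their own reference.

## Batch analyses

* `gene_deletion(model, combinations=k, algorithm=...)` enumerates all
  C(n, k) gene subsets in lexicographic order (reproducible outputs),
  records the wild type first, and for each subset zeroes the bounds of the
  rule-disabled reactions on the shared handle, solves, and restores. No
  lethal-subset pruning is done by default, so the enumeration is exactly
  exhaustive.
* Lethality: a knockout is lethal when its solve is non-optimal
  (infeasible) or its biomass falls below 1% of the wild-type optimum; the
  1% threshold (configurable) separates numerical zero from genuine
  residual growth.
* `flux_deletion` applies the same loop to reaction sets directly.
* `flux_variability(model, gamma)` pins c·v ≥ γ·z* − ε and minimises and
  maximises each reaction flux on one handle (two solves per reaction).
  The pin is an inequality with γ defaulting to 1.0; a strict-equality pin
  is representable as a user choice of row limits but is not the default,
  for the robustness reason above.
* `robustness` fixes a control flux (lb = ub) at equally spaced points and
  records the FBA objective; infeasible points are recorded and skipped,
  not fatal.
* `phenotypic_phase_plane` fixes two fluxes over a grid and records the
  objective and the two control duals (shadow prices). Phases are labelled
  by the distinct dual pairs after rounding at 1e−6: shadow prices are
  piecewise constant over the plane and jump exactly at phase boundaries,
  so rounded dual pairs are a procedure-free phase detector.

## Synthetic fixtures

The generators in `fluxkit.fixtures` define the networks everything is
verified on; they are package code, not test scaffolding.

* `make_chain_model` (linear chain, optimum = uptake),
  `make_branched_model` (redundant routes; parsimonious total flux 30 vs
  40, MOMA re-routes half the flux after the g1 knockout),
  `make_two_substrate_model` (yields 1 vs 2, distinct shadow prices) have
  hand-derived optima used as frozen expected values.
* `make_random_model` builds feasible-by-construction path networks:
  disjoint chains of unit conversions from capacity-limited sources into a
  shared biomass metabolite, with random capacities in [1, 10] and random
  one/two-gene rules dealt so a requested gene-pool size is fully used.
  Arbitrary random stoichiometric matrices were rejected because they are
  usually infeasible or unbounded; path networks keep the analytic optimum
  (sum of per-path bottlenecks) available as an independent check. Same
  seed ⇒ bit-identical model and TSV serialisation.
* `make_core_like_model` is a curated ~57-reaction, 30-gene network shaped
  like central carbon metabolism (glycolysis-like backbone with a 1→2
  cleavage, a pentose-phosphate-like shunt, fermentative branches, a closed
  TCA-like cycle with anaplerosis and a glyoxylate-like bypass, short
  biosynthesis chains, a multi-precursor biomass reaction). The
  stoichiometry is cofactor-free pseudo-chemistry on purpose: the fixture
  reproduces the *shape* of a curated reconstruction (branches, cycles,
  isoenzymes, enzyme complexes) without copying any published model.

What these fixtures do not emulate: cofactor and energy balancing,
compartment-specific transporters, realistic GPR depth, and thermodynamic
constraints beyond simple irreversibility. Passing tests therefore
demonstrate the correctness of the *algorithms and architecture* on
networks of realistic structure, not predictive accuracy on any real
organism.

## Verification strategy and problem sizes

Every optimisation path is checked against an independent route:

* FBA/mtf/lmoma against independently assembled dense LP formulations with
  different variable layouts (and FBA additionally against a separate
  implementation via GLPK in the unit tests); MOMA against an SLSQP
  solve of the raw nonlinear program; ROOM against exhaustive enumeration
  of all 2ⁿ on/off patterns (networks ≤ 8 reactions).
* The oracle suite runs on 100 random networks of ≤ 12 reactions; the
  shared-handle/rebuild equivalence screen uses a 30-gene random network
  (all 30 single and 435 pairwise deletions, both routes). These sizes keep
  the whole verification suite in the tens of seconds while exercising
  every code path; the algorithms themselves have no size-specific logic.

## Known limitations

* The QP path targets the strictly convex, box-and-equality-constrained
  quadratics of metabolic adjustment; it is not a general-purpose QP solver
  (indefinite or heavily rank-deficient Q are out of scope).
* The MILP path returns no duals, and ROOM solve times grow exponentially
  in the worst case, as for any branch-and-bound.
* One solve runs at a time per handle (single-owner contract); parallel
  screens should build one handle per worker.
* SBML is intentionally not parsed here; `read_sbml_model` raises with a
  pointer to the companion-package route, and the TSV dialect is the
  supported interchange format.
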