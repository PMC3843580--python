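# fluxkit

Constraint-based analysis of genome-scale metabolic networks: flux-balance
analysis and its perturbation variants, batch gene-knockout screens, flux
variability, robustness and phenotypic phase planes — built on an
optimisation layer that formulates each problem once and then only
transmits the small per-iteration changes to the solver.

## Who this is for

Systems biologists and metabolic engineers who want to script large *in
silico* experiments — e.g. every pairwise gene knockout of a
genome-scale reconstruction — from Python, with results as plain
DataFrames/TSV, and who want each analysis algorithm stated as an explicit,
checkable optimisation problem.

## The models

A metabolic network is a stoichiometric matrix **S** (metabolites ×
reactions) with per-reaction flux bounds *lb ≤ v ≤ ub* (mmol·gDW⁻¹·h⁻¹ by
convention), linear objective coefficients *c* (usually a biomass
reaction), and boolean gene–protein–reaction (GPR) rules such as
`(b0001 and b0002) or b0003` linking gene deletions to disabled reactions.

The algorithms, each a formal optimisation problem over steady-state flux
vectors `S·v = 0`:

| name | problem | class |
|---|---|---|
| `fba` | max c·v | LP |
| `mtf` | min Σ\|v\| s.t. c·v ≥ z\* − ε (parsimonious optimum) | LP |
| `moma` | min Σ (v − w)² against wild-type fluxes w | QP |
| `lmoma` | min Σ \|v − w\| | LP |
| `room` | min #{j : v_j outside w_j ± (δ\|w_j\| + ε)} | MILP |

Knockout screens force the bounds of rule-disabled reactions to zero on a
single pre-built problem, solve, and restore — the result is contractually
identical to rebuilding the problem for every knockout (this equivalence is
tested), just much cheaper.

## Worked example

A branched toy network (source → direct route R1, or a two-step bypass
R2a/R2b → biomass; genes g1, g2, g3 guard the three internal reactions):

```sh
$ fluxkit fixture --name branched --out branched.tsv
$ fluxkit fba --model branched.tsv
status	optimal
objective	10
biomass	10
$ fluxkit gendel --model branched.tsv --combinations 2
knockout	status	objective	biomass	affected	lethal
	optimal	10	10		false
g1,g2	optimal	0	0	R1,R2a	true
g1,g3	optimal	0	0	R1,R2b	true
g2,g3	optimal	10	10	R2a,R2b	false
```

The wild type grows at 10 (the source capacity). Deleting g1 together with
either bypass gene severs both routes — a synthetic-lethal pair — while
g2+g3 only removes the redundant bypass. Flux variability at the pinned
optimum shows the redundancy directly:

```sh
$ fluxkit fva --model branched.tsv
reaction	min	max	gamma
S_A	9.99999	10	1
R1	0	10	1
R2a	0	10	1
R2b	0	10	1
BIO	9.99999	10	1
```

R1 and R2a can each carry anywhere from 0 to 10 at the optimum (the small
slack on S_A/BIO is the documented ε used to pin the optimum). The same
analyses are available as library calls:

```python
from fluxkit import fixtures, gene_deletion

model = fixtures.make_branched_model()
result = gene_deletion(model, combinations=2, algorithm="lmoma")
print(result.to_frame())
```

## Scope

SBML input is deliberately out of scope (`read_sbml_model` points to a
companion package); models are exchanged in the column-based tab-separated
reaction-list dialect documented in `fluxkit.io`. Plotting and flux
coupling analysis are not included. See `docs/methods.md` for the methods,
numerical choices and limitations.
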