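"""Deterministic synthetic models with analytically known optima.

These generators are first-class package code: they define the networks the
test bed and the worked examples run on.  The three curated toys have
hand-checkable optima; :func:`make_random_model` produces feasible-by-
construction path networks (arbitrary random stoichiometric matrices are
usually infeasible or unbounded, so randomness is confined to path lengths,
capacities and gene rules); :func:`make_core_like_model` is a ~60-reaction
glycolysis-shaped network standing in for a curated central-metabolism
reconstruction, generated programmatically so nothing need be downloaded.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import UsageError
from .gpr import parse_gpr
from .io import parse_reaction_equation
from .model import DEFAULT_UB, MetabolicModel

__all__ = [
    "build_model",
    "make_chain_model",
    "make_branched_model",
    "make_two_substrate_model",
    "make_random_model",
    "make_core_like_model",
]


def build_model(model_id: str,
                reactions: list[tuple[str, str, float, float, float, str]]
                ) -> MetabolicModel:
    """Assemble a model from rows ``(id, equation, lb, ub, obj, gpr)``."""
    ids, mets, met_index = [], [], {}
    triplets: list[tuple[int, int, float]] = []
    lbs, ubs, objs, rules = [], [], [], []
    for j, (rxn, equation, lb, ub, obj, gpr_text) in enumerate(reactions):
        ids.append(rxn)
        eq = parse_reaction_equation(equation)
        for met, coef in eq.stoich.items():
            if met not in met_index:
                met_index[met] = len(mets)
                mets.append(met)
            triplets.append((met_index[met], j, coef))
        lbs.append(lb)
        ubs.append(ub)
        objs.append(obj)
        rules.append(parse_gpr(gpr_text))
    S = sp.coo_matrix(
        ([t[2] for t in triplets], ([t[0] for t in triplets],
                                    [t[1] for t in triplets])),
        shape=(len(mets), len(ids))).tocsc()
    return MetabolicModel(
        model_id=model_id, metabolites=mets, reactions=ids, S=S,
        lower_bound=np.array(lbs, dtype=float),
        upper_bound=np.array(ubs, dtype=float),
        objective_coef=np.array(objs, dtype=float),
        gpr=rules,
    )


def make_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """Linear chain A[e] → A[c] → B[c] → biomass; FBA optimum = ``uptake``.

    The single conversion step R1 is guarded by the isoenzyme rule
    ``g1 or g2``, so either gene alone sustains growth but the pair is a
    synthetic-lethal set.
    """
    if uptake < 0:
        raise UsageError("uptake must be non-negative")
    return build_model("chain", [
        ("EX_A", "A[e] <==>", -uptake, DEFAULT_UB, 0.0, ""),
        ("T_A", "A[e] --> A[c]", 0.0, DEFAULT_UB, 0.0, ""),
        ("R1", "A[c] --> B[c]", 0.0, DEFAULT_UB, 0.0, "g1 or g2"),
        ("BIO", "B[c] -->", 0.0, DEFAULT_UB, 1.0, ""),
    ])


def make_branched_model() -> MetabolicModel:
    """Source → {direct route R1 | two-step bypass R2a,R2b} → biomass.

    FBA optimum 10 either way; the parsimonious (minimal-total-flux)
    solution routes everything through R1 (total flux 30 versus 40 via the
    bypass), which makes the g1 knockout an instructive perturbation for
    the adjustment-minimising algorithms.
    """
    return build_model("branched", [
        ("S_A", "--> A", 0.0, 10.0, 0.0, ""),
        ("R1", "A --> B", 0.0, DEFAULT_UB, 0.0, "g1"),
        ("R2a", "A --> C", 0.0, DEFAULT_UB, 0.0, "g2"),
        ("R2b", "C --> B", 0.0, DEFAULT_UB, 0.0, "g3"),
        ("BIO", "B -->", 0.0, DEFAULT_UB, 1.0, ""),
    ])


def make_two_substrate_model() -> MetabolicModel:
    """Two substrates with different biomass yields (1 vs 2).

    With both source fluxes pinned to (va, vb) the optimum is va + 2·vb, so
    the two shadow prices differ — the phase-plane test bed.
    """
    return build_model("two_substrate", [
        ("S_A", "--> A", 0.0, DEFAULT_UB, 0.0, ""),
        ("S_B", "--> B", 0.0, DEFAULT_UB, 0.0, ""),
        ("RA", "A --> P", 0.0, DEFAULT_UB, 0.0, ""),
        ("RB", "B --> (2) P", 0.0, DEFAULT_UB, 0.0, ""),
        ("BIO", "P -->", 0.0, DEFAULT_UB, 1.0, ""),
    ])


def make_random_model(n_internal: int, n_paths: int, seed: int,
                      n_genes: int | None = None) -> MetabolicModel:
    """Random feasible path network with a strictly positive FBA optimum.

    Each path is a chain of unit conversions from a capacity-limited source
    to the shared biomass metabolite; path capacities are drawn from
    [1, 10].  The first path's internal steps are fully open, so its
    bottleneck is the source capacity and the optimum is the sum of path
    bottlenecks — always positive.  Internal reactions get random one- or
    two-gene rules drawn from a pool that is cycled so every pool gene is
    used.  Identical arguments produce a bit-identical model.
    """
    if n_internal < 1 or n_paths < 1:
        raise UsageError("n_internal and n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, float, float, float, str]] = []
    rule_slots: list[int] = []  # indices of rows that take a gene rule

    for p in range(n_paths):
        length = int(rng.integers(1, n_internal + 1))
        cap = float(np.round(rng.uniform(1.0, 10.0), 3))
        mets = [f"M{p}_{k}" for k in range(length)] + ["BM"]
        rows.append((f"SRC{p}", f"--> {mets[0]}", 0.0, cap, 0.0, ""))
        for k in range(length):
            open_cap = DEFAULT_UB if p == 0 else float(
                np.round(rng.uniform(1.0, 10.0), 3))
            rule_slots.append(len(rows))
            rows.append((f"R{p}_{k}", f"{mets[k]} --> {mets[k + 1]}",
                         0.0, open_cap, 0.0, ""))
    rows.append(("BIO", "BM -->", 0.0, DEFAULT_UB, 1.0, ""))

    n_rules = len(rule_slots)
    pool_size = n_genes if n_genes is not None else max(2, n_rules // 2)
    pool_size = min(pool_size, 2 * n_rules)  # a rule holds at most 2 genes
    pool = [f"g{i + 1}" for i in range(pool_size)]
    if pool_size > 2 * n_rules:
        raise UsageError(
            f"cannot place {pool_size} genes on {n_rules} internal reactions")
    # deal every pool gene at least once across the (up to two) rule slots
    order = list(rng.permutation(pool_size))
    first = [pool[order[r % pool_size]] for r in range(n_rules)]
    leftover = [pool[i] for i in order[n_rules:]]  # genes needing a 2nd slot
    texts = []
    for r in range(n_rules):
        g1 = first[r]
        style = int(rng.integers(0, 3))
        g2 = None
        if leftover:
            g2 = leftover.pop()
            if style == 0:
                style = int(rng.integers(1, 3))
        elif style and pool_size > 1:
            g2 = pool[int(rng.integers(0, pool_size))]
        if g2 is None or g2 == g1:
            texts.append(g1)
        else:
            texts.append(f"{g1} {'and' if style == 1 else 'or'} {g2}")
    for slot, text in zip(rule_slots, texts):
        rxn, eqn, lb, ub, obj, _ = rows[slot]
        rows[slot] = (rxn, eqn, lb, ub, obj, text)
    return build_model(f"random_{seed}", rows)


def make_core_like_model() -> MetabolicModel:
    """A curated ~60-reaction central-carbon-shaped synthetic network.

    Glucose enters a ten-step glycolysis-like backbone with a 1→2 cleavage
    step, feeds a pentose-phosphate-like shunt, fermentative branches and a
    closed TCA-like cycle with anaplerosis, and three short biosynthesis
    chains supply a multi-precursor biomass reaction.  The stoichiometry is
    deliberately cofactor-free pseudo-chemistry: the point is a network of
    realistic *shape* (branches, a cycle, isoenzymes, complexes, 30 genes),
    not chemical accuracy.  All internal steps are open ([0, 1000] or
    reversible), so the optimum is set by the glucose and oxygen supply.
    """
    U = DEFAULT_UB
    g = lambda k: f"b{k:04d}"  # noqa: E731 - compact gene namer
    rows: list[tuple[str, str, float, float, float, str]] = [
        # exchanges (negative lower bound = uptake allowed)
        ("EX_glc", "glc[e] <==>", -10.0, U, 0.0, ""),
        ("EX_o2", "o2[e] <==>", -20.0, U, 0.0, ""),
        ("EX_co2", "co2[e] <==>", 0.0, U, 0.0, ""),
        ("EX_etoh", "etoh[e] <==>", 0.0, U, 0.0, ""),
        ("EX_ac", "ac[e] <==>", 0.0, U, 0.0, ""),
        ("EX_lac", "lac[e] <==>", 0.0, U, 0.0, ""),
        # transport
        ("GLCt", "glc[e] --> glc[c]", 0.0, U, 0.0, f"{g(1)} and {g(2)}"),
        ("O2t", "o2[e] <==> o2[c]", -U, U, 0.0, ""),
        ("CO2t", "co2[c] <==> co2[e]", -U, U, 0.0, ""),
        ("ETOHt", "etoh[c] --> etoh[e]", 0.0, U, 0.0, ""),
        ("ACt", "ac[c] --> ac[e]", 0.0, U, 0.0, ""),
        ("LACt", "lac[c] --> lac[e]", 0.0, U, 0.0, ""),
        # glycolysis-like backbone (1->2 cleavage at step 4)
        ("HEX1", "glc[c] --> g6p[c]", 0.0, U, 0.0, g(3)),
        ("PGI", "g6p[c] <==> f6p[c]", -U, U, 0.0, g(4)),
        ("PFK", "f6p[c] --> fdp[c]", 0.0, U, 0.0, f"{g(5)} or {g(6)}"),
        ("FBA", "fdp[c] --> (2) g3p[c]", 0.0, U, 0.0, g(7)),
        ("GAPD", "g3p[c] <==> dpg[c]", -U, U, 0.0, g(8)),
        ("PGK", "dpg[c] <==> pg3[c]", -U, U, 0.0, g(9)),
        ("PGM", "pg3[c] <==> pg2[c]", -U, U, 0.0, g(10)),
        ("ENO", "pg2[c] <==> pep[c]", -U, U, 0.0, g(11)),
        ("PYK", "pep[c] --> pyr[c]", 0.0, U, 0.0, f"{g(12)} or {g(13)}"),
        # pentose-phosphate-like shunt (rejoins the backbone)
        ("G6PDH", "g6p[c] --> pgl[c]", 0.0, U, 0.0, g(14)),
        ("PGL", "pgl[c] --> ru5p[c] + co2[c]", 0.0, U, 0.0, g(15)),
        ("RPI", "ru5p[c] <==> r5p[c]", -U, U, 0.0, g(16)),
        ("TKT", "(2) r5p[c] --> f6p[c] + g3p[c] + co2[c]", 0.0, U, 0.0,
         f"{g(17)} and {g(18)}"),
        # fermentative branches
        ("PDC", "pyr[c] --> acald[c] + co2[c]", 0.0, U, 0.0, g(19)),
        ("ADH", "acald[c] --> etoh[c]", 0.0, U, 0.0, f"{g(20)} or {g(21)}"),
        ("PTA", "accoa[c] --> ac[c]", 0.0, U, 0.0, g(22)),
        ("LDH", "pyr[c] --> lac[c]", 0.0, U, 0.0, g(23)),
        # pyruvate to cycle, the cycle itself, and anaplerosis
        ("PDH", "pyr[c] + o2[c] --> accoa[c] + co2[c]", 0.0, U, 0.0,
         f"{g(24)} and {g(25)}"),
        ("CS", "accoa[c] + oaa[c] --> cit[c]", 0.0, U, 0.0, g(26)),
        ("ACONT", "cit[c] <==> icit[c]", -U, U, 0.0, g(27)),
        ("ICDH", "icit[c] --> akg[c] + co2[c]", 0.0, U, 0.0, g(28)),
        ("AKGDH", "akg[c] + o2[c] --> succ[c] + co2[c]", 0.0, U, 0.0,
         f"{g(24)} and {g(29)}"),
        ("SUCDH", "succ[c] --> fum[c]", 0.0, U, 0.0, g(30)),
        ("FUM", "fum[c] <==> mal[c]", -U, U, 0.0, g(27)),
        ("MDH", "mal[c] --> oaa[c]", 0.0, U, 0.0, g(26)),
        ("PPC", "pep[c] + co2[c] --> oaa[c]", 0.0, U, 0.0, g(14)),
        # glyoxylate-like shunt
        ("ICL", "icit[c] --> glx[c] + succ[c]", 0.0, U, 0.0, g(30)),
        ("MALS", "accoa[c] + glx[c] --> mal[c]", 0.0, U, 0.0, g(23)),
        # storage branch
        ("GLYS", "g6p[c] --> glyg[c]", 0.0, U, 0.0, f"{g(3)} and {g(5)}"),
        ("DM_glyg", "glyg[c] -->", 0.0, U, 0.0, ""),
        # short biosynthesis chains feeding biomass precursors
        ("GLUS", "akg[c] --> glu[c]", 0.0, U, 0.0, f"{g(8)} or {g(28)}"),
        ("GLNS", "glu[c] --> gln[c]", 0.0, U, 0.0, g(9)),
        ("ALAT", "pyr[c] --> ala[c]", 0.0, U, 0.0, g(10)),
        ("ASPT", "oaa[c] --> asp[c]", 0.0, U, 0.0, g(11)),
        ("ASNS", "asp[c] + gln[c] --> asn[c] + glu[c]", 0.0, U, 0.0, g(12)),
        ("DM_asn", "asn[c] -->", 0.0, U, 0.0, ""),
        ("PRPPS", "r5p[c] --> prpp[c]", 0.0, U, 0.0, g(16)),
        ("NUCS", "prpp[c] + gln[c] --> nuc[c]", 0.0, U, 0.0,
         f"{g(17)} and {g(15)}"),
        ("LIPS", "accoa[c] + g3p[c] --> lipid[c]", 0.0, U, 0.0, g(19)),
        ("PROTS", "ala[c] + asp[c] + glu[c] --> prot[c]", 0.0, U, 0.0,
         f"{g(20)} and {g(22)}"),
        # sinks/demands that keep optional branches usable
        ("DM_nuc", "nuc[c] -->", 0.0, U, 0.0, ""),
        ("DM_lipid", "lipid[c] -->", 0.0, U, 0.0, ""),
        ("DM_prot", "prot[c] -->", 0.0, U, 0.0, ""),
        # biomass: drains precursors in fixed proportions
        ("BIOMASS",
         "(0.5) g6p[c] + (0.5) pyr[c] + (0.2) nuc[c] + (0.2) lipid[c] "
         "+ (0.3) prot[c] -->",
         0.0, U, 1.0, ""),
    ]
    return build_model("core_like", rows)
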