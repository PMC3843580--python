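"""Independent reference computations used to cross-check the package.

Each oracle re-derives the quantity from first principles with a dense,
independently written formulation (different variable layout, different
solver path) so that agreement is evidence of correctness, not of shared
code.  They are deliberately slow and simple.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
from scipy.optimize import linprog, minimize


def fba_oracle(model):
    """Dense LP: maximise c·v s.t. S v = 0, bounds."""
    S = model.S.toarray()
    res = linprog(-model.objective_coef, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(model.lower_bound, model.upper_bound)),
                  method="highs")
    if res.status != 0:
        return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(
            res.status, "failure"), None
    return "optimal", -res.fun


def mtf_oracle(model, z_opt):
    """Split-variable LP without an explicit v: v = p − q, min Σ(p+q)."""
    S = model.S.toarray()
    m, n = S.shape
    eps = 1e-6 * max(1.0, abs(z_opt))
    # variables [p; q] >= 0
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    I = np.eye(n)
    # lb <= p - q <= ub  and  c(p-q) >= z - eps, as <=-rows
    A_ub = np.vstack([
        np.hstack([I, -I]),
        np.hstack([-I, I]),
        -np.hstack([model.objective_coef, -model.objective_coef])[None, :],
    ])
    b_ub = np.concatenate([model.upper_bound, -model.lower_bound,
                           [-(z_opt - eps)]])
    c = np.ones(2 * n)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (2 * n), method="highs")
    if res.status != 0:
        return "infeasible" if res.status == 2 else "failure", None
    return "optimal", res.fun


def lmoma_oracle(model, wt_flux):
    """L1 distance via t-variables: min Σt, t ≥ ±(v − w)."""
    S = model.S.toarray()
    m, n = S.shape
    w = np.asarray(wt_flux, dtype=float)
    # variables [v; t]
    A_eq = np.hstack([S, np.zeros((m, n))])
    I = np.eye(n)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    b_ub = np.concatenate([w, -w])
    bounds = list(zip(model.lower_bound, model.upper_bound)) + [(0, None)] * n
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(m),
                  bounds=bounds, method="highs")
    if res.status != 0:
        return "infeasible" if res.status == 2 else "failure", None
    return "optimal", res.fun


def moma_oracle(model, wt_flux):
    """Squared-distance QP via a general NLP solver (SLSQP)."""
    S = model.S.toarray()
    w = np.asarray(wt_flux, dtype=float)
    lb, ub = model.lower_bound, model.upper_bound
    x0 = np.clip(w, lb, ub)
    # project x0 towards feasibility of S v = 0 first via an LP
    res0 = linprog(np.zeros(len(w)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                   bounds=list(zip(lb, ub)), method="highs")
    if res0.status == 2:
        return "infeasible", None
    if res0.status == 0:
        x0 = res0.x
    res = minimize(
        lambda v: float((v - w) @ (v - w)),
        x0,
        jac=lambda v: 2.0 * (v - w),
        bounds=list(zip(lb, ub)),
        constraints=[{"type": "eq", "fun": lambda v: S @ v,
                      "jac": lambda v: S}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        return "failure", None
    return "optimal", float(res.fun)


def room_oracle(model, wt_flux, delta=0.03, epsilon=0.001):
    """Exhaustive change-pattern enumeration (models with few reactions).

    For every binary pattern y, a flux with y_j = 0 is confined to the
    wild-type band; the pattern is feasible if the resulting box admits a
    steady state.  The answer is the smallest Σy over feasible patterns.
    """
    S = model.S.toarray()
    n = S.shape[1]
    w = np.asarray(wt_flux, dtype=float)
    w_u = w + delta * np.abs(w) + epsilon
    w_l = w - delta * np.abs(w) - epsilon
    lb, ub = model.lower_bound, model.upper_bound

    for count in range(n + 1):
        for changed in itertools.combinations(range(n), count):
            blo, bhi = lb.copy(), ub.copy()
            ok = True
            for j in range(n):
                if j not in changed:
                    blo[j] = max(blo[j], w_l[j])
                    bhi[j] = min(bhi[j], w_u[j])
                    if blo[j] > bhi[j]:
                        ok = False
                        break
            if not ok:
                continue
            res = linprog(np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=list(zip(blo, bhi)), method="highs")
            if res.status == 0:
                return "optimal", count
    return "infeasible", None


def gpr_truth_table_eval(rule_text: str, knocked_out: set[str],
                         genes: list[str]) -> bool:
    """Evaluate rule text by direct substitution into a Python expression."""
    if not rule_text.strip():
        return True
    expr = rule_text
    for gene in sorted(genes, key=len, reverse=True):
        value = " True " if gene not in knocked_out else " False "
        expr = re.sub(rf"(?<![\w.-]){re.escape(gene)}(?![\w.-])", value, expr)
    expr = expr.replace("&", " and ").replace("|", " or ")
    return bool(eval(expr))  # noqa: S307 - controlled test input
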