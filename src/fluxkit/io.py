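"""Read and write metabolic models in a column-based reaction-list format.

The format is a tab-separated table with one reaction per row — the style of
exported BiGG reaction lists.  Recognised columns (header names matched
case-insensitively): ``abbreviation`` (required), ``name``, ``equation``
(required), ``lowbnd``, ``uppbnd``, ``obj_coef``, ``rule``, ``subsystem``.
Unknown columns are carried along and written back on round-trip but are
otherwise ignored.  Lines starting with ``#`` are comments.

Reaction equations use arrows ``-->`` (irreversible), ``<==>`` (reversible)
and ``<--`` (irreversible, written right-to-left); coefficients other than
one are parenthesised, ``(2) h2o``; an optional ``[c] :`` prefix sets a
default compartment for bare metabolite names; an empty side denotes an
exchange/demand reaction.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import EquationParseError, FluxkitError, FormatError, IdentifierConflictError
from .gpr import parse_gpr
from .model import DEFAULT_UB, MetabolicModel

__all__ = [
    "ReactionEquation",
    "parse_reaction_equation",
    "format_reaction_equation",
    "read_tsv_model",
    "write_tsv_model",
    "read_sbml_model",
]

_ARROWS = ("<==>", "-->", "<--")
_PREFIX_RE = re.compile(r"^\s*\[(?P<comp>[A-Za-z0-9]+)\]\s*:\s*")
_PAREN_COEF_RE = re.compile(r"^\((?P<c>[^()]+)\)$")
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


@dataclass
class ReactionEquation:
    """A parsed reaction equation: net stoichiometry plus directionality."""

    stoich: dict[str, float]
    reversible: bool
    default_compartment: str | None = None


def _parse_side(text: str, default_compartment: str | None,
                sign: float, stoich: dict[str, float]) -> None:
    text = text.strip()
    if not text:
        return
    for term in re.split(r"\s\+\s|^\+\s|\s\+$", " " + text + " "):
        term = term.strip()
        if not term:
            continue
        tokens = term.split()
        if len(tokens) == 1:
            coef, met = 1.0, tokens[0]
        elif len(tokens) == 2:
            raw, met = tokens
            m = _PAREN_COEF_RE.match(raw)
            if m:
                raw = m.group("c").strip()
            if not _NUMBER_RE.match(raw):
                raise EquationParseError(
                    f"malformed coefficient {tokens[0]!r} in term {term!r}")
            coef = float(raw)
            if coef == 0:
                raise EquationParseError(f"zero coefficient in term {term!r}")
        else:
            raise EquationParseError(f"malformed term {term!r}")
        if not met.endswith("]") and default_compartment:
            met = f"{met}[{default_compartment}]"
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def parse_reaction_equation(text: str) -> ReactionEquation:
    """Parse one reaction-equation string (dialect in the module docstring).

    Left-hand (substrate) coefficients come out negative, right-hand
    (product) coefficients positive; metabolites appearing on both sides are
    netted.
    """
    comp = None
    m = _PREFIX_RE.match(text)
    if m:
        comp = m.group("comp")
        text = text[m.end():]
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise EquationParseError(
            f"no reaction arrow (--> / <==> / <--) in {text.strip()!r}")
    left, right = text.split(arrow, 1)
    if arrow == "<--":
        left, right = right, left
    stoich: dict[str, float] = {}
    _parse_side(left, comp, -1.0, stoich)
    _parse_side(right, comp, +1.0, stoich)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise EquationParseError(f"equation {text.strip()!r} has no net conversion")
    return ReactionEquation(stoich=stoich, reversible=(arrow == "<==>"),
                            default_compartment=comp)


def _format_number(x: float) -> str:
    """Shortest decimal that round-trips through ``float``."""
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def _format_side(entries: list[tuple[str, float]]) -> str:
    parts = []
    for met, coef in entries:
        if coef == 1:
            parts.append(met)
        else:
            parts.append(f"({_format_number(coef)}) {met}")
    return " + ".join(parts)


def format_reaction_equation(stoich: dict[str, float], reversible: bool) -> str:
    left = [(m, -c) for m, c in stoich.items() if c < 0]
    right = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<==>" if reversible else "-->"
    return f"{_format_side(left)} {arrow} {_format_side(right)}".strip()


_KNOWN_COLUMNS = ("abbreviation", "name", "equation", "lowbnd", "uppbnd",
                  "obj_coef", "rule", "subsystem")


def _read_table(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t")
                if row and not row[0].lstrip().startswith("#")]
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    body = [row + [""] * (len(header) - len(row)) for row in rows[1:]]
    return header, body


def read_tsv_model(
    react_path: str | Path,
    desc_path: str | Path | None = None,
    met_path: str | Path | None = None,
    model_id: str | None = None,
) -> MetabolicModel:
    """Build a :class:`MetabolicModel` from a reaction-list file.

    ``desc_path`` / ``met_path`` optionally add a model description and
    metabolite display names; only the reactions file is required.  Missing
    bound cells default per equation reversibility (``[-1000, 1000]``
    reversible, ``[0, 1000]`` irreversible); missing ``obj_coef`` is 0 and a
    missing ``rule`` is the empty rule.
    """
    react_path = Path(react_path)
    header, body = _read_table(react_path)
    lower = [h.lower() for h in header]
    col = {name: lower.index(name) for name in lower}
    for required in ("abbreviation", "equation"):
        if required not in col:
            raise FormatError(f"{react_path}: missing required column {required!r}")

    extra_keys = [header[i] for i, h in enumerate(lower) if h not in _KNOWN_COLUMNS]

    reactions: list[str] = []
    names: list[str] = []
    metabolites: list[str] = []
    met_index: dict[str, int] = {}
    triplets: list[tuple[int, int, float]] = []
    lbs, ubs, objs = [], [], []
    rules, subsystems = [], []
    extras: dict[str, list[str]] = {k: [] for k in extra_keys}

    def cell(row: list[str], name: str) -> str:
        return row[col[name]].strip() if name in col else ""

    def number(row: list[str], name: str, default: float, rxn: str) -> float:
        raw = cell(row, name)
        if raw == "":
            return default
        try:
            return float(raw)
        except ValueError:
            raise FormatError(
                f"{react_path}: non-numeric {name} {raw!r} for {rxn!r}") from None

    for j, row in enumerate(body):
        rxn = cell(row, "abbreviation")
        if not rxn:
            raise FormatError(f"{react_path}: blank abbreviation in data row {j + 1}")
        if rxn in reactions:
            raise IdentifierConflictError(
                f"{react_path}: duplicate abbreviation {rxn!r}")
        try:
            eq = parse_reaction_equation(cell(row, "equation"))
        except EquationParseError as exc:
            raise FormatError(f"{react_path}: row {j + 1} ({rxn}): {exc}") from exc
        reactions.append(rxn)
        names.append(cell(row, "name") or rxn)
        for met, coef in eq.stoich.items():
            if met not in met_index:
                met_index[met] = len(metabolites)
                metabolites.append(met)
            triplets.append((met_index[met], j, coef))
        lb_default = -DEFAULT_UB if eq.reversible else 0.0
        lbs.append(number(row, "lowbnd", lb_default, rxn))
        ubs.append(number(row, "uppbnd", DEFAULT_UB, rxn))
        objs.append(number(row, "obj_coef", 0.0, rxn))
        rules.append(parse_gpr(cell(row, "rule")))
        subsystems.append(cell(row, "subsystem"))
        for k in extra_keys:
            extras[k].append(row[header.index(k)].strip())

    rows_idx = [t[0] for t in triplets]
    cols_idx = [t[1] for t in triplets]
    data = [t[2] for t in triplets]
    S = sp.coo_matrix((data, (rows_idx, cols_idx)),
                      shape=(len(metabolites), len(reactions))).tocsc()

    met_names = list(metabolites)
    if met_path is not None:
        mh, mb = _read_table(Path(met_path))
        ml = [h.lower() for h in mh]
        if "abbreviation" in ml and "name" in ml:
            ai, ni = ml.index("abbreviation"), ml.index("name")
            lookup = {r[ai].strip(): r[ni].strip() for r in mb}
            met_names = [lookup.get(m, m) for m in metabolites]

    mid = model_id
    if mid is None and desc_path is not None:
        dh, db = _read_table(Path(desc_path))
        dl = [h.lower() for h in dh]
        if "id" in dl and db:
            mid = db[0][dl.index("id")].strip()
        elif "name" in dl and db:
            mid = db[0][dl.index("name")].strip()
    if mid is None:
        mid = react_path.stem

    return MetabolicModel(
        model_id=mid,
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lower_bound=np.array(lbs),
        upper_bound=np.array(ubs),
        objective_coef=np.array(objs),
        gpr=rules,
        subsystem=subsystems,
        reaction_names=names,
        metabolite_names=met_names,
        extras=extras,
    )


def write_tsv_model(model: MetabolicModel, react_path: str | Path) -> None:
    """Write the reaction-list file; ``read_tsv_model`` reproduces the model.

    The equation arrow is chosen from the derived reversibility (``<==>``
    iff the lower bound is negative), so bounds and arrows can never
    disagree on disk.
    """
    react_path = Path(react_path)
    S = model.S.tocsc()
    header = list(_KNOWN_COLUMNS) + list(model.extras)
    with open(react_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for j, rxn in enumerate(model.reactions):
            colslice = slice(S.indptr[j], S.indptr[j + 1])
            stoich = {model.metabolites[i]: v
                      for i, v in zip(S.indices[colslice], S.data[colslice])}
            row = [
                rxn,
                model.reaction_names[j],
                format_reaction_equation(stoich, bool(model.reversible[j])),
                _format_number(model.lower_bound[j]),
                _format_number(model.upper_bound[j]),
                _format_number(model.objective_coef[j]),
                model.gpr[j].to_text(),
                model.subsystem[j],
            ]
            row.extend(model.extras[k][j] for k in model.extras)
            writer.writerow(row)


def read_sbml_model(path: str | Path) -> MetabolicModel:
    """Not provided here: SBML support lives in a companion package."""
    raise FluxkitError(
        "SBML input is not part of this package; install the SBML companion "
        "package (or export the model as a tab-separated reaction list and "
        "use read_tsv_model)."
    )
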