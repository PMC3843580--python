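"""Gene–protein–reaction (GPR) association rules.

A GPR rule is a boolean expression over gene identifiers that states which
gene products a reaction needs in order to carry flux.  ``"g1 and g2"``
models an enzyme complex (both subunits required), ``"g1 or g2"`` models
isoenzymes (either suffices).  Deleting a set of genes disables exactly the
reactions whose rule evaluates to false when those genes are absent.

Grammar
-------
* gene tokens: ``[A-Za-z0-9_.-]+``
* operators: ``and`` / ``or`` (case-insensitive) or the synonyms ``&`` / ``|``
* parentheses for grouping; ``and`` binds tighter than ``or``
* whitespace is insignificant; empty text denotes the empty rule (a reaction
  with no gene association, unaffected by any deletion)

There is no NOT operator: inhibitory associations are not part of GPR
conventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from .errors import GPRSyntaxError

if TYPE_CHECKING:  # pragma: no cover
    from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "GPRRule",
    "Literal",
    "And",
    "Or",
    "EMPTY",
    "parse_gpr",
    "evaluate_gpr",
    "affected_reactions",
]


@dataclass(frozen=True)
class GPRRule:
    """Base node of a rule expression tree."""

    def genes(self) -> set[str]:
        raise NotImplementedError

    def evaluate(self, knocked_out: Iterable[str]) -> bool:
        return evaluate_gpr(self, set(knocked_out))

    def to_text(self) -> str:
        """Canonical rendering: fully parenthesised, lower-case operators."""
        raise NotImplementedError

    @property
    def is_empty(self) -> bool:
        return isinstance(self, _Empty)


@dataclass(frozen=True)
class _Empty(GPRRule):
    def genes(self) -> set[str]:
        return set()

    def to_text(self) -> str:
        return ""


#: The empty rule: no gene association, always true.
EMPTY = _Empty()


@dataclass(frozen=True)
class Literal(GPRRule):
    gene: str

    def __post_init__(self):
        if not self.gene:
            raise GPRSyntaxError("empty gene identifier")

    def genes(self) -> set[str]:
        return {self.gene}

    def to_text(self) -> str:
        return self.gene


@dataclass(frozen=True)
class And(GPRRule):
    children: tuple[GPRRule, ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))

    def to_text(self) -> str:
        return "(" + " and ".join(c.to_text() for c in self.children) + ")"


@dataclass(frozen=True)
class Or(GPRRule):
    children: tuple[GPRRule, ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))

    def to_text(self) -> str:
        return "(" + " or ".join(c.to_text() for c in self.children) + ")"


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\() |
        (?P<rpar>\)) |
        (?P<amp>&)   |
        (?P<pipe>\|) |
        (?P<word>[A-Za-z0-9_.\-]+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            # skip trailing whitespace
            if text[pos:].strip() == "":
                break
            raise GPRSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        value = m.group(kind)
        start = m.start(kind)
        if kind == "word":
            low = value.lower()
            if low == "and":
                kind = "and"
            elif low == "or":
                kind = "or"
        elif kind == "amp":
            kind = "and"
        elif kind == "pipe":
            kind = "or"
        tokens.append((kind, value, start))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; ``or`` is the outermost level."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of rule", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> GPRRule:
        if not self.tokens:
            return EMPTY
        rule = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GPRSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return rule

    def parse_or(self) -> GPRRule:
        children = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[0] == "or":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self) -> GPRRule:
        children = [self.parse_atom()]
        while (tok := self.peek()) is not None and tok[0] == "and":
            self.next()
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_atom(self) -> GPRRule:
        kind, value, pos = self.next()
        if kind == "word":
            return Literal(value)
        if kind == "lpar":
            inner = self.parse_or()
            tok = self.peek()
            if tok is None or tok[0] != "rpar":
                raise GPRSyntaxError("unbalanced parenthesis", pos)
            self.next()
            return inner
        raise GPRSyntaxError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str | None) -> GPRRule:
    """Parse rule text into an expression tree.

    Blank or missing text yields :data:`EMPTY`.  Raises
    :class:`~fluxkit.errors.GPRSyntaxError` naming the offending position on
    unbalanced parentheses or dangling operators.
    """
    if text is None or not text.strip():
        return EMPTY
    return _Parser(text).parse()


def evaluate_gpr(rule: GPRRule, knocked_out: set[str]) -> bool:
    """True iff the reaction guarded by ``rule`` remains catalysable.

    A literal is true when its gene is not knocked out; AND requires all
    children, OR any child; the empty rule is always true.
    """
    if isinstance(rule, _Empty):
        return True
    if isinstance(rule, Literal):
        return rule.gene not in knocked_out
    if isinstance(rule, And):
        return all(evaluate_gpr(c, knocked_out) for c in rule.children)
    if isinstance(rule, Or):
        return any(evaluate_gpr(c, knocked_out) for c in rule.children)
    raise TypeError(f"not a GPR node: {rule!r}")


def affected_reactions(model: "MetabolicModel", knocked_out: Iterable[str]) -> list[str]:
    """Reactions disabled by deleting ``knocked_out`` genes.

    Returns exactly the reactions whose rule evaluates to false; reactions
    with an empty rule are never affected.  Genes absent from the model are
    ignored (logged at debug level) so externally derived gene lists can be
    screened directly.
    """
    ko = set(knocked_out)
    unknown = ko - set(model.genes)
    if unknown:
        logger.debug("ignoring genes absent from model %s: %s",
                     model.model_id, sorted(unknown))
    return [
        rxn
        for rxn, rule in zip(model.reactions, model.gpr)
        if not rule.is_empty and not evaluate_gpr(rule, ko)
    ]
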