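"""Gene-protein-reaction (GPR) boolean rules.

A GPR links a reaction to the genes whose products catalyse it: ``AND``
joins subunits of a complex (all required), ``OR`` joins isozymes (any
suffices).  Rules are parsed into an explicit boolean tree so that
expression values can later be mapped onto reactions (AND = min of the
subunits, OR = sum of the isozymes; see :mod:`fluxcohort.eflux`).

Grammar (case-insensitive keywords, AND binds tighter than OR)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := GENE | "(" expr ")"
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Union


class GprParseError(ValueError):
    """Raised for malformed GPR rule strings; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GeneRef:
    """Leaf node: a single gene identifier."""

    gene: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene id must be non-empty")


@dataclass(frozen=True)
class BoolOp:
    """Internal node: AND/OR over two or more children."""

    op: str  # "and" | "or"
    children: tuple["GprNode", ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node needs >= 2 children")


GprNode = Union[GeneRef, BoolOp]


@dataclass(frozen=True)
class Gpr:
    """A parsed GPR rule; ``root is None`` means the reaction has no GPR."""

    root: Optional[GprNode] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        if self.root is None:
            return frozenset()
        out: set[str] = set()
        stack: list[GprNode] = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, GeneRef):
                out.add(node.gene)
            else:
                stack.extend(node.children)
        return frozenset(out)

    def to_string(self) -> str:
        """Serialize back to a normalized rule string.

        Parentheses are emitted only where required by precedence, so
        ``parse(gpr.to_string())`` reproduces the tree exactly.
        """
        if self.root is None:
            return ""
        return _serialize(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _serialize(node: GprNode) -> str:
    if isinstance(node, GeneRef):
        return node.gene
    parts = []
    for child in node.children:
        text = _serialize(child)
        # grouping is needed for an OR child under an AND parent (precedence)
        # and for a same-operator child (to preserve the tree's nesting)
        if isinstance(child, BoolOp) and (node.op == "and" or child.op == node.op):
            text = f"({text})"
        parts.append(text)
    return f" {node.op} ".join(parts)


def _tokenize(rule: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            yield ("lparen", ch, i)
            i += 1
        elif ch == ")":
            yield ("rparen", ch, i)
            i += 1
        else:
            j = i
            while j < n and not rule[j].isspace() and rule[j] not in "()":
                j += 1
            word = rule[i:j]
            low = word.lower()
            if low in ("and", "or"):
                yield ("op", low, i)
            else:
                yield ("gene", word, i)
            i = j


class _Parser:
    def __init__(self, rule: str):
        self.tokens = list(_tokenize(rule))
        self.pos = 0
        self.length = len(rule)

    def _peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, str, int]:
        tok = self._peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", self.length)
        self.pos += 1
        return tok

    def parse(self) -> GprNode:
        node = self._expr()
        tok = self._peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def _expr(self) -> GprNode:
        children = [self._term()]
        while (tok := self._peek()) is not None and tok[:2] == ("op", "or"):
            self._next()
            children.append(self._term())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    def _term(self) -> GprNode:
        children = [self._factor()]
        while (tok := self._peek()) is not None and tok[:2] == ("op", "and"):
            self._next()
            children.append(self._factor())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def _factor(self) -> GprNode:
        kind, value, pos = self._next()
        if kind == "gene":
            return GeneRef(value)
        if kind == "lparen":
            node = self._expr()
            tok = self._peek()
            if tok is None or tok[0] != "rparen":
                raise GprParseError("unbalanced parentheses", pos)
            self._next()
            return node
        raise GprParseError(f"dangling operator or misplaced {value!r}", pos)


def parse_gpr(rule: str) -> Gpr:
    """Parse a boolean GPR rule string into a :class:`Gpr` tree.

    AND binds tighter than OR; parentheses override.  A blank/empty rule
    yields the empty GPR (reaction not gene-associated).

    Raises
    ------
    GprParseError
        On unbalanced parentheses or dangling operators, naming the
        offending position in the input string.
    """
    if rule is None or not rule.strip():
        return Gpr(None)
    return Gpr(_Parser(rule).parse())
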