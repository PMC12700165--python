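"""KEGG module DEFINITION parsing and stepwise completeness.

A KEGG module DEFINITION is a boolean expression over KO identifiers
organized into *steps*.  Grammar implemented here:

* top-level spaces separate steps (a module is the AND of its steps);
* within an expression, a space again means AND (sub-steps), a comma
  means OR (alternative enzymes), ``+`` joins subunits of a complex
  (AND), ``-`` marks an optional component (ignored in evaluation),
  parentheses group, and ``--`` is a placeholder for a step with no
  known KO (never satisfiable);
* leaves are KO ids (``K#####``) or nested module ids (``M#####``),
  the latter resolved one level deep against the definition table.

Precedence, loosest to tightest: space (AND) < comma (OR) < +/- chain.

*Stepwise completeness* of a genome for a module is the fraction of
top-level steps whose expression evaluates true given the genome's KO
set; a genome is called "complete" for the module above a configurable
cutoff (default 0.75).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

import pandas as pd

from .errors import DefinitionParseError
from .io import warn

KO_RE = re.compile(r"K\d{5}$")
MODULE_RE = re.compile(r"M\d{5}$")


# --- AST node kinds --------------------------------------------------------

@dataclass(frozen=True)
class Ko:
    ko: str


@dataclass(frozen=True)
class ModuleRef:
    module_id: str


@dataclass(frozen=True)
class Gap:
    """'--' placeholder: a step whose enzyme is unknown; never satisfied."""


@dataclass(frozen=True)
class Optional_:
    """A '-'-prefixed component; excluded from evaluation entirely."""
    child: "Node"


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]
    complex: bool = False  # True for '+'-joined subunit complexes


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]


Node = Union[Ko, ModuleRef, Gap, Optional_, And, Or]


@dataclass
class ModuleDefinition:
    module_id: str
    name: str
    steps: list[Node] = field(default_factory=list)
    raw: str = ""


# --- tokenizer -------------------------------------------------------------

_TOKEN_RE = re.compile(r"K\d{5}|M\d{5}|--|[()+,\- ]")


def _tokenize(defn: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(defn):
        m = _TOKEN_RE.match(defn, pos)
        if not m:
            raise DefinitionParseError(
                f"unexpected character {defn[pos]!r}", offset=pos)
        tok = m.group()
        if tok == " ":
            if tokens and tokens[-1][0] != " ":
                tokens.append((" ", pos))
        else:
            tokens.append((tok, pos))
        pos = m.end()
    while tokens and tokens[-1][0] == " ":
        tokens.pop()
    return tokens


# --- recursive-descent parser ---------------------------------------------

class _Parser:
    def __init__(self, defn: str):
        self.tokens = _tokenize(defn)
        self.i = 0
        self.end_offset = len(defn)

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def offset(self) -> int:
        return (self.tokens[self.i][1] if self.i < len(self.tokens)
                else self.end_offset)

    def advance(self) -> str:
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def parse_steps(self) -> list[Node]:
        """Top level: space-separated steps.

        Unlike a parenthesized space group (one step whose sub-steps
        must all hold), top-level spaces delimit separately counted
        steps, so they are split here rather than folded into an AND.
        """
        if not self.tokens:
            raise DefinitionParseError("empty definition", offset=0)
        steps = [self.comma_expr()]
        while self.peek() == " ":
            self.advance()
            steps.append(self.comma_expr())
        if self.peek() is not None:
            raise DefinitionParseError(
                f"unexpected token {self.peek()!r}", offset=self.offset())
        return steps

    def space_expr(self) -> Node:
        parts = [self.comma_expr()]
        while self.peek() == " ":
            self.advance()
            parts.append(self.comma_expr())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def comma_expr(self) -> Node:
        parts = [self.chain()]
        while self.peek() == ",":
            self.advance()
            parts.append(self.chain())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def chain(self) -> Node:
        parts: list[Node] = []
        if self.peek() == "-":  # leading optional, e.g. "-K00001"
            self.advance()
            parts.append(Optional_(self.factor()))
        else:
            parts.append(self.factor())
        while self.peek() in ("+", "-"):
            op = self.advance()
            nxt = self.factor()
            parts.append(nxt if op == "+" else Optional_(nxt))
        if len(parts) == 1:
            return parts[0]
        return And(tuple(parts), complex=True)

    def factor(self) -> Node:
        tok = self.peek()
        off = self.offset()
        if tok is None or tok in (",", "+", "-", ")", " "):
            raise DefinitionParseError(
                f"expected a KO, module id, '--' or '(', got {tok!r}",
                offset=off)
        self.advance()
        if tok == "(":
            inner = self.space_expr()
            if self.peek() != ")":
                raise DefinitionParseError("unbalanced parentheses",
                                           offset=self.offset())
            self.advance()
            return inner
        if tok == "--":
            return Gap()
        if KO_RE.match(tok):
            return Ko(tok)
        if MODULE_RE.match(tok):
            return ModuleRef(tok)
        raise DefinitionParseError(f"unexpected token {tok!r}", offset=off)


def parse_definition(defn: str) -> list[Node]:
    """Parse a DEFINITION string into its list of top-level step ASTs."""
    if not defn or not defn.strip():
        raise DefinitionParseError("empty definition", offset=0)
    return _Parser(defn.strip()).parse_steps()


# --- serialization (canonical form) ----------------------------------------

def serialize(node: Node, parent: str = "space") -> str:
    """Render a node back to DEFINITION syntax with minimal parentheses."""
    if isinstance(node, Ko):
        return node.ko
    if isinstance(node, ModuleRef):
        return node.module_id
    if isinstance(node, Gap):
        return "--"
    if isinstance(node, Optional_):
        inner = serialize(node.child, "chain")
        if inner.startswith("-"):  # avoid "---" ambiguity with the gap token
            inner = f"({inner})"
        return "-" + inner
    if isinstance(node, Or):
        text = ",".join(serialize(c, "comma") for c in node.children)
        return f"({text})" if parent == "chain" else text
    if isinstance(node, And):
        if node.complex:
            out = []
            for i, c in enumerate(node.children):
                if isinstance(c, Optional_):
                    inner = serialize(c.child, "chain")
                    if inner.startswith("-"):
                        inner = f"({inner})"
                    out.append("-" + inner)
                elif i == 0:
                    out.append(serialize(c, "chain"))
                else:
                    out.append("+" + serialize(c, "chain"))
            return "".join(out)
        text = " ".join(serialize(c, "comma") for c in node.children)
        return f"({text})" if parent != "space" else text
    raise TypeError(f"unknown node {node!r}")


def serialize_steps(steps: list[Node]) -> str:
    return " ".join(serialize(s, "comma") for s in steps)


# --- evaluation ------------------------------------------------------------

def _eval(node: Node, kos: set[str],
          defs: dict[str, "ModuleDefinition"] | None,
          depth: int) -> bool | None:
    """Evaluate a node; None means 'optional, ignore me'."""
    if isinstance(node, Ko):
        return node.ko in kos
    if isinstance(node, Gap):
        return False
    if isinstance(node, Optional_):
        return None
    if isinstance(node, ModuleRef):
        if defs is not None and node.module_id in defs and depth < 1:
            sub = defs[node.module_id]
            return stepwise_completeness(sub.steps, kos, defs,
                                         _depth=depth + 1) >= 1.0
        warn(f"unresolved nested module {node.module_id}; "
             "treated as unsatisfied")
        return False
    if isinstance(node, And):
        vals = [_eval(c, kos, defs, depth) for c in node.children]
        vals = [v for v in vals if v is not None]
        return all(vals) if vals else True
    if isinstance(node, Or):
        vals = [_eval(c, kos, defs, depth) for c in node.children]
        vals = [v for v in vals if v is not None]
        return any(vals) if vals else True
    raise TypeError(f"unknown node {node!r}")


def stepwise_completeness(steps: list[Node], kos: set[str],
                          defs: dict[str, ModuleDefinition] | None = None,
                          _depth: int = 0) -> float:
    """Fraction of top-level steps satisfied by a KO set."""
    if not steps:
        raise ValueError("module has no steps")
    kos = set(kos)
    # a step made only of optional components is vacuously satisfied
    vals = [_eval(s, kos, defs, _depth) for s in steps]
    satisfied = sum(1 for v in vals if v is None or v)
    return satisfied / len(steps)


def parse_module_table(table: pd.DataFrame) -> dict[str, ModuleDefinition]:
    """Parse a (module_id, name, definition) frame into ModuleDefinitions."""
    defs: dict[str, ModuleDefinition] = {}
    for _, row in table.iterrows():
        mid = row["module_id"]
        if mid in defs:
            raise ValueError(f"duplicate module id {mid!r}")
        defs[mid] = ModuleDefinition(module_id=mid, name=row["name"],
                                     steps=parse_definition(row["definition"]),
                                     raw=row["definition"])
    return defs


def completeness_matrix(defs: dict[str, ModuleDefinition],
                        ko_sets: dict[str, set[str]],
                        complete_cutoff: float = 0.75,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome x module stepwise completeness, plus a boolean 'complete'
    matrix at the given cutoff."""
    genomes = sorted(ko_sets)
    modules = sorted(defs)
    data = [[stepwise_completeness(defs[m].steps, ko_sets[g], defs)
             for m in modules] for g in genomes]
    comp = pd.DataFrame(data, index=pd.Index(genomes, name="genome_id"),
                        columns=modules)
    return comp, comp >= complete_cutoff
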