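"""Boolean gene regulatory networks: rule parsing, evaluation, state encoding.

A Boolean network over genes ``g_1..g_n`` is defined by one update rule per
gene, each a Boolean expression over the gene identifiers using NOT/AND/OR
(precedence NOT > AND > OR).  The network function ``f: {0,1}^n -> {0,1}^n``
applies every rule synchronously.  Genes may be *frozen* to a constant, which
overrides their rule — the mechanism used to model a mutation such as a gene
stuck at OFF.

State encoding convention
-------------------------
Gene ``j`` (0-based position in ``gene_names``) contributes bit value
``x_j * 2**j`` to the packed integer index, i.e. the first listed gene is the
least-significant bit.  Packed indices are 0-based in code; the 1-based index
``1 + sum_j x_j 2**j`` conventional in the Markov-chain literature is exposed
as :attr:`StateVector.index`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "StateVector",
    "RuleParseError",
    "parse_rules",
    "pack_states",
    "unpack_states",
    "all_states",
    "find_cycle",
]


class RuleParseError(ValueError):
    """Raised for malformed rule text or undeclared identifiers."""


# --------------------------------------------------------------------------
# state encoding helpers

def pack_states(bits: np.ndarray) -> np.ndarray:
    """Pack Boolean state vectors ``(..., n)`` into 0-based integer indices."""
    bits = np.asarray(bits)
    n = bits.shape[-1]
    weights = np.int64(1) << np.arange(n, dtype=np.int64)
    return (bits.astype(np.int64) * weights).sum(axis=-1)


def unpack_states(indices: np.ndarray, n: int) -> np.ndarray:
    """Unpack 0-based integer indices into Boolean state vectors ``(..., n)``."""
    idx = np.asarray(indices, dtype=np.int64)
    return ((idx[..., None] >> np.arange(n, dtype=np.int64)) & 1).astype(bool)


def all_states(n: int) -> np.ndarray:
    """Return the full ``(2**n, n)`` Boolean state enumeration in index order."""
    return unpack_states(np.arange(1 << n), n)


@dataclass(frozen=True)
class StateVector:
    """A single Boolean network state with its canonical integer index."""

    bits: tuple

    def __post_init__(self):
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def index(self) -> int:
        """1-based canonical index ``1 + sum_j x_j 2**j``."""
        return 1 + int(pack_states(np.array(self.bits)))

    @classmethod
    def from_index(cls, index: int, n: int) -> "StateVector":
        if not 1 <= index <= (1 << n):
            raise ValueError(f"index {index} out of range 1..{1 << n}")
        return cls(tuple(unpack_states(index - 1, n)))

    def to_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=bool)


# --------------------------------------------------------------------------
# expression parsing

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<op_not>NOT\b|¬|!)
      | (?P<op_and>AND\b|∧|&&|&)
      | (?P<op_or>OR\b|∨|\|\||\|)
      | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
      | (?P<const>[01])
    )""",
    re.VERBOSE | re.IGNORECASE,
)


def _tokenize(expr: str, lineno: int) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            raise RuleParseError(f"line {lineno}: cannot parse near {expr[pos:]!r}")
        pos = m.end()
        kind = m.lastgroup
        text = m.group(kind)
        if kind == "name" and text.upper() in ("NOT", "AND", "OR"):
            kind = {"NOT": "op_not", "AND": "op_and", "OR": "op_or"}[text.upper()]
        tokens.append((kind, text))
        if pos == m.start():  # pragma: no cover - regex always advances
            raise RuleParseError(f"line {lineno}: tokenizer stalled")
    return tokens


class _Parser:
    """Recursive-descent parser producing tuple ASTs.

    Nodes: ``('var', name)``, ``('const', bool)``, ``('not', a)``,
    ``('and', a, b)``, ``('or', a, b)``.
    """

    def __init__(self, tokens: list[tuple[str, str]], lineno: int):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.pos != len(self.tokens):
            raise RuleParseError(
                f"line {self.lineno}: unexpected token {self.tokens[self.pos][1]!r}"
            )
        return node

    def expr(self):
        node = self.term()
        while self._peek() == "op_or":
            self._next()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self._peek() == "op_and":
            self._next()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        kind = self._peek()
        if kind is None:
            raise RuleParseError(f"line {self.lineno}: unexpected end of expression")
        if kind == "op_not":
            self._next()
            return ("not", self.factor())
        if kind == "lparen":
            self._next()
            node = self.expr()
            if self._peek() != "rparen":
                raise RuleParseError(f"line {self.lineno}: missing ')'")
            self._next()
            return node
        if kind == "name":
            return ("var", self._next()[1])
        if kind == "const":
            return ("const", self._next()[1] == "1")
        raise RuleParseError(f"line {self.lineno}: unexpected token")


def _ast_vars(node) -> set:
    kind = node[0]
    if kind == "var":
        return {node[1]}
    if kind == "const":
        return set()
    return set().union(*(_ast_vars(child) for child in node[1:]))


def _compile_ast(node, gene_index: Mapping[str, int]):
    """Compile an AST to a closure over a ``(..., n)`` Boolean array."""
    kind = node[0]
    if kind == "var":
        j = gene_index[node[1]]
        return lambda X: X[..., j]
    if kind == "const":
        val = node[1]
        return lambda X: np.broadcast_to(np.bool_(val), X.shape[:-1])
    if kind == "not":
        fa = _compile_ast(node[1], gene_index)
        return lambda X: ~fa(X)
    fa = _compile_ast(node[1], gene_index)
    fb = _compile_ast(node[2], gene_index)
    if kind == "and":
        return lambda X: fa(X) & fb(X)
    return lambda X: fa(X) | fb(X)


def _format_ast(node) -> str:
    kind = node[0]
    if kind == "var":
        return node[1]
    if kind == "const":
        return "1" if node[1] else "0"
    if kind == "not":
        inner = _format_ast(node[1])
        if node[1][0] in ("and", "or"):
            inner = f"({inner})"
        return f"NOT {inner}"
    op = " AND " if kind == "and" else " OR "
    parts = []
    for child in node[1:]:
        s = _format_ast(child)
        if child[0] == "or" and kind == "and":
            s = f"({s})"
        parts.append(s)
    return op.join(parts)


# --------------------------------------------------------------------------
# network

@dataclass
class BooleanNetwork:
    """An n-gene synchronous Boolean network with optional frozen genes."""

    gene_names: tuple
    rules: tuple  # one AST per gene, same order as gene_names
    frozen_genes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gene_names = tuple(self.gene_names)
        self.rules = tuple(self.rules)
        if len(self.gene_names) != len(self.rules):
            raise ValueError("one rule per gene required")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise RuleParseError("duplicate gene names")
        index = {g: j for j, g in enumerate(self.gene_names)}
        for g, ast in zip(self.gene_names, self.rules):
            unknown = _ast_vars(ast) - set(index)
            if unknown:
                raise RuleParseError(
                    f"rule for {g!r} references undefined identifier(s): "
                    f"{', '.join(sorted(unknown))}"
                )
        for g in self.frozen_genes:
            if g not in index:
                raise RuleParseError(f"cannot freeze unknown gene {g!r}")
        self._index = index
        self._compiled = [_compile_ast(ast, index) for ast in self.rules]

    @property
    def n(self) -> int:
        return len(self.gene_names)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Apply the network function to states ``x`` of shape ``(..., n)``.

        Frozen genes are forced to their constants in the output.  Accepts a
        single state vector or any batch; returns an array of the same shape.
        """
        X = np.asarray(x).astype(bool)
        if X.shape[-1] != self.n:
            raise ValueError(f"state has {X.shape[-1]} bits, network has {self.n}")
        out = np.empty_like(X)
        for j, fn in enumerate(self._compiled):
            out[..., j] = fn(X)
        for g, val in self.frozen_genes.items():
            out[..., self._index[g]] = bool(val)
        return out

    def evaluate_state(self, x: StateVector) -> StateVector:
        return StateVector(tuple(self.evaluate(x.to_array())))

    def with_frozen(self, frozen: Mapping[str, int]) -> "BooleanNetwork":
        """Return a copy with additional genes frozen to constants."""
        merged = dict(self.frozen_genes)
        merged.update({g: bool(v) for g, v in frozen.items()})
        return BooleanNetwork(self.gene_names, self.rules, merged)

    def permuted(self, order: Sequence[int]) -> "BooleanNetwork":
        """Return the same network with genes reordered by ``order``."""
        order = list(order)
        names = tuple(self.gene_names[j] for j in order)
        rules = tuple(self.rules[j] for j in order)
        return BooleanNetwork(names, rules, dict(self.frozen_genes))

    def rule_text(self) -> str:
        lines = [
            f"{g} = {_format_ast(ast)}"
            for g, ast in zip(self.gene_names, self.rules)
        ]
        for g, v in self.frozen_genes.items():
            lines.append(f"FREEZE {g} = {1 if v else 0}")
        return "\n".join(lines) + "\n"


def parse_rules(text: str) -> BooleanNetwork:
    """Parse rule text, one ``NAME = EXPRESSION`` line per gene.

    Blank lines and ``#`` comments are ignored.  A ``FREEZE NAME = 0|1`` line
    pins a gene to a constant (overriding its rule).  Both ASCII
    (``NOT/AND/OR``, ``!/&/|``) and Unicode (``¬/∧/∨``) operator spellings are
    accepted.
    """
    names: list[str] = []
    asts: list = []
    frozen: dict[str, bool] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise RuleParseError(f"line {lineno}: expected 'NAME = EXPRESSION'")
        lhs, rhs = line.split("=", 1)
        lhs = lhs.strip()
        freeze = False
        if lhs.upper().startswith("FREEZE "):
            freeze = True
            lhs = lhs[len("FREEZE "):].strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", lhs):
            raise RuleParseError(f"line {lineno}: invalid gene name {lhs!r}")
        if freeze:
            rhs = rhs.strip()
            if rhs not in ("0", "1"):
                raise RuleParseError(f"line {lineno}: FREEZE value must be 0 or 1")
            frozen[lhs] = rhs == "1"
            continue
        if lhs in names:
            raise RuleParseError(f"line {lineno}: duplicate definition of {lhs!r}")
        tokens = _tokenize(rhs, lineno)
        asts.append(_Parser(tokens, lineno).parse())
        names.append(lhs)
    if not names:
        raise RuleParseError("no rules found")
    return BooleanNetwork(tuple(names), tuple(asts), frozen)


def find_cycle(net: BooleanNetwork, x0: np.ndarray, max_steps: int | None = None):
    """Iterate the noise-free network from ``x0`` until a state repeats.

    Returns ``(transient_length, cycle_length)``.  The state space is finite so
    this always terminates within ``2**n`` steps; ``max_steps`` (default
    ``2**n``) guards against programming errors.
    """
    if max_steps is None:
        max_steps = 1 << net.n
    x = np.asarray(x0, dtype=bool)
    seen = {int(pack_states(x)): 0}
    for step in range(1, max_steps + 1):
        x = net.evaluate(x)
        idx = int(pack_states(x))
        if idx in seen:
            return seen[idx], step - seen[idx]
        seen[idx] = step
    raise RuntimeError("no cycle found within max_steps (impossible for a "
                       "deterministic finite-state map unless max_steps < 2**n)")
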