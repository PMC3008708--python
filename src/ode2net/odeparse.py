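"""Parsing of ODE systems from XPPAUT-style ``.ode`` files and a native dialect.

An ODE system is a set of first-order equations ``dx_i/dt = f_i(x, k)`` over
species variables ``x`` and symbolic rate parameters ``k``.  Right-hand sides
are held as :mod:`sympy` expressions built from symbols, integer/rational
literals, sums, products, quotients and integer powers — the fragment needed
for mass-action and Michaelian kinetics.  Symbols are classified by the file
structure: a symbol with an equation line is a variable, every other symbol
is a parameter.  Numeric values attached to parameters (``par`` lines) and
initial conditions (``init`` lines) are kept as metadata only; they never
enter symbolic computation, because structure inference requires the
parameters to stay symbolic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from fractions import Fraction
from typing import Callable, Iterable

import sympy as sp

__all__ = [
    "Expression",
    "OdeSystem",
    "OdeParseError",
    "parse_expression",
    "parse_ode_text",
    "to_ode_text",
]

#: Alias for the expression trees used throughout the package.
Expression = sp.Expr


class OdeParseError(ValueError):
    """Syntax or structural error in an ODE file or expression.

    Carries 1-based ``line`` and ``column`` positions when known.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        where = ""
        if line is not None:
            where = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + where)


# ---------------------------------------------------------------------------
# Expression grammar:  expr  := term (('+'|'-') term)*
#                      term  := unary (('*'|'/') unary)*
#                      unary := ('+'|'-') unary | power
#                      power := atom ('^' exponent)?
#                      atom  := NAME | NUMBER | '(' expr ')'
# Exponents must be (possibly parenthesised, possibly negated) integer
# literals; anything else is rejected at parse time.
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<number>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<op>[-+*/^()]))"
)


def _tokenize(text: str, line: int | None = None) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise OdeParseError(f"unexpected character {text[pos:].lstrip()[0]!r}", line, pos + 1)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind) + 1))
        pos = m.end()
    tokens.append(("end", "", len(text) + 1))
    return tokens


def _number_literal(text: str, line: int | None, col: int) -> sp.Rational:
    try:
        return sp.Rational(Fraction(Decimal(text)))
    except InvalidOperation:  # pragma: no cover - tokenizer guarantees shape
        raise OdeParseError(f"bad numeric literal {text!r}", line, col)


class _Parser:
    def __init__(self, tokens, symbols: Callable[[str], sp.Symbol], line: int | None):
        self.tokens = tokens
        self.i = 0
        self.symbols = symbols
        self.line = line

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op: str):
        kind, value, col = self.next()
        if kind != "op" or value != op:
            raise OdeParseError(f"expected {op!r}, found {value!r}", self.line, col)

    def parse(self) -> Expression:
        expr = self.expr()
        kind, value, col = self.peek()
        if kind != "end":
            raise OdeParseError(f"unexpected token {value!r}", self.line, col)
        return expr

    def expr(self) -> Expression:
        node = self.term()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in "+-":
                self.next()
                rhs = self.term()
                node = node + rhs if value == "+" else node - rhs
            else:
                return node

    def term(self) -> Expression:
        node = self.unary()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in "*/":
                self.next()
                rhs = self.unary()
                node = node * rhs if value == "*" else node / rhs
            else:
                return node

    def unary(self) -> Expression:
        kind, value, _ = self.peek()
        if kind == "op" and value in "+-":
            self.next()
            inner = self.unary()
            return inner if value == "+" else -inner
        return self.power()

    def power(self) -> Expression:
        base = self.atom()
        kind, value, _ = self.peek()
        if kind == "op" and value == "^":
            self.next()
            return sp.Pow(base, self.exponent())
        return base

    def exponent(self) -> sp.Integer:
        kind, value, col = self.next()
        if kind == "op" and value in "+-":
            sign = -1 if value == "-" else 1
            return sign * self.exponent()
        if kind == "op" and value == "(":
            inner = self.exponent()
            self.expect_op(")")
            return inner
        if kind == "number":
            num = _number_literal(value, self.line, col)
            if not num.is_Integer:
                raise OdeParseError(f"non-integer exponent {value!r}", self.line, col)
            return num
        raise OdeParseError(f"expected integer exponent, found {value!r}", self.line, col)

    def atom(self) -> Expression:
        kind, value, col = self.next()
        if kind == "name":
            return self.symbols(value)
        if kind == "number":
            return _number_literal(value, self.line, col)
        if kind == "op" and value == "(":
            inner = self.expr()
            self.expect_op(")")
            return inner
        raise OdeParseError(f"unexpected token {value!r}", self.line, col)


def parse_expression(
    text: str,
    symbols: Callable[[str], sp.Symbol] = sp.Symbol,
    line: int | None = None,
) -> Expression:
    """Parse an infix arithmetic expression into a sympy tree.

    Supports ``+ - * / ^`` and parentheses.  Power exponents must be integer
    literals (``A^0.5`` is a parse error); unary minus folds into the numeric
    coefficient of the term it precedes.  ``symbols`` maps an identifier to
    its :class:`sympy.Symbol` — parsers use it to intern names (e.g.
    case-insensitively for the XPPAUT dialect).
    """
    return _Parser(_tokenize(text, line), symbols, line).parse()


# ---------------------------------------------------------------------------
# ODE system container
# ---------------------------------------------------------------------------


@dataclass
class OdeSystem:
    """An ordered system ``dx/dt = f(x, k)``.

    Parameters
    ----------
    variables:
        Species names, in declaration order; one place per variable in the
        inferred net.
    parameters:
        Parameter name -> optional numeric default.  Defaults are metadata
        for serialization only.
    equations:
        Variable name -> right-hand side expression.
    initial_values:
        Variable name -> initial amount, from ``init`` lines (metadata).
    """

    variables: list[str] = field(default_factory=list)
    parameters: dict[str, float | None] = field(default_factory=dict)
    equations: dict[str, Expression] = field(default_factory=dict)
    initial_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`OdeParseError` if broken."""
        if set(self.variables) != set(self.equations):
            raise OdeParseError("every variable must have exactly one equation")
        if len(set(self.variables)) != len(self.variables):
            raise OdeParseError("duplicate variable name")
        overlap = set(self.variables) & set(self.parameters)
        if overlap:
            raise OdeParseError(f"symbols both variable and parameter: {sorted(overlap)}")
        universe = set(self.variables) | set(self.parameters)
        for var, rhs in self.equations.items():
            free = {s.name for s in rhs.free_symbols}
            unknown = free - universe
            if unknown:
                raise OdeParseError(
                    f"equation for {var} uses undeclared symbols {sorted(unknown)}"
                )

    @property
    def variable_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(v) for v in self.variables]


class _SymbolTable:
    """Interns identifiers, optionally case-insensitively (XPPAUT convention).

    The first-seen spelling of each name is kept for output.
    """

    def __init__(self, case_sensitive: bool):
        self.case_sensitive = case_sensitive
        self._names: dict[str, str] = {}

    def key(self, name: str) -> str:
        return name if self.case_sensitive else name.lower()

    def intern(self, name: str) -> str:
        return self._names.setdefault(self.key(name), name)

    def symbol(self, name: str) -> sp.Symbol:
        return sp.Symbol(self.intern(name))


# XPPAUT constructs outside the supported subset, rejected by name.
_XPP_UNSUPPORTED = {
    "table", "global", "wiener", "markov", "volt", "volterra", "special",
    "bndry", "bdry", "solv", "number", "export", "import", "option", "set",
    "derived", "!",
}

_XPP_EQ_D_RE = re.compile(r"^d([A-Za-z_][A-Za-z0-9_]*)/dt\s*=\s*(.*)$", re.IGNORECASE)
_XPP_EQ_PRIME_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)'\s*=\s*(.*)$")
_ASSIGN_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)\s*=\s*([^\s,]+)")


def _parse_assignments(rest: str, line_no: int) -> Iterable[tuple[str, float]]:
    rest = rest.strip()
    if rest and not _ASSIGN_RE.search(rest):
        raise OdeParseError(f"expected name=value pairs, found {rest!r}", line_no)
    for m in _ASSIGN_RE.finditer(rest):
        try:
            value = float(m.group(2))
        except ValueError:
            raise OdeParseError(f"bad numeric value {m.group(2)!r}", line_no)
        yield m.group(1), value


def parse_ode_text(text: str, dialect: str = "xpp") -> OdeSystem:
    """Parse an ODE file into an :class:`OdeSystem`.

    ``dialect='xpp'`` accepts the XPPAUT subset: ``dX/dt=...`` / ``X'=...``
    equation lines, ``par``/``param`` lines (numeric defaults kept as
    metadata), ``init`` lines, ``aux`` (ignored with a warning), ``@``
    option lines, ``#`` comments and ``done``.  Any other XPPAUT construct
    raises :class:`OdeParseError` naming it.  Symbols are compared
    case-insensitively, keeping the first-seen spelling.

    ``dialect='native'`` accepts one ``name' = expr`` per line plus
    ``param:`` header lines; symbols are case-sensitive.
    """
    if dialect not in ("xpp", "native"):
        raise ValueError(f"unknown dialect {dialect!r}")
    table = _SymbolTable(case_sensitive=(dialect == "native"))
    equations: dict[str, Expression] = {}
    declared: dict[str, float | None] = {}
    inits: dict[str, float] = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if dialect == "xpp" and line.lower() == "done":
            break
        if dialect == "xpp" and line.startswith("@"):
            continue

        m = _XPP_EQ_D_RE.match(line) if dialect == "xpp" else None
        if m is None:
            m = _XPP_EQ_PRIME_RE.match(line)
        if m is not None:
            name = table.intern(m.group(1))
            if name in equations:
                raise OdeParseError(f"duplicate equation for {name}", line_no)
            equations[name] = parse_expression(m.group(2), table.symbol, line_no)
            continue

        head, _, rest = line.partition(" ")
        keyword = head.lower()
        if dialect == "native" and line.lower().startswith("param:"):
            rest = line.split(":", 1)[1]
            for part in rest.split(","):
                part = part.strip()
                if not part:
                    continue
                name, _, value = part.partition("=")
                declared[table.intern(name.strip())] = (
                    float(value) if value.strip() else None
                )
            continue
        if dialect == "xpp" and keyword in ("par", "param", "params", "p"):
            for name, value in _parse_assignments(rest, line_no):
                declared[table.intern(name)] = value
            continue
        if dialect == "xpp" and keyword == "init":
            for name, value in _parse_assignments(rest, line_no):
                inits[table.intern(name)] = value
            continue
        if dialect == "xpp" and keyword == "aux":
            warnings.warn(f"ignoring aux definition on line {line_no}: {line!r}")
            continue
        if dialect == "xpp" and (keyword in _XPP_UNSUPPORTED or line.startswith("!")):
            raise OdeParseError(f"unsupported XPPAUT construct {head!r}", line_no)
        raise OdeParseError(f"unrecognized line {line!r}", line_no)

    variables = list(equations)
    conflict = set(variables) & set(declared)
    if conflict:
        raise OdeParseError(
            f"symbols declared as parameters but also equated: {sorted(conflict)}"
        )
    parameters: dict[str, float | None] = dict(declared)
    for rhs in equations.values():
        for sym in rhs.free_symbols:
            if sym.name not in equations:
                parameters.setdefault(sym.name, None)
    initial_values = {n: v for n, v in inits.items() if n in equations}
    return OdeSystem(
        variables=variables,
        parameters=parameters,
        equations=equations,
        initial_values=initial_values,
    )


def format_expression(expr: Expression) -> str:
    """Render an expression in the file syntax (``^`` for powers)."""
    return sp.sstr(expr).replace("**", "^")


def to_ode_text(system: OdeSystem, dialect: str = "xpp") -> str:
    """Serialize an :class:`OdeSystem`; re-parsing yields an equal system."""
    lines: list[str] = []
    if dialect == "xpp":
        for var in system.variables:
            lines.append(f"d{var}/dt={format_expression(system.equations[var])}")
        pars = [
            f"{name}={value:g}" for name, value in system.parameters.items()
            if value is not None
        ]
        if pars:
            lines.append("par " + ", ".join(pars))
        if system.initial_values:
            lines.append(
                "init " + ", ".join(f"{n}={v:g}" for n, v in system.initial_values.items())
            )
        lines.append("done")
    elif dialect == "native":
        withval = [
            f"{n}={v:g}" if v is not None else n for n, v in system.parameters.items()
        ]
        if withval:
            lines.append("param: " + ", ".join(withval))
        for var in system.variables:
            lines.append(f"{var}' = {format_expression(system.equations[var])}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(lines) + "\n"
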