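"""Canonicalization of ODE right-hand sides into rate terms.

Uniqueness of the inferred network rests on the right-hand sides being
polynomials over the variables whose coefficients are integer linear
combinations of symbolic parameters, i.e. sums of terms

    n * k * x1^a1 * ... * xm^am          (mass action)

optionally extended with Michaelian (Michaelis-Menten) terms

    n * k * x1^a1 * ... * xm^am / (Km + S)

with ``n`` a nonzero integer, ``k`` and ``Km`` symbolic parameters and the
substrate ``S`` among the numerator variables.  :func:`canonicalize` fully
expands each equation, classifies every additive term into this shape (or
rejects it with a precise mass-action-condition diagnostic), and merges
terms that denote the same reaction: terms sharing parameter and monomial
(and, for Michaelian terms, Km and substrate) necessarily come from one
transition, so their integer multiplicities are summed per equation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import sympy as sp

from .odeparse import Expression, OdeSystem

__all__ = [
    "Kinetics",
    "Monomial",
    "RateTerm",
    "CanonicalSystem",
    "Diagnostic",
    "DiagnosticCode",
    "Condition1Violation",
    "canonicalize",
    "match_michaelian",
]


class Kinetics(str, enum.Enum):
    """Kind of rate law attached to a term or transition."""

    MASS_ACTION = "mass_action"
    MICHAELIAN = "michaelian"
    #: Whole-RHS rates produced by the naive translation; never admissible.
    OPAQUE = "opaque"


class DiagnosticCode(str, enum.Enum):
    CONDITION1 = "CONDITION1"
    CONDITION2 = "CONDITION2"
    CONDITION3 = "CONDITION3"
    NEGATIVE_POST_WEIGHT = "NEGATIVE_POST_WEIGHT"


@dataclass(frozen=True)
class Diagnostic:
    """Machine-readable record of a condition violation or rejection."""

    code: DiagnosticCode
    detail: str
    context: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ctx = f" [{', '.join(self.context)}]" if self.context else ""
        return f"{self.code.value}: {self.detail}{ctx}"


class Condition1Violation(ValueError):
    """A right-hand side term falls outside mass-action/Michaelian form."""

    def __init__(self, detail: str, term: Expression, variable: str | None = None):
        self.term = term
        self.variable = variable
        self.diagnostic = Diagnostic(
            DiagnosticCode.CONDITION1,
            detail,
            context=tuple(
                x for x in (variable and f"equation d{variable}/dt", f"term {sp.sstr(term)}") if x
            ),
        )
        super().__init__(str(self.diagnostic))


class InferenceError(ValueError):
    """Inference rejected the system; carries the diagnostics."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(str(d) for d in diagnostics))


@dataclass(frozen=True)
class Monomial:
    """A product of variables with positive integer exponents.

    Stored as a sorted exponent table; equality and hashing are
    order-independent.  The empty monomial (constant rate) is allowed.
    """

    items: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def from_dict(exponents: Mapping[str, int]) -> "Monomial":
        for name, e in exponents.items():
            if int(e) < 1:
                raise ValueError(f"exponent of {name} must be >= 1, got {e}")
        return Monomial(tuple(sorted((n, int(e)) for n, e in exponents.items())))

    @property
    def exponents(self) -> dict[str, int]:
        return dict(self.items)

    def degree(self, name: str) -> int:
        return self.exponents.get(name, 0)

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.items)

    def as_sympy(self) -> Expression:
        return sp.Mul(*[sp.Symbol(n) ** e for n, e in self.items])

    def __str__(self) -> str:
        if not self.items:
            return "1"
        return "".join(f"{n}{e if e > 1 else ''}" for n, e in self.items)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.items)


@dataclass
class RateTerm:
    """One canonical term: a single reaction's contribution to the ODEs.

    ``coefficients`` maps each variable to the term's signed integer
    multiplicity in that variable's equation (the eventual ``post - pre``
    stoichiometry); entries are nonzero and the map is non-empty for any
    term that survives merging.
    """

    parameter: str
    kind: Kinetics
    monomial: Monomial
    coefficients: dict[str, int]
    substrate: str | None = None
    km_parameter: str | None = None

    def key(self) -> tuple:
        """Identification key; two terms with equal keys are one reaction."""
        if self.kind is Kinetics.MICHAELIAN:
            return (self.kind.value, self.parameter, self.km_parameter,
                    self.substrate, self.monomial.items)
        return (self.kind.value, self.parameter, self.monomial.items)

    def rate_expression(self) -> Expression:
        """The rate law ``k * monomial`` (over ``Km + S`` if Michaelian)."""
        rate = sp.Symbol(self.parameter) * self.monomial.as_sympy()
        if self.kind is Kinetics.MICHAELIAN:
            rate = rate / (sp.Symbol(self.km_parameter) + sp.Symbol(self.substrate))
        return rate


@dataclass
class CanonicalSystem:
    """An accepted system as a merged, key-unique list of rate terms."""

    variables: list[str]
    terms: list[RateTerm] = field(default_factory=list)

    def as_odes(self) -> OdeSystem:
        """Recombine the terms into an explicit ODE system (for checking)."""
        equations = {v: sp.Integer(0) for v in self.variables}
        params: dict[str, float | None] = {}
        for term in self.terms:
            params.setdefault(term.parameter, None)
            if term.km_parameter:
                params.setdefault(term.km_parameter, None)
            rate = term.rate_expression()
            for var, n in term.coefficients.items():
                equations[var] = equations[var] + n * rate
        return OdeSystem(
            variables=list(self.variables), parameters=params, equations=equations
        )


# ---------------------------------------------------------------------------
# Term classification
# ---------------------------------------------------------------------------


def _numeric_and_core(expr: Expression) -> tuple[sp.Rational, Expression]:
    """Split off the numeric content (works for Add via primitive())."""
    if expr.is_Add:
        c, rest = expr.primitive()
        return sp.Rational(c), rest
    c, rest = expr.as_coeff_Mul(rational=True)
    return sp.Rational(c), rest


def _classify_numerator(
    num: Expression,
    variables: set[str],
    parameters: set[str],
    fold_parameters: bool,
    term: Expression,
    variable: str | None,
) -> tuple[str, Monomial]:
    """Split a numeric-free numerator into (parameter, monomial)."""
    exps: dict[str, int] = {}
    param_factors: list[str] = []
    for base, e in num.as_powers_dict().items():
        if base is sp.S.One:
            continue
        if not base.is_Symbol:
            raise Condition1Violation(
                f"factor {sp.sstr(base)} is not a symbol", term, variable
            )
        if not (e.is_Integer and e > 0):
            raise Condition1Violation(
                f"non-positive or non-integer exponent on {base.name}", term, variable
            )
        if base.name in variables:
            exps[base.name] = int(e)
        elif base.name in parameters:
            param_factors.extend([base.name] * int(e))
        else:  # pragma: no cover - closed symbol universe upstream
            raise Condition1Violation(f"unknown symbol {base.name}", term, variable)
    if not param_factors:
        raise Condition1Violation(
            "no symbolic parameter factor (numeric coefficients alone are not "
            "mass-action rates)", term, variable,
        )
    if len(param_factors) > 1:
        if not fold_parameters:
            raise Condition1Violation(
                f"product of parameters {sorted(param_factors)} in one term "
                "(enable parameter folding to treat it as one compound parameter)",
                term, variable,
            )
        parameter = "_".join(sorted(param_factors))
    else:
        parameter = param_factors[0]
    return parameter, Monomial.from_dict(exps)


def _match_denominator(
    den: Expression, variables: set[str], parameters: set[str]
) -> tuple[str, str] | None:
    """Match ``Km + S`` (one parameter plus one variable, both linear)."""
    if not den.is_Add or len(den.args) != 2:
        return None
    names = []
    for arg in den.args:
        if not arg.is_Symbol:
            return None
        names.append(arg.name)
    pars = [n for n in names if n in parameters]
    svars = [n for n in names if n in variables]
    if len(pars) != 1 or len(svars) != 1:
        return None
    return pars[0], svars[0]


def _classify_term(
    addend: Expression,
    variables: set[str],
    parameters: set[str],
    allow_michaelian: bool,
    fold_parameters: bool,
    variable: str | None = None,
) -> tuple[int, RateTerm]:
    num, den = addend.as_numer_denom()
    ncoeff, num = _numeric_and_core(num)
    dcoeff, den = _numeric_and_core(den)
    coeff = sp.Rational(ncoeff, dcoeff)

    if den == 1:
        if not coeff.is_Integer:
            raise Condition1Violation(
                f"non-integer coefficient {coeff}", addend, variable
            )
        parameter, monomial = _classify_numerator(
            num, variables, parameters, fold_parameters, addend, variable
        )
        return int(coeff), RateTerm(
            parameter=parameter, kind=Kinetics.MASS_ACTION,
            monomial=monomial, coefficients={},
        )

    if not allow_michaelian:
        raise Condition1Violation(
            "denominator present but Michaelian kinetics disabled", addend, variable
        )
    matched = _match_denominator(den, variables, parameters)
    if matched is None:
        raise Condition1Violation(
            f"denominator {sp.sstr(den)} is not of the Michaelian form "
            "(parameter + single variable, both degree one)", addend, variable,
        )
    km, substrate = matched
    if not coeff.is_Integer:
        raise Condition1Violation(f"non-integer coefficient {coeff}", addend, variable)
    parameter, monomial = _classify_numerator(
        num, variables, parameters, fold_parameters, addend, variable
    )
    if monomial.degree(substrate) < 1:
        raise Condition1Violation(
            f"Michaelian substrate {substrate} does not occur in the numerator "
            "(rational term not in recombined form)", addend, variable,
        )
    if km == parameter:
        raise Condition1Violation(
            f"parameter {km} used both as rate constant and Michaelis constant "
            "in one term", addend, variable,
        )
    return int(coeff), RateTerm(
        parameter=parameter, kind=Kinetics.MICHAELIAN, monomial=monomial,
        coefficients={}, substrate=substrate, km_parameter=km,
    )


def match_michaelian(
    term: Expression, variables: set[str], parameters: set[str]
) -> tuple[str, str, str, Monomial] | None:
    """Match one additive term against ``k * monomial / (Km + S)``.

    Returns ``(parameter, km_parameter, substrate, monomial)`` or ``None``.
    Commutative reorderings of the sums/products all match; the integer
    prefactor is ignored here (it is the term's multiplicity).
    """
    try:
        _, rt = _classify_term(term, variables, parameters,
                               allow_michaelian=True, fold_parameters=False)
    except Condition1Violation:
        return None
    if rt.kind is not Kinetics.MICHAELIAN:
        return None
    return rt.parameter, rt.km_parameter, rt.substrate, rt.monomial


def term_sort_key(term: RateTerm) -> tuple:
    return (term.parameter, term.km_parameter or "", term.substrate or "",
            term.monomial.items)


def canonicalize(
    system: OdeSystem,
    allow_michaelian: bool = True,
    fold_parameters: bool = False,
) -> CanonicalSystem:
    """Rewrite an ODE system into merged canonical rate terms.

    Fully expands every right-hand side, classifies each additive term
    (raising :class:`Condition1Violation` on anything outside the admissible
    rate shapes), merges terms with identical identification keys by summing
    their per-equation integer multiplicities, and drops entries/terms whose
    merged multiplicity is zero.  The result is independent of equation
    order and of the ordering of sums and products in the input.

    With ``fold_parameters`` a product of parameters in one term is treated
    as a single compound parameter named by joining the sorted factor names;
    uniqueness then holds over that folded parameter alphabet.
    """
    variables = set(system.variables)
    parameters = set(system.parameters)
    merged: dict[tuple, RateTerm] = {}
    for var in system.variables:
        rhs = sp.expand(system.equations[var])
        if rhs == 0:
            continue
        for addend in sp.Add.make_args(rhs):
            n, rt = _classify_term(
                addend, variables, parameters, allow_michaelian, fold_parameters, var
            )
            slot = merged.setdefault(rt.key(), rt)
            slot.coefficients[var] = slot.coefficients.get(var, 0) + n
    terms = []
    for rt in merged.values():
        rt.coefficients = {v: n for v, n in rt.coefficients.items() if n != 0}
        if rt.coefficients:
            terms.append(rt)
    terms.sort(key=term_sort_key)
    return CanonicalSystem(variables=list(system.variables), terms=terms)
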