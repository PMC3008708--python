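"""Construction of the unique continuous Petri net from canonical rate terms.

A continuous Petri net (CPN) has one place per species and one transition
per reaction; Pre and Post weight vectors give reactant and product
stoichiometries, and each transition carries a symbolic-rate kinetic law
whose variables are restricted to its pre-places.  Under three conditions —
mass-action/Michaelian symbolic kinetics, no void reaction (Pre = Post), and
no parameter reused for two reactions with identical reactants — a system of
ODEs determines at most one such net.  The construction is direct: each
canonical term yields a transition whose Pre weights are the monomial
exponents (mass action) and whose Post weights are Pre plus the term's
signed multiplicity per equation; a negative Post weight proves that no
admissible net generates the system, and the input is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy as sp

from .canonical import (
    CanonicalSystem,
    Diagnostic,
    DiagnosticCode,
    InferenceError,
    Kinetics,
    Monomial,
    RateTerm,
    term_sort_key,
)
from .odeparse import Expression, OdeSystem

__all__ = [
    "Transition",
    "CPNet",
    "Diagnostic",
    "DiagnosticCode",
    "InferenceError",
    "infer_net",
    "verify_conditions",
    "naive_net",
]


@dataclass
class Transition:
    """A reaction: Pre/Post arc weights plus a symbolic rate law.

    For MASS_ACTION the rate is ``parameter * prod(x^pre(x))`` — Pre *is*
    the rate monomial.  For MICHAELIAN the rate is
    ``parameter * prod(x^monomial(x)) / (km_parameter + substrate)``; the
    Pre weights may exceed the monomial exponents (stoichiometry is not tied
    to the saturating rate), so the monomial is stored explicitly.  OPAQUE
    transitions (naive whole-RHS translation) carry an arbitrary ``rate``
    expression and are outside the admissible class.
    """

    id: str
    kind: Kinetics
    parameter: str | None
    pre: dict[str, int] = field(default_factory=dict)
    post: dict[str, int] = field(default_factory=dict)
    km_parameter: str | None = None
    substrate: str | None = None
    monomial: Monomial | None = None
    rate: Expression | None = None  # OPAQUE only

    def rate_expression(self) -> Expression:
        if self.kind is Kinetics.OPAQUE:
            return self.rate
        if self.kind is Kinetics.MASS_ACTION:
            mono = sp.Mul(*[sp.Symbol(x) ** w for x, w in sorted(self.pre.items())])
            return sp.Symbol(self.parameter) * mono
        mono = self.monomial.as_sympy()
        return (sp.Symbol(self.parameter) * mono
                / (sp.Symbol(self.km_parameter) + sp.Symbol(self.substrate)))

    def rate_variables(self) -> set[str]:
        """Variables occurring in the rate law (must be pre-places)."""
        if self.kind is Kinetics.OPAQUE:
            return {s.name for s in self.rate.free_symbols if s.name in self.pre}
        if self.kind is Kinetics.MASS_ACTION:
            return set(self.pre)
        return set(self.monomial.support) | {self.substrate}

    def signature(self) -> tuple:
        """Identity up to transition id, for net comparison."""
        return (
            self.kind.value,
            self.parameter,
            self.km_parameter,
            self.substrate,
            self.monomial.items if self.monomial is not None else None,
            tuple(sorted((x, w) for x, w in self.pre.items() if w)),
            tuple(sorted((x, w) for x, w in self.post.items() if w)),
        )


@dataclass
class CPNet:
    """Places plus transitions; the output of structure inference."""

    places: list[str]
    transitions: list[Transition] = field(default_factory=list)


def _transition_id(term: RateTerm) -> str:
    parts = ["t", term.parameter]
    if term.km_parameter:
        parts.append(term.km_parameter)
    parts.append(str(term.monomial))
    return "_".join(parts)


def infer_net(canon: CanonicalSystem) -> CPNet:
    """Build the unique admissible CPN for a canonical system.

    Pre weights: the monomial exponents for mass-action terms; for
    Michaelian terms the minimal weights compatible with nonnegative Post
    and with the rate variables being pre-places, i.e.
    ``pre(x) = max(monomial(x), -coefficient(x), [1 if x is the substrate])``
    (a documented convention — the saturating rate does not pin Pre down).
    Post weights are ``pre(x) + coefficient(x)`` everywhere.

    Raises
    ------
    InferenceError
        With a NEGATIVE_POST_WEIGHT diagnostic when some Post weight would
        be negative (no admissible net exists), or with CONDITION2/3
        diagnostics if the constructed net violates them.
    """
    transitions: list[Transition] = []
    used_ids: dict[str, int] = {}
    for term in sorted(canon.terms, key=term_sort_key):
        exps = term.monomial.exponents
        support = set(exps) | set(term.coefficients)
        if term.kind is Kinetics.MICHAELIAN:
            support |= {term.substrate}
        pre: dict[str, int] = {}
        post: dict[str, int] = {}
        for x in support:
            if term.kind is Kinetics.MASS_ACTION:
                w = exps.get(x, 0)
            else:
                w = max(exps.get(x, 0), -term.coefficients.get(x, 0),
                        1 if x == term.substrate else 0)
            p = w + term.coefficients.get(x, 0)
            if p < 0:
                raise InferenceError([Diagnostic(
                    DiagnosticCode.NEGATIVE_POST_WEIGHT,
                    f"place {x}: pre weight {w} plus coefficient "
                    f"{term.coefficients.get(x, 0)} gives negative post weight {p}",
                    context=(f"term {term.parameter}*{term.monomial}",),
                )])
            if w:
                pre[x] = w
            if p:
                post[x] = p
        tid = _transition_id(term)
        if tid in used_ids:  # disambiguate folded/colliding names deterministically
            used_ids[tid] += 1
            tid = f"{tid}_{used_ids[tid]}"
        else:
            used_ids[tid] = 0
        transitions.append(Transition(
            id=tid, kind=term.kind, parameter=term.parameter, pre=pre, post=post,
            km_parameter=term.km_parameter, substrate=term.substrate,
            monomial=term.monomial if term.kind is Kinetics.MICHAELIAN else None,
        ))
    net = CPNet(places=list(canon.variables), transitions=transitions)
    problems = verify_conditions(net)
    if problems:
        raise InferenceError(problems)
    return net


def verify_conditions(net: CPNet) -> list[Diagnostic]:
    """Check the no-void-reaction and parameter-reuse conditions on any net.

    Returns one CONDITION2 diagnostic per void transition (Pre = Post as
    weight vectors — catalysts with some other net effect are fine) and one
    CONDITION3 diagnostic per pair of distinct transitions sharing
    (parameter, Pre).  An empty list means the net is admissible.
    """
    diagnostics: list[Diagnostic] = []
    for t in net.transitions:
        pre = {x: w for x, w in t.pre.items() if w}
        post = {x: w for x, w in t.post.items() if w}
        if pre == post:
            diagnostics.append(Diagnostic(
                DiagnosticCode.CONDITION2,
                f"transition {t.id} is a void reaction (identical reactants "
                "and products)", context=(t.id,),
            ))
    seen: dict[tuple, str] = {}
    for t in net.transitions:
        key = (t.parameter, tuple(sorted((x, w) for x, w in t.pre.items() if w)))
        if key in seen:
            diagnostics.append(Diagnostic(
                DiagnosticCode.CONDITION3,
                f"parameter {t.parameter} used for two reactions with the same "
                f"reactants ({seen[key]}, {t.id})", context=(seen[key], t.id),
            ))
        else:
            seen[key] = t.id
    return diagnostics


def naive_net(system: OdeSystem) -> CPNet:
    """Whole-RHS translation: one opaque transition per equation.

    Every variable of the right-hand side becomes a pre-place with weight 1
    and an identical post-place, except the equation's own variable whose
    post weight is pre + 1; the untouched right-hand side is the rate.  This
    always works but hides all structure in the kinetics; it is provided as
    the baseline the structured inference improves on, and is marked OPAQUE
    (outside the admissible class).
    """
    variables = set(system.variables)
    transitions = []
    for var in system.variables:
        rhs = system.equations[var]
        if rhs == 0:
            continue
        deps = sorted(s.name for s in rhs.free_symbols if s.name in variables)
        pre = {x: 1 for x in deps}
        post = dict(pre)
        post[var] = pre.get(var, 0) + 1
        transitions.append(Transition(
            id=f"t_naive_{var}", kind=Kinetics.OPAQUE, parameter=None,
            pre=pre, post=post, rate=rhs,
        ))
    return CPNet(places=list(system.variables), transitions=transitions)
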