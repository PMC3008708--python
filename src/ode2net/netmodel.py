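"""Forward semantics of a CPN and the equivalence oracles.

A net defines its ODE system exactly: for every place ``x``,
``dx/dt = sum_t (Post(x,t) - Pre(x,t)) * v_t`` with ``v_t`` the transition's
rate law.  This regeneration is the ground truth for all round-trip checks:
inference is sound iff regenerating the inferred net's ODEs gives back the
input system up to basic arithmetic, which :func:`systems_equivalent`
decides exactly by common-denominator polynomial comparison (no numeric
sampling — the systems are small and symbolic).
"""

from __future__ import annotations

import sympy as sp

from .infer import CPNet
from .odeparse import OdeSystem

__all__ = ["net_to_odes", "systems_equivalent", "nets_equal"]


def net_to_odes(net: CPNet) -> OdeSystem:
    """Regenerate the ODE system a net defines.

    Raises ``ValueError`` if some transition's rate law mentions a variable
    that is not one of its pre-places (a structurally ill-formed net).
    """
    places = set(net.places)
    equations = {x: sp.Integer(0) for x in net.places}
    parameters: dict[str, float | None] = {}
    for t in net.transitions:
        rate = t.rate_expression()
        rate_places = {s.name for s in rate.free_symbols if s.name in places}
        missing = rate_places - {x for x, w in t.pre.items() if w}
        if missing:
            raise ValueError(
                f"rate of transition {t.id} uses non-pre-place variables "
                f"{sorted(missing)}"
            )
        for s in rate.free_symbols:
            if s.name not in places:
                parameters.setdefault(s.name, None)
        for x in set(t.pre) | set(t.post):
            delta = t.post.get(x, 0) - t.pre.get(x, 0)
            if delta:
                equations[x] = equations[x] + delta * rate
    return OdeSystem(
        variables=list(net.places), parameters=parameters, equations=equations
    )


def systems_equivalent(a: OdeSystem, b: OdeSystem) -> bool:
    """Exact symbolic equality of two systems, up to basic arithmetic.

    Requires identical variable sets; for each variable the difference of
    the right-hand sides is brought over a common denominator and the
    expanded numerator compared with zero.
    """
    if set(a.variables) != set(b.variables):
        raise ValueError(
            f"variable sets differ: {sorted(a.variables)} vs {sorted(b.variables)}"
        )
    for var in a.variables:
        diff = sp.together(a.equations[var] - b.equations[var])
        num, _den = diff.as_numer_denom()
        if sp.expand(num) != 0:
            return False
    return True


def nets_equal(a: CPNet, b: CPNet) -> bool:
    """Structural equality up to transition ids and ordering.

    True iff the place sets coincide and there is a bijection between the
    transition lists matching kind, parameter(s), substrate, rate monomial,
    and the Pre/Post weight vectors exactly.  Opaque rates are compared
    symbolically.
    """
    if set(a.places) != set(b.places):
        return False
    if len(a.transitions) != len(b.transitions):
        return False

    def sig(t):
        s = t.signature()
        if t.rate is not None:
            s = s + (sp.srepr(sp.expand(t.rate)),)
        return s

    return sorted(map(sig, a.transitions)) == sorted(map(sig, b.transitions))
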