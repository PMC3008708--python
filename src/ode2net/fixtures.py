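"""Deterministic generators of admissible nets and condition counterexamples.

`random_cpn` draws nets that satisfy the three admissibility conditions by
construction — every transition gets a fresh rate parameter (so no parameter
is ever reused for two reactions with the same reactants), weight vectors
are redrawn until Pre differs from Post (no void reaction), and Michaelian
transitions get a fresh Michaelis constant and a substrate with Pre weight
at least 1.  These nets drive the round-trip property suites: regenerating
their ODEs and re-inferring must give the same net back.

`counterexample_suite` returns the four behavioural scenarios that delimit
the method: the minimal uniquely-invertible decay/production system; a
numeric-coefficient system with no symbolic parameter (mass-action condition
violated); a net reusing one parameter for two reactions with the same
reactant (which regenerates the very same decay/production ODEs — the
ambiguity the reuse ban removes); and a system whose term consumes more of
a species than its rate order allows, so no nonnegative product
stoichiometry exists.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .canonical import DiagnosticCode, Kinetics, Monomial
from .infer import CPNet, Transition
from .odeparse import OdeSystem, parse_ode_text

__all__ = ["FixtureConfig", "Scenario", "random_cpn", "counterexample_suite"]

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class FixtureConfig:
    """Shape of a randomly generated net."""

    n_places: int = 5
    n_transitions: int = 8
    max_weight: int = 3
    michaelian_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_places < 1 or self.n_transitions < 0 or self.max_weight < 1:
            raise ValueError("invalid fixture bounds")
        if not 0.0 <= self.michaelian_fraction <= 1.0:
            raise ValueError("michaelian_fraction must be in [0, 1]")


def random_cpn(config: FixtureConfig) -> CPNet:
    """Draw an admissible net; identical configs give identical nets.

    Weight vectors are rejection-sampled (bounded retries) until the
    transition is not void and, for Michaelian kinds, some place has Pre
    weight >= 1 to serve as substrate.  The Michaelian rate monomial is the
    full Pre vector, keeping rate variables exactly the pre-places.
    """
    rng = random.Random(config.seed)
    places = [f"x{i + 1}" for i in range(config.n_places)]
    transitions: list[Transition] = []
    for j in range(config.n_transitions):
        michaelian = rng.random() < config.michaelian_fraction
        for attempt in range(_MAX_REDRAWS):
            pre = {x: rng.randint(0, config.max_weight) for x in places}
            post = {x: rng.randint(0, config.max_weight) for x in places}
            if pre == post:
                continue
            if michaelian and not any(pre.values()):
                continue
            break
        else:
            raise RuntimeError("could not draw a non-void transition")
        pre = {x: w for x, w in pre.items() if w}
        post = {x: w for x, w in post.items() if w}
        parameter = f"k{j + 1}"
        if michaelian:
            substrate = rng.choice(sorted(pre))
            transitions.append(Transition(
                id=f"t{j + 1}", kind=Kinetics.MICHAELIAN, parameter=parameter,
                pre=pre, post=post, km_parameter=f"K{j + 1}", substrate=substrate,
                monomial=Monomial.from_dict(pre),
            ))
        else:
            transitions.append(Transition(
                id=f"t{j + 1}", kind=Kinetics.MASS_ACTION, parameter=parameter,
                pre=pre, post=post,
            ))
    return CPNet(places=places, transitions=transitions)


@dataclass(frozen=True)
class Scenario:
    """One behavioural contract: a system or net with its expected outcome.

    ``expected`` is None when conversion must succeed, otherwise the
    diagnostic code the pipeline must report.  Net-level scenarios carry a
    ``net`` instead of a ``system``.
    """

    name: str
    description: str
    expected: DiagnosticCode | None
    system: OdeSystem | None = None
    net: CPNet | None = None


def _system(text: str) -> OdeSystem:
    return parse_ode_text(text, dialect="xpp")


def counterexample_suite() -> list[Scenario]:
    """The four delimiting scenarios (systems reconstructed from their
    published descriptions; net weights are the minimal instances)."""
    decay_production = _system("dA/dt=-k*A\ndB/dt=k*A\ndone\n")

    # Reconstruction: same parameter k on two reactions with reactant A
    # (A -> A+B and A -> nothing, both at rate k*A); regenerates exactly the
    # decay/production ODEs above, so the structure would be ambiguous.
    reused_parameter_net = CPNet(
        places=["A", "B"],
        transitions=[
            Transition(id="t1", kind=Kinetics.MASS_ACTION, parameter="k",
                       pre={"A": 1}, post={"A": 1, "B": 1}),
            Transition(id="t2", kind=Kinetics.MASS_ACTION, parameter="k",
                       pre={"A": 1}, post={}),
        ],
    )

    return [
        Scenario(
            name="unique_decay_production",
            description="dA/dt=-k*A, dB/dt=k*A has exactly one admissible "
                        "net: A -(k*A)-> B with unit weights",
            expected=None,
            system=decay_production,
        ),
        Scenario(
            name="numeric_coefficient",
            description="dA/dt=2*A carries no symbolic parameter; without "
                        "one the structure is not unique (reconstruction)",
            expected=DiagnosticCode.CONDITION1,
            system=_system("dA/dt=2*A\ndone\n"),
        ),
        Scenario(
            name="parameter_reuse",
            description="one parameter on two reactions with the same "
                        "reactant regenerates the decay/production ODEs "
                        "(reconstruction of the published net)",
            expected=DiagnosticCode.CONDITION3,
            net=reused_parameter_net,
        ),
        Scenario(
            name="negative_post_weight",
            description="dA/dt=-2*k*A: rate order 1 but consumption 2, so "
                        "the product weight would be -1 (reconstruction)",
            expected=DiagnosticCode.NEGATIVE_POST_WEIGHT,
            system=_system("dA/dt=-2*k*A\ndone\n"),
        ),
    ]
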