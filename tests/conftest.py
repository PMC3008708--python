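import random

import pytest
import sympy as sp

from ode2net import (
    FixtureConfig,
    OdeSystem,
    parse_ode_text,
    random_cpn,
)
from ode2net.odeparse import format_expression


@pytest.fixture
def decay_production() -> OdeSystem:
    """The minimal uniquely-invertible system: A decays, B is produced."""
    return parse_ode_text("dA/dt=-k*A\ndB/dt=k*A\npar k=0.1\ndone\n")


@pytest.fixture
def michaelis_menten() -> OdeSystem:
    """Saturating conversion of a substrate into a product."""
    return parse_ode_text(
        "dS/dt=-Vm*S/(Km+S)\ndP/dt=Vm*S/(Km+S)\npar Vm=1, Km=0.5\ndone\n"
    )


ACCEPTED_CORPUS: dict[str, str] = {
    "decay_production": "dA/dt=-k*A\ndB/dt=k*A\ndone\n",
    "dimerization": "dA/dt=-2*k*A^2\ndB/dt=k*A^2\ndone\n",
    "autocatalysis": "dA/dt=k*A^2\ndone\n",
    "constant_source": "dA/dt=k\ndone\n",
    "reversible_binding": (
        "dA/dt=-kon*A*B+koff*C\ndB/dt=-kon*A*B+koff*C\ndC/dt=kon*A*B-koff*C\ndone\n"
    ),
    "catalyzed_mass_action": "dE/dt=0\ndS/dt=-k*E*S\ndP/dt=k*E*S\ndone\n",
    "michaelis_menten": "dS/dt=-Vm*S/(Km+S)\ndP/dt=Vm*S/(Km+S)\ndone\n",
    "catalyzed_michaelian": (
        "dE/dt=0\ndS/dt=-kcat*E*S/(Km+S)\ndP/dt=kcat*E*S/(Km+S)\ndone\n"
    ),
    "mixed_kinetics": (
        "dS/dt=ks-kd*S-Vm*S/(Km+S)\ndP/dt=Vm*S/(Km+S)-kp*P\ndone\n"
    ),
}


@pytest.fixture(params=sorted(ACCEPTED_CORPUS), ids=sorted(ACCEPTED_CORPUS))
def accepted_system(request) -> OdeSystem:
    """A corpus of systems the inference must accept and invert soundly."""
    return parse_ode_text(ACCEPTED_CORPUS[request.param])


def make_random_net(seed: int, michaelian_fraction: float = 0.3):
    """An admissible random net at the scale the property suites use."""
    rng = random.Random(seed)
    config = FixtureConfig(
        n_places=rng.randint(1, 10),
        n_transitions=rng.randint(0, 15),
        max_weight=4,
        michaelian_fraction=michaelian_fraction,
        seed=seed,
    )
    return random_cpn(config)


def permuted_ode_text(system: OdeSystem, rng: random.Random) -> str:
    """Re-render a system with equations and additive terms shuffled."""
    lines = []
    for var in system.variables:
        terms = list(sp.Add.make_args(sp.expand(system.equations[var])))
        rendered = [f"({format_expression(t)})" for t in terms]
        rng.shuffle(rendered)
        lines.append(f"d{var}/dt=" + "+".join(rendered))
    rng.shuffle(lines)
    return "\n".join(lines) + "\ndone\n"
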