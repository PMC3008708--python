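import random

import pytest
import sympy as sp

from ode2net import (
    CPNet,
    Monomial,
    infer_net,
    Kinetics,
    OdeSystem,
    Transition,
    canonicalize,
    net_to_odes,
    nets_equal,
    parse_ode_text,
    systems_equivalent,
)

from conftest import make_random_net

k, A, B, Km, S, Vm = sp.symbols("k A B Km S Vm")


def simple_net(**overrides):
    kwargs = dict(id="t1", kind=Kinetics.MASS_ACTION, parameter="k",
                  pre={"A": 1}, post={"B": 1})
    kwargs.update(overrides)
    return CPNet(places=["A", "B"], transitions=[Transition(**kwargs)])


class TestNetToOdes:
    def test_decay_production(self):
        system = net_to_odes(simple_net())
        assert system.equations == {"A": -k * A, "B": k * A}

    def test_no_transitions_all_zero(self):
        system = net_to_odes(CPNet(places=["A", "B"]))
        assert all(rhs == 0 for rhs in system.equations.values())

    def test_autocatalytic_weights(self):
        net = CPNet(places=["A"], transitions=[Transition(
            id="t1", kind=Kinetics.MASS_ACTION, parameter="k",
            pre={"A": 2}, post={"A": 3},
        )])
        system = net_to_odes(net)
        assert system.equations["A"] == k * A**2

    def test_michaelian_rate(self):
        net = CPNet(places=["S", "P"], transitions=[Transition(
            id="t1", kind=Kinetics.MICHAELIAN, parameter="Vm",
            km_parameter="Km", substrate="S",
            monomial=Monomial.from_dict({"S": 1}),
            pre={"S": 1}, post={"P": 1},
        )])
        system = net_to_odes(net)
        assert system.equations["S"] == -Vm * S / (Km + S)

    def test_rate_variable_must_be_pre_place(self):
        net = simple_net(pre={})  # rate k*... with no pre-places at all
        net.transitions[0].kind = Kinetics.OPAQUE
        net.transitions[0].rate = k * A
        net.transitions[0].post = {"B": 1}
        with pytest.raises(ValueError, match="non-pre-place"):
            net_to_odes(net)

    @pytest.mark.parametrize("seed", range(10))
    def test_linear_in_transitions(self, seed):
        """Adding a transition adds exactly its (post-pre)*rate contribution."""
        net = make_random_net(seed)
        if not net.transitions:
            return
        extra = net.transitions[-1]
        base = CPNet(places=net.places, transitions=net.transitions[:-1])
        full = net_to_odes(net)
        partial = net_to_odes(base)
        rate = extra.rate_expression()
        for x in net.places:
            delta = extra.post.get(x, 0) - extra.pre.get(x, 0)
            assert sp.expand(
                full.equations[x] - partial.equations[x] - delta * rate
            ) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_no_term_key_collisions_for_admissible_nets(self, seed):
        """Distinct transitions of an admissible net never produce terms
        with the same (parameter, monomial) identification key."""
        net = make_random_net(seed)
        canon = canonicalize(net_to_odes(net))
        keys = [t.key() for t in canon.terms]
        assert len(keys) == len(set(keys))


class TestSystemsEquivalent:
    def sys(self, text):
        return parse_ode_text(text)

    def test_distributivity(self):
        a = self.sys("dA/dt=k*(A+B)\ndB/dt=0\ndone")
        b = self.sys("dA/dt=k*A+k*B\ndB/dt=0\ndone")
        assert systems_equivalent(a, b)

    def test_different_systems(self):
        a = self.sys("dA/dt=k*A\ndB/dt=0\ndone")
        b = self.sys("dA/dt=k*B\ndB/dt=0\ndone")
        assert not systems_equivalent(a, b)

    def test_partial_fraction_identity(self):
        a = OdeSystem(variables=["S"], parameters={"Vm": None, "Km": None},
                      equations={"S": Vm * S / (Km + S)})
        b = OdeSystem(variables=["S"], parameters={"Vm": None, "Km": None},
                      equations={"S": Vm - Vm * Km / (Km + S)})
        assert systems_equivalent(a, b)

    def test_variable_set_mismatch(self):
        a = self.sys("dA/dt=k*A\ndone")
        b = self.sys("dB/dt=k*B\ndone")
        with pytest.raises(ValueError, match="variable sets differ"):
            systems_equivalent(a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_equivalence_relation(self, seed):
        nets = [make_random_net(seed * 3 + i) for i in range(3)]
        places = nets[0].places
        systems = [
            net_to_odes(CPNet(places=places, transitions=[
                t for t in n.transitions
                if set(t.pre) | set(t.post) <= set(places)
            ]))
            for n in nets
        ]
        a, b, c = systems
        assert systems_equivalent(a, a)  # reflexive
        assert systems_equivalent(a, b) == systems_equivalent(b, a)  # symmetric
        if systems_equivalent(a, b) and systems_equivalent(b, c):
            assert systems_equivalent(a, c)  # transitive


class TestNetsEqual:
    def test_permutation_invariance(self):
        net = make_random_net(3)
        shuffled = CPNet(places=list(reversed(net.places)),
                         transitions=list(reversed(net.transitions)))
        assert nets_equal(net, shuffled)

    def test_weight_difference_detected(self):
        a = simple_net()
        b = simple_net(post={"B": 2})
        assert not nets_equal(a, b)

    def test_kind_difference_detected(self):
        a = simple_net()
        b = simple_net(kind=Kinetics.MICHAELIAN, km_parameter="Km",
                       substrate="A",
                       monomial=Monomial.from_dict({"A": 1}))
        assert not nets_equal(a, b)

    def test_inferred_matches_hand_built(self, decay_production):
        inferred = infer_net(canonicalize(decay_production))
        assert nets_equal(inferred, simple_net())
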