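import pytest

from ode2net import (
    CanonicalSystem,
    CPNet,
    DiagnosticCode,
    InferenceError,
    Kinetics,
    Monomial,
    RateTerm,
    Transition,
    canonicalize,
    infer_net,
    naive_net,
    net_to_odes,
    parse_ode_text,
    systems_equivalent,
    verify_conditions,
)


def mass_action_term(parameter, monomial, coefficients):
    return RateTerm(parameter=parameter, kind=Kinetics.MASS_ACTION,
                    monomial=Monomial.from_dict(monomial), coefficients=coefficients)


class TestInferNet:
    def test_single_decay_production_transition(self):
        canon = CanonicalSystem(
            variables=["A", "B"],
            terms=[mass_action_term("k", {"A": 1}, {"A": -1, "B": 1})],
        )
        net = infer_net(canon)
        assert net.places == ["A", "B"]
        (t,) = net.transitions
        assert (t.pre, t.post) == ({"A": 1}, {"B": 1})
        assert t.id == "t_k_A"

    def test_empty_system_gives_empty_net(self):
        net = infer_net(CanonicalSystem(variables=["A"], terms=[]))
        assert net.places == ["A"] and net.transitions == []

    def test_second_order_consumption(self):
        canon = CanonicalSystem(
            variables=["A", "B"],
            terms=[mass_action_term("k", {"A": 2}, {"A": -2, "B": 1})],
        )
        net = infer_net(canon)
        (t,) = net.transitions
        assert (t.pre, t.post) == ({"A": 2}, {"B": 1})
        # oracle: the net regenerates dA/dt = -2kA^2, dB/dt = kA^2
        regenerated = net_to_odes(net)
        expected = parse_ode_text("dA/dt=-2*k*A^2\ndB/dt=k*A^2\ndone")
        assert systems_equivalent(regenerated, expected)

    def test_negative_post_weight_rejected(self):
        canon = CanonicalSystem(
            variables=["A"], terms=[mass_action_term("k", {"A": 1}, {"A": -2})]
        )
        with pytest.raises(InferenceError) as exc:
            infer_net(canon)
        assert [d.code for d in exc.value.diagnostics] == [
            DiagnosticCode.NEGATIVE_POST_WEIGHT
        ]

    def test_michaelian_pre_weights_follow_max_rule(self):
        term = RateTerm(
            parameter="Vm", kind=Kinetics.MICHAELIAN,
            monomial=Monomial.from_dict({"S": 1}),
            coefficients={"S": -2, "P": 1},
            substrate="S", km_parameter="Km",
        )
        net = infer_net(CanonicalSystem(variables=["S", "P"], terms=[term]))
        (t,) = net.transitions
        # consumption of 2 exceeds the rate order 1: pre = max(1, 2, 1) = 2
        assert (t.pre, t.post) == ({"S": 2}, {"P": 1})
        assert t.monomial == Monomial.from_dict({"S": 1})

    def test_deterministic_ids_and_order(self):
        terms = [
            mass_action_term("k2", {"B": 1}, {"B": -1}),
            mass_action_term("k1", {"A": 1}, {"A": -1, "B": 1}),
        ]
        net_a = infer_net(CanonicalSystem(variables=["A", "B"], terms=terms))
        net_b = infer_net(CanonicalSystem(variables=["A", "B"], terms=terms[::-1]))
        assert [t.id for t in net_a.transitions] == ["t_k1_A", "t_k2_B"]
        assert [t.id for t in net_a.transitions] == [t.id for t in net_b.transitions]


class TestVerifyConditions:
    def test_void_transition_reported(self):
        net = CPNet(places=["A"], transitions=[Transition(
            id="t1", kind=Kinetics.MASS_ACTION, parameter="k",
            pre={"A": 1}, post={"A": 1},
        )])
        (diag,) = verify_conditions(net)
        assert diag.code is DiagnosticCode.CONDITION2
        assert "t1" in diag.context

    def test_parameter_reuse_reported(self):
        net = CPNet(places=["A", "B", "C"], transitions=[
            Transition(id="t1", kind=Kinetics.MASS_ACTION, parameter="k",
                       pre={"A": 1}, post={"B": 1}),
            Transition(id="t2", kind=Kinetics.MASS_ACTION, parameter="k",
                       pre={"A": 1}, post={"C": 1}),
        ])
        (diag,) = verify_conditions(net)
        assert diag.code is DiagnosticCode.CONDITION3
        assert set(diag.context) == {"t1", "t2"}

    def test_admissible_net_clean(self):
        net = CPNet(places=["A", "B"], transitions=[
            Transition(id="t1", kind=Kinetics.MASS_ACTION, parameter="k1",
                       pre={"A": 1}, post={"B": 1}),
            Transition(id="t2", kind=Kinetics.MASS_ACTION, parameter="k2",
                       pre={"A": 1}, post={"B": 1}),
        ])
        assert verify_conditions(net) == []

    def test_catalyst_is_not_void(self):
        net = CPNet(places=["E", "S", "P"], transitions=[Transition(
            id="t1", kind=Kinetics.MASS_ACTION, parameter="k",
            pre={"E": 1, "S": 1}, post={"E": 1, "P": 1},
        )])
        assert verify_conditions(net) == []

    def test_inferred_nets_always_admissible(self, accepted_system):
        net = infer_net(canonicalize(accepted_system))
        assert verify_conditions(net) == []


class TestNaiveNet:
    def test_one_opaque_transition_per_equation(self, decay_production):
        net = naive_net(decay_production)
        assert [t.kind for t in net.transitions] == [Kinetics.OPAQUE] * 2
        rates = {str(t.rate) for t in net.transitions}
        assert rates == {"-A*k", "A*k"}
        # the naive construction regenerates the input too
        assert systems_equivalent(net_to_odes(net), decay_production)

    def test_empty_system(self):
        assert naive_net(parse_ode_text("")).transitions == []

    def test_constant_source(self):
        net = naive_net(parse_ode_text("dA/dt=k\ndone"))
        (t,) = net.transitions
        assert (t.pre, t.post) == ({}, {"A": 1})

    def test_marked_outside_admissible_class(self, decay_production):
        net = naive_net(decay_production)
        # the naive net of this system hides k*A in two opaque rates and is
        # never admissible: its own-variable bump makes a void-free but
        # parameterless structure outside the mass-action class
        assert all(t.parameter is None for t in net.transitions)
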