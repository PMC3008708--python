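import random

import pytest
import sympy as sp

from ode2net import (
    Condition1Violation,
    Kinetics,
    Monomial,
    canonicalize,
    match_michaelian,
    net_to_odes,
    parse_expression,
    parse_ode_text,
    systems_equivalent,
)

from conftest import make_random_net, permuted_ode_text


def term_view(t):
    return (t.parameter, t.kind, dict(t.monomial), t.coefficients,
            t.km_parameter, t.substrate)


class TestCanonicalize:
    def test_single_mass_action_term(self, decay_production):
        canon = canonicalize(decay_production)
        assert [term_view(t) for t in canon.terms] == [
            ("k", Kinetics.MASS_ACTION, {"A": 1}, {"A": -1, "B": 1}, None, None)
        ]

    def test_cancellation_removes_term(self):
        system = parse_ode_text("dA/dt=k*A-k*A\ndone")
        assert canonicalize(system).terms == []

    def test_numeric_coefficient_rejected(self):
        system = parse_ode_text("dA/dt=2*A\ndone")
        with pytest.raises(Condition1Violation, match="no symbolic parameter"):
            canonicalize(system)

    def test_michaelian_term(self, michaelis_menten):
        canon = canonicalize(michaelis_menten)
        assert [term_view(t) for t in canon.terms] == [
            ("Vm", Kinetics.MICHAELIAN, {"S": 1}, {"S": -1, "P": 1}, "Km", "S")
        ]
        # oracle: recombining the term reproduces the input exactly
        assert systems_equivalent(canon.as_odes(), michaelis_menten)

    def test_michaelian_disabled(self, michaelis_menten):
        with pytest.raises(Condition1Violation, match="Michaelian kinetics disabled"):
            canonicalize(michaelis_menten, allow_michaelian=False)

    def test_non_integer_rational_coefficient_rejected(self):
        system = parse_ode_text("dA/dt=-0.5*k*A\ndone")
        with pytest.raises(Condition1Violation, match="non-integer coefficient"):
            canonicalize(system)

    def test_variable_in_plain_denominator_rejected(self):
        system = parse_ode_text("dA/dt=-k*A/B\ndB/dt=0\ndone")
        with pytest.raises(Condition1Violation, match="denominator"):
            canonicalize(system)

    def test_negative_variable_exponent_rejected(self):
        system = parse_ode_text("dA/dt=-k*A^(-1)\ndone")
        with pytest.raises(Condition1Violation):
            canonicalize(system)

    def test_parameter_product_strict_vs_folded(self):
        system = parse_ode_text("dA/dt=-k2*k1*A\ndB/dt=k1*k2*A\ndone")
        with pytest.raises(Condition1Violation, match="product of parameters"):
            canonicalize(system)
        canon = canonicalize(system, fold_parameters=True)
        (term,) = canon.terms
        assert term.parameter == "k1_k2"  # deterministic: sorted factor names
        assert term.coefficients == {"A": -1, "B": 1}

    def test_like_terms_merge_across_spellings(self):
        # k*A appearing twice in one RHS merges into multiplicity -2
        system = parse_ode_text("dA/dt=-k*A-A*k\ndone")
        # -2kA with rate order 1 is exactly the unrepresentable case at the
        # net level, but canonicalization itself must merge it first
        (term,) = canonicalize(system).terms
        assert term.coefficients == {"A": -2}

    def test_distribution_over_parameter_sums(self):
        system = parse_ode_text("dA/dt=-(k1+k2)*A\ndone")
        canon = canonicalize(system)
        assert sorted(t.parameter for t in canon.terms) == ["k1", "k2"]
        assert all(t.coefficients == {"A": -1} for t in canon.terms)


class TestMatchMichaelian:
    variables = {"S", "E", "P"}
    parameters = {"Vm", "Km", "k"}

    def case(self, text):
        return match_michaelian(parse_expression(text), self.variables, self.parameters)

    def test_basic_pattern(self):
        assert self.case("Vm*S/(Km+S)") == ("Vm", "Km", "S", Monomial.from_dict({"S": 1}))

    def test_catalysed_pattern_commuted(self):
        assert self.case("S/(S+Km)*E*k") == (
            "k", "Km", "S", Monomial.from_dict({"E": 1, "S": 1})
        )

    @pytest.mark.parametrize("text", [
        "k*S/(Km+S^2)",      # denominator not degree one
        "k*S/(Km+S+E)",      # three-term denominator
        "k*E/(Km+S)",        # substrate absent from numerator
        "k*S/(Km+Vm)",       # no variable in denominator
        "Km*S/(Km+S)",       # rate and Michaelis parameter coincide
        "k*S",               # no quotient at all
    ])
    def test_no_match(self, text):
        assert self.case(text) is None


class TestProperties:
    def test_order_independence(self, accepted_system):
        reference = canonicalize(accepted_system)
        rng = random.Random(7)
        for _ in range(5):
            shuffled = parse_ode_text(permuted_ode_text(accepted_system, rng))
            canon = canonicalize(shuffled)
            assert sorted(map(term_view, canon.terms)) == sorted(
                map(term_view, reference.terms)
            )

    def test_soundness_recombination(self, accepted_system):
        """Expanding the canonical terms gives back the input system."""
        canon = canonicalize(accepted_system)
        assert systems_equivalent(canon.as_odes(), accepted_system)

    @pytest.mark.parametrize("seed", range(25))
    def test_post_merge_key_uniqueness(self, seed):
        system = net_to_odes(make_random_net(seed))
        canon = canonicalize(system)
        keys = [t.key() for t in canon.terms]
        assert len(keys) == len(set(keys))
        assert all(t.coefficients for t in canon.terms)
        assert all(n != 0 for t in canon.terms for n in t.coefficients.values())
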