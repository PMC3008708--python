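# ode2net

**Unique inference of reaction-network structure from ordinary differential
equations.**

Many systems-biology models are published only as ODEs, yet structural
("kinetic-free") analyses — invariant computation, pathway/flux analysis,
stochastic simulation — need a well-defined reaction network: which species
are consumed, produced or catalytic, and with what stoichiometry. `ode2net`
reads an ODE system and either constructs **the** continuous Petri net (CPN)
that regenerates it, or rejects the input with a precise diagnostic showing
why no unambiguous network exists.

## The method

A CPN is a set of places `P` (one per species variable) and transitions `T`
(one per reaction) with nonnegative integer incidence matrices `Pre` and
`Post`; it defines the ODE system

```
dx/dt = Σ_t (Post(x,t) − Pre(x,t)) · v_t .
```

Going the other way is ambiguous in general, but becomes unique under three
biochemically natural conditions:

1. **Symbolic mass-action kinetics** — every rate is
   `v_t = k_t · Π_x x^Pre(x,t)` with a symbolic parameter `k_t`; each ODE
   right-hand side is then a polynomial over the variables whose
   coefficients are integer combinations of parameters. Optionally,
   Michaelian (Michaelis–Menten) rates `k · m(x) / (Km + S)` are allowed,
   provided the rational terms appear already in this decomposed form.
2. **No void reaction** — no transition with `Pre = Post` (it would
   contribute nothing to any ODE).
3. **No parameter reuse** — one parameter never rates two reactions with
   identical reactant multisets.

Under these conditions every additive term `n · k · x₁^a₁···xₘ^aₘ` of the
expanded right-hand sides pins down one transition: `Pre` weights are the
exponents `aᵢ`, and `Post(x) = Pre(x) + n(x)` where `n(x)` is the term's
integer multiplicity in `dx/dt`. Like terms merge; a negative `Post` weight
proves that no admissible net exists, and the conversion is rejected rather
than silently patched.

The package provides the canonicalization, the constructive inference, the
reverse semantics (net → ODEs) used as a round-trip oracle, condition
checking for arbitrary nets, a deterministic random-net generator for
property testing, and writers for SBML Level 2 Version 1, PNML and a native
JSON interchange format. The naive one-transition-per-equation translation
is included as a baseline (`naive_net`), illustrating the structure the
method recovers from opaque whole-RHS rates.

## Worked example

`decay.ode` (XPPAUT syntax):

```
dA/dt=-k*A
dB/dt=k*A
par k=0.1
init A=5
done
```

```bash
$ ode2net check decay.ode
{
  "status": "converted",
  "diagnostics": [],
  "counts": {
    "places": 2,
    "transitions": 1,
    "mass_action": 1,
    "michaelian": 0
  },
  "source": "decay.ode"
}
```

The two equations share the single term `k·A`: both are explained by one
reaction `A → B` with rate `k·A`, so the net has 2 places, 1 transition, a
pre-arc of weight 1 from `A` and a post-arc of weight 1 to `B` — not the
two-transition net the naive per-equation translation would give.
`ode2net convert decay.ode` emits this as SBML (species `A`, `B`; parameter
`k = 0.1`; one irreversible reaction with stoichiometry 1/1 and kinetic law
`k*A` as content MathML); `--format pnml` / `--format json` select the
Petri-net formats.

From Python:

```python
>>> import ode2net as o
>>> system = o.parse_ode_text("dA/dt=-k*A\ndB/dt=k*A\ndone")
>>> net, report = o.convert_system(system)
>>> [(t.id, t.pre, t.post) for t in net.transitions]
[('t_k_A', {'A': 1}, {'B': 1})]
>>> o.systems_equivalent(o.net_to_odes(net), system)   # round-trip soundness
True
```

Rejections carry machine-readable diagnostics, e.g. `dA/dt=-2*k*A` (rate
order 1 but consumption 2) yields `NEGATIVE_POST_WEIGHT`: no nonnegative
product stoichiometry exists, hence no admissible network. `ode2net compare
model.ode net.json` checks a hand-drawn network against the ODEs it claims
to implement.

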