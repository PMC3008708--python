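# Methods

## Problem and model

The package infers reaction-network structure from a system of first-order
ODEs `dx_i/dt = f_i(x, k)` over species concentrations `x` and symbolic rate
parameters `k`. The target representation is a continuous Petri net: places
`P` (one per variable), transitions `T`, nonnegative integer incidence
matrices `Pre`, `Post`, and one rate law `v_t` per transition whose
variables are restricted to the transition's pre-places. The net's forward
semantics is

    dx/dt = Σ_t (Post(x,t) − Pre(x,t)) · v_t,

implemented in `net_to_odes` and used as the oracle for every round-trip
check.

Inference is only well posed under three admissibility conditions:

1. every rate is pure mass action, `v_t = k_t · Π_x x^Pre(x,t)`, with a
   *symbolic* parameter (optionally extended by Michaelian rates, below);
2. no transition is void (`Pre = Post` as vectors — a species that is both
   consumed and reproduced with the same weight, i.e. a catalyst, is fine
   as long as the transition has some net effect somewhere);
3. a parameter never rates two transitions with the same reactant multiset.

Violating any one of these makes distinct nets generate identical ODEs; the
`fixtures.counterexample_suite` scenarios exhibit the ambiguity each
condition removes, and `verify_conditions` checks 2–3 on arbitrary nets.

## Procedure

**Canonicalization** (`canonical.canonicalize`). Each right-hand side is
fully expanded with sympy and every additive term classified as
`(integer n) · (parameter) · (monomial over variables)`, or — when
Michaelian kinetics is enabled — `n · k · m(x) / (Km + S)` with `Km` a
parameter and the substrate `S` occurring in the numerator monomial `m`.
Terms with the same identification key — `(parameter, monomial)`, extended
with `(Km, substrate)` for Michaelian terms — necessarily stem from one
transition and are merged by summing their multiplicities per equation;
zero sums are dropped. Anything else (no parameter factor, a plain numeric
term, a non-integer coefficient, a variable in an unmatched denominator, a
negative or fractional exponent) raises a mass-action-condition violation
carrying the offending sub-expression. Because classification happens on
sympy's canonical expanded form, the result is independent of equation
order and of the textual ordering of sums and products.

Two deliberate strictness choices:

* **Non-integer coefficients are rejected, never rescaled.** `0.5·k·A`
  could be absorbed by redefining `k`, but that silently changes the
  stoichiometric reading of the model; the error message leaves the choice
  to the modeller.
* **Parameter products** (`k1·k2·A`) are rejected by default, since the
  uniqueness argument is stated for single-parameter coefficients. With
  `fold_parameters=True` (CLI `--fold-params`) the product is treated as
  one compound parameter named by joining the sorted factor names with
  `_`; uniqueness then holds over the folded alphabet, which the CLI warns
  about.

**Inference** (`infer.infer_net`). One place per variable, one transition
per canonical term. For mass action, `Pre(x)` is exactly the monomial
exponent of `x` (the rate law forces it), and
`Post(x) = Pre(x) + n(x)` with `n(x)` the term's multiplicity in `dx/dt`.
If some `Post(x)` would be negative the system provably has no admissible
net and an `InferenceError` with a `NEGATIVE_POST_WEIGHT` diagnostic is
raised — no partial output is produced. Transition ids are assigned
deterministically (`t_<param>[_<Km>]_<monomial>`, monomial in sorted
variable order), so equal inputs give byte-equal serializations. Every
inferred net is re-checked with `verify_conditions` before being returned.

**Michaelian extension.** Rates of the form `k · m(x) / (Km + S)` are
matched purely syntactically on the quotient shape — one parameter plus one
variable in the denominator, both linear, substrate present in the
numerator. No partial-fraction machinery or pole-finding is attempted: a
decomposed rational right-hand side whose simple fractions have been left
as `c/(Km+S)` with a constant numerator is rejected rather than recombined,
and Hill-type denominators (`Km + S^2`) are rejected as outside the
admissible class. Unlike mass action, a saturating rate does not pin the
stoichiometry down, so Pre weights use the minimal convention compatible
with nonnegative Post and with rate variables being pre-places:

    Pre(x) = max(m(x), −n(x), 1 if x is the substrate else 0).

Because the rate monomial can therefore differ from Pre, Michaelian
transitions store their monomial explicitly; `net_to_odes` uses it, keeping
regeneration exact. This convention is a documented design choice, not a
forced consequence of the conditions.

**Equivalence** (`netmodel.systems_equivalent`) is decided exactly: the
difference of right-hand sides is brought over a common denominator and the
expanded numerator compared with zero. No probabilistic or numeric
evaluation is used; the systems involved are small enough that exact
rational-function arithmetic is cheap.

## Input formats

The XPPAUT reader supports the subset auto-generated model exports use:
`dX/dt=…` / `X'=…` equations, `par`/`param`, `init`, `aux` (ignored with a
warning), `@` option lines, `#` comments, `done`. Any other XPPAUT
construct (tables, delays, global flags, …) raises a parse error naming the
construct — silently misreading a model would be worse than refusing it.
Symbols are case-insensitive in this dialect (first spelling wins), and
`par` values are metadata only: the symbolic computation never substitutes
them, since admissibility requires symbolic parameters. Expression parsing
is a small tokenizer plus recursive-descent parser over `+ - * / ^` with
integer-literal exponents enforced at parse time; it builds sympy trees
directly, interning identifiers through the dialect's symbol table so that
species named `S`, `E`, `I` or `N` are ordinary symbols.

## Output formats

* **SBML Level 2 Version 1**: one compartment, one species per place, one
  global parameter per rate/Michaelis constant (numeric values attached
  where the input declared them), one irreversible reaction per transition
  with integer stoichiometries and the exact rate law as content MathML.
  Catalysts are written as reactant *and* product with equal stoichiometry
  (not as modifiers) so the ODEs are reconstructible from stoichiometry and
  kinetic laws alone; an annotation on the model records the convention.
  Empty `listOf` containers are omitted, as SBML requires. The MathML is
  emitted by the package's own writer restricted to the rate-law fragment
  (symbols, integers, rationals, sums, products, quotients, integer
  powers), so symbol names round-trip verbatim. `odes_from_sbml` reads this
  fragment back and is the basis of the document-level round-trip test;
  it is not a general SBML importer.
* **PNML** (ISO/IEC 15909-2 core model): places, transitions, arcs with
  integer inscriptions equal to the Pre/Post weights; rate laws ride along
  as tool-specific annotations since the core model has no kinetics slot.
* **Native JSON**: lossless, including kind/parameter/substrate/monomial
  metadata; places are written sorted so equivalent inputs serialize
  identically. `read_json` validates the schema (known places, nonnegative
  integer weights, mandatory Michaelian fields).

Document validity is checked structurally (`validate_sbml`,
`validate_pnml`): well-formedness, namespaces, element nesting and order,
reference resolution, positive integer stoichiometries/inscriptions, and
parseable kinetic-law MathML. The checks are written against the two
formats' element rules rather than delegating to external schema files.

## Random fixtures and what they do (not) show

`random_cpn` draws admissible nets directly: fresh parameter per transition
(condition 3 holds trivially), Pre/Post vectors rejection-sampled until the
transition is non-void (bounded at 1000 redraws), and, for Michaelian
transitions, a fresh `Km` and a substrate among the places with Pre ≥ 1;
the Michaelian rate monomial is the full Pre vector. Defaults used by the
property suites: up to 10 places, up to 15 transitions, arc weights up to
4, 30 % Michaelian — comfortably above the complexity of the individual
reactions in published mass-action models, whose equations are long sums of
exactly such terms. The generator makes no attempt at biological realism
(no conservation relations, no scale-free topology, no Hill kinetics); what
passing the 1000-trial round-trip shows is exactly the uniqueness guarantee
— admissible structure is recovered without loss — not that any particular
published model is admissible. Real models also stress the *parser* and the
rejection paths, which the hand-written corpus and counterexample scenarios
cover separately.

## Numerical and degenerate-input choices

All algebra is exact (sympy rationals; decimal literals are converted to
exact rationals at parse time), so there are no tolerances anywhere. An
empty ODE file yields an empty system and an empty net; a zero right-hand
side contributes no terms; complete cancellation (`k*A − k*A`) removes the
term before inference. Ties in transition ordering cannot arise: the sort
key (parameter, Km, substrate, monomial) is exactly the term identification
key, which is unique after merging.

## Known limitations

* Hill kinetics and arbitrary rate laws are out of scope by design; the
  uniqueness argument does not extend to them.
* Michaelian terms must already appear in quotient form; no automatic
  partial-fraction decomposition with unknown denominators is attempted.
* SBML is write-only (plus the fragment reader used for self-checking);
  there is no import of general SBML models or uncovering of structure
  hidden in SBML kinetic laws.
* When the conditions fail, the tool only diagnoses; it implements no
  heuristics for choosing among the multiple consistent structures.
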