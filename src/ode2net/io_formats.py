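"""Serialization of inferred nets: SBML Level 2 Version 1, PNML, native JSON.

SBML carries the net as one irreversible reaction per transition with
integer stoichiometries and the exact rate law as content MathML; a species
acting as a catalyst (equal pre and post weight) is listed as both reactant
and product with that stoichiometry, so the ODE system is reconstructible
from stoichiometry and kinetic laws alone.  PNML (the ISO 15909-2 Petri net
interchange) carries places, transitions and weighted arcs, with rate laws
attached as tool-specific annotations.  The JSON format is the lossless
native round-trip representation.  A small structural reader for the SBML
output (:func:`odes_from_sbml`) supports the semantic round-trip check
document -> ODEs -> compare; it is not a general SBML importer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import sympy as sp
from lxml import etree

from .canonical import Condition1Violation, Diagnostic, Kinetics, Monomial, canonicalize
from .infer import CPNet, InferenceError, Transition, infer_net
from .odeparse import Expression, OdeSystem, format_expression

__all__ = [
    "ConversionReport",
    "SchemaError",
    "write_sbml",
    "write_pnml",
    "write_json",
    "read_json",
    "odes_from_sbml",
    "validate_sbml",
    "validate_pnml",
    "convert_system",
]

SBML_NS = "http://www.sbml.org/sbml/level2"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
PNML_PTNET = "http://www.pnml.org/version-2009/grammar/ptnet"
TOOL_NS = "urn:ode2net"


class SchemaError(ValueError):
    """A document violates the expected format."""


@dataclass
class ConversionReport:
    """Outcome summary of one ODE-to-net conversion."""

    status: str  # "converted" | "rejected"
    diagnostics: list[Diagnostic] = field(default_factory=list)
    places: int = 0
    transitions: int = 0
    mass_action_transitions: int = 0
    michaelian_transitions: int = 0
    source: str | None = None

    def __post_init__(self):
        if self.status == "rejected" and not self.diagnostics:
            raise ValueError("a rejection must carry at least one diagnostic")

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "diagnostics": [
                {"code": d.code.value, "detail": d.detail, "context": list(d.context)}
                for d in self.diagnostics
            ],
            "counts": {
                "places": self.places,
                "transitions": self.transitions,
                "mass_action": self.mass_action_transitions,
                "michaelian": self.michaelian_transitions,
            },
            "source": self.source,
        }


def convert_system(
    system: OdeSystem,
    allow_michaelian: bool = True,
    fold_parameters: bool = False,
    source: str | None = None,
) -> tuple[CPNet | None, ConversionReport]:
    """Run the full canonicalize-and-infer pipeline with a report.

    On rejection no partial net is produced: the result is ``(None, report)``
    with the condition diagnostics.
    """
    try:
        canon = canonicalize(system, allow_michaelian=allow_michaelian,
                             fold_parameters=fold_parameters)
        net = infer_net(canon)
    except Condition1Violation as exc:
        return None, ConversionReport(
            status="rejected", diagnostics=[exc.diagnostic], source=source
        )
    except InferenceError as exc:
        return None, ConversionReport(
            status="rejected", diagnostics=exc.diagnostics, source=source
        )
    report = ConversionReport(
        status="converted",
        places=len(net.places),
        transitions=len(net.transitions),
        mass_action_transitions=sum(
            1 for t in net.transitions if t.kind is Kinetics.MASS_ACTION
        ),
        michaelian_transitions=sum(
            1 for t in net.transitions if t.kind is Kinetics.MICHAELIAN
        ),
        source=source,
    )
    return net, report


# ---------------------------------------------------------------------------
# MathML (content markup) bridge
# ---------------------------------------------------------------------------


def _emit_mathml(expr: Expression, parent: etree._Element) -> None:
    """Emit content MathML for the rate-law expression fragment.

    Handles exactly the shapes rate laws use: symbols, integers, rationals,
    sums, products, integer powers and quotients.  Symbol names are written
    verbatim in <ci> (no sub/superscript prettification, so the document
    round-trips exactly).
    """

    def apply(op: str):
        node = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
        etree.SubElement(node, f"{{{MATHML_NS}}}{op}")
        return node

    if expr.is_Symbol:
        etree.SubElement(parent, f"{{{MATHML_NS}}}ci").text = expr.name
        return
    if expr.is_Integer:
        etree.SubElement(parent, f"{{{MATHML_NS}}}cn").text = str(int(expr))
        return
    if expr.is_Rational:
        cn = etree.SubElement(parent, f"{{{MATHML_NS}}}cn", type="rational")
        cn.text = str(expr.p)
        sep = etree.SubElement(cn, f"{{{MATHML_NS}}}sep")
        sep.tail = str(expr.q)
        return
    if expr.is_Add:
        node = apply("plus")
        for arg in expr.args:
            _emit_mathml(arg, node)
        return
    if expr.is_Mul:
        num, den = expr.as_numer_denom()
        if den != 1:
            node = apply("divide")
            _emit_mathml(num, node)
            _emit_mathml(den, node)
            return
        node = apply("times")
        for arg in expr.args:
            _emit_mathml(arg, node)
        return
    if expr.is_Pow:
        base, exponent = expr.args
        node = apply("power")
        _emit_mathml(base, node)
        _emit_mathml(exponent, node)
        return
    raise ValueError(f"cannot encode expression {sp.sstr(expr)} as MathML")


def _mathml_element(expr: Expression) -> etree._Element:
    """Render a sympy expression as namespaced content MathML under <math>."""
    math = etree.Element(f"{{{MATHML_NS}}}math")
    _emit_mathml(expr, math)
    return math


def _mathml_to_sympy(node: etree._Element) -> Expression:
    """Read the content-MathML subset our writer emits back into sympy."""
    tag = etree.QName(node).localname
    if tag == "math":
        (child,) = list(node)
        return _mathml_to_sympy(child)
    if tag == "ci":
        return sp.Symbol(node.text.strip())
    if tag == "cn":
        text = (node.text or "").strip()
        parts = [text] + [
            (c.tail or "").strip() for c in node if etree.QName(c).localname == "sep"
        ]
        if len(parts) == 2:
            return sp.Rational(int(parts[0]), int(parts[1]))
        return sp.Rational(text) if "." in text or "e" in text.lower() else sp.Integer(int(text))
    if tag == "apply":
        children = list(node)
        op = etree.QName(children[0]).localname
        args = [_mathml_to_sympy(c) for c in children[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "times":
            return sp.Mul(*args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return sp.Pow(args[0], args[1])
        raise SchemaError(f"unsupported MathML operator {op!r}")
    raise SchemaError(f"unsupported MathML element {tag!r}")


# ---------------------------------------------------------------------------
# SBML Level 2 Version 1
# ---------------------------------------------------------------------------


def write_sbml(
    net: CPNet,
    defaults: dict[str, float | None] | None = None,
    initial_values: dict[str, float] | None = None,
    model_id: str = "model",
) -> str:
    """Serialize an admissible net as an SBML Level 2 Version 1 document.

    ``defaults`` supplies numeric values for rate/Michaelis parameters where
    known (others are emitted without a value, i.e. remaining symbolic);
    ``initial_values`` supplies species initial amounts (default 0, with a
    warning).
    """
    defaults = defaults or {}
    initial_values = initial_values or {}
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "2")
    root.set("version", "1")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model", id=model_id)
    ann = etree.SubElement(model, f"{{{SBML_NS}}}annotation")
    note = etree.SubElement(ann, f"{{{TOOL_NS}}}convention", nsmap={"ode2net": TOOL_NS})
    note.text = (
        "Catalysts are encoded as reactant+product with equal stoichiometry "
        "so the ODE system is exactly reconstructible from stoichiometry and "
        "kinetic laws."
    )

    compartments = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(compartments, f"{{{SBML_NS}}}compartment", id="default", size="1")

    # SBML forbids empty listOf containers: emit each only when non-empty
    if net.places:
        species_list = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    missing_init = []
    for place in net.places:
        amount = initial_values.get(place)
        if amount is None:
            missing_init.append(place)
            amount = 0.0
        etree.SubElement(
            species_list, f"{{{SBML_NS}}}species",
            id=place, compartment="default", initialAmount=repr(float(amount)),
        )
    if missing_init:
        warnings.warn(
            f"no initial amount for species {missing_init}; defaulting to 0"
        )

    param_names: list[str] = []
    for t in net.transitions:
        for name in (t.parameter, t.km_parameter):
            if name and name not in param_names:
                param_names.append(name)
    if param_names:
        params = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
        for name in param_names:
            el = etree.SubElement(params, f"{{{SBML_NS}}}parameter", id=name)
            if defaults.get(name) is not None:
                el.set("value", repr(float(defaults[name])))

    if net.transitions:
        reactions = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for t in net.transitions:
        reaction = etree.SubElement(
            reactions, f"{{{SBML_NS}}}reaction", id=t.id, reversible="false"
        )
        if any(t.pre.values()):
            reactants = etree.SubElement(reaction, f"{{{SBML_NS}}}listOfReactants")
            for x, w in sorted(t.pre.items()):
                if w:
                    etree.SubElement(
                        reactants, f"{{{SBML_NS}}}speciesReference",
                        species=x, stoichiometry=str(w),
                    )
        if any(t.post.values()):
            products = etree.SubElement(reaction, f"{{{SBML_NS}}}listOfProducts")
            for x, w in sorted(t.post.items()):
                if w:
                    etree.SubElement(
                        products, f"{{{SBML_NS}}}speciesReference",
                        species=x, stoichiometry=str(w),
                    )
        law = etree.SubElement(reaction, f"{{{SBML_NS}}}kineticLaw")
        law.append(_mathml_element(t.rate_expression()))

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()


def odes_from_sbml(text: str) -> OdeSystem:
    """Rebuild the ODE system encoded by a document our writer produced.

    Uses only stoichiometries and kinetic-law MathML, which is exactly what
    the semantic round-trip guarantee promises.
    """
    root = etree.fromstring(text.encode())
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise SchemaError("no <model> element")
    species = [
        el.get("id")
        for el in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    ]
    equations = {x: sp.Integer(0) for x in species}
    parameters: dict[str, float | None] = {}
    for el in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        parameters[el.get("id")] = (
            float(el.get("value")) if el.get("value") is not None else None
        )
    for reaction in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        stoich = {x: 0 for x in species}
        for ref in reaction.findall(
            f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
        ):
            stoich[ref.get("species")] -= int(float(ref.get("stoichiometry", "1")))
        for ref in reaction.findall(
            f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
        ):
            stoich[ref.get("species")] += int(float(ref.get("stoichiometry", "1")))
        math = reaction.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        if math is None:
            raise SchemaError(f"reaction {reaction.get('id')} has no kinetic law")
        rate = _mathml_to_sympy(math)
        for x, n in stoich.items():
            if n:
                equations[x] = equations[x] + n * rate
    for rhs in equations.values():
        for s in rhs.free_symbols:
            if s.name not in equations:
                parameters.setdefault(s.name, None)
    return OdeSystem(variables=species, parameters=parameters, equations=equations)


def validate_sbml(text: str) -> list[str]:
    """Structural conformance check of an SBML L2V1 document.

    Returns a list of problems (empty = conformant): correct namespace,
    level/version attributes, required element nesting and ordering,
    resolvable compartment/species references, positive integer
    stoichiometries, and MathML kinetic laws that parse.
    """
    problems: list[str] = []
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != f"{{{SBML_NS}}}sbml":
        problems.append(f"root element is {root.tag}, expected SBML L2 <sbml>")
        return problems
    if root.get("level") != "2" or root.get("version") != "1":
        problems.append("level/version attributes are not 2/1")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        return problems + ["missing <model>"]
    order = [etree.QName(c).localname for c in model]
    allowed = ["annotation", "notes", "listOfFunctionDefinitions",
               "listOfUnitDefinitions", "listOfCompartments", "listOfSpecies",
               "listOfParameters", "listOfRules", "listOfReactions",
               "listOfEvents"]
    ranks = [allowed.index(o) for o in order if o in allowed]
    if ranks != sorted(ranks) or len(ranks) != len(order):
        problems.append(f"model children out of schema order: {order}")
    for child in model:
        name = etree.QName(child).localname
        if name.startswith("listOf") and len(child) == 0:
            problems.append(f"empty <{name}> container")
    compartments = {
        el.get("id")
        for el in model.findall(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment")
    }
    species = {}
    for el in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        species[el.get("id")] = el
        if el.get("compartment") not in compartments:
            problems.append(f"species {el.get('id')} has unresolved compartment")
    for reaction in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = reaction.get("id")
        if rid is None:
            problems.append("reaction without id")
        for ref in reaction.iter(f"{{{SBML_NS}}}speciesReference"):
            if ref.get("species") not in species:
                problems.append(f"reaction {rid}: unresolved species reference")
            st = ref.get("stoichiometry", "1")
            if not (float(st).is_integer() and float(st) > 0):
                problems.append(f"reaction {rid}: non-positive-integer stoichiometry {st}")
        math = reaction.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        if math is None:
            problems.append(f"reaction {rid}: kineticLaw math missing or not MathML")
        else:
            try:
                _mathml_to_sympy(math)
            except SchemaError as exc:
                problems.append(f"reaction {rid}: {exc}")
    return problems


# ---------------------------------------------------------------------------
# PNML
# ---------------------------------------------------------------------------


def _pnml_place_id(name: str) -> str:
    return f"p_{name}"


def write_pnml(net: CPNet, net_id: str = "net1") -> str:
    """Serialize a net as a PNML core-model (place/transition) document.

    Arc inscriptions carry the integer Pre/Post weights; each transition's
    rate law is attached as a tool-specific annotation (PNML has no
    standard slot for continuous kinetics).
    """
    root = etree.Element(f"{{{PNML_NS}}}pnml", nsmap={None: PNML_NS})
    netel = etree.SubElement(root, f"{{{PNML_NS}}}net", id=net_id, type=PNML_PTNET)
    page = etree.SubElement(netel, f"{{{PNML_NS}}}page", id="page1")
    for place in net.places:
        pel = etree.SubElement(page, f"{{{PNML_NS}}}place", id=_pnml_place_id(place))
        name = etree.SubElement(pel, f"{{{PNML_NS}}}name")
        etree.SubElement(name, f"{{{PNML_NS}}}text").text = place
    arc_no = 0
    for t in net.transitions:
        tel = etree.SubElement(page, f"{{{PNML_NS}}}transition", id=t.id)
        name = etree.SubElement(tel, f"{{{PNML_NS}}}name")
        etree.SubElement(name, f"{{{PNML_NS}}}text").text = t.id
        tool = etree.SubElement(
            tel, f"{{{PNML_NS}}}toolspecific", tool="ode2net", version="0.1"
        )
        rate = etree.SubElement(tool, f"{{{TOOL_NS}}}rate", nsmap={"ode2net": TOOL_NS})
        rate.text = format_expression(t.rate_expression())
        for x, w in sorted(t.pre.items()):
            if not w:
                continue
            arc_no += 1
            arc = etree.SubElement(
                page, f"{{{PNML_NS}}}arc", id=f"a{arc_no}",
                source=_pnml_place_id(x), target=t.id,
            )
            ins = etree.SubElement(arc, f"{{{PNML_NS}}}inscription")
            etree.SubElement(ins, f"{{{PNML_NS}}}text").text = str(w)
        for x, w in sorted(t.post.items()):
            if not w:
                continue
            arc_no += 1
            arc = etree.SubElement(
                page, f"{{{PNML_NS}}}arc", id=f"a{arc_no}",
                source=t.id, target=_pnml_place_id(x),
            )
            ins = etree.SubElement(arc, f"{{{PNML_NS}}}inscription")
            etree.SubElement(ins, f"{{{PNML_NS}}}text").text = str(w)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()


def validate_pnml(text: str) -> list[str]:
    """Structural conformance check of a PNML core-model document."""
    problems: list[str] = []
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != f"{{{PNML_NS}}}pnml":
        return [f"root element is {root.tag}, expected <pnml>"]
    for netel in root.findall(f"{{{PNML_NS}}}net"):
        if not netel.get("id"):
            problems.append("net without id")
        nodes: set[str] = set()
        pages = netel.findall(f"{{{PNML_NS}}}page")
        if not pages:
            problems.append("net without page")
        for page in pages:
            for el in page:
                local = etree.QName(el).localname
                if local in ("place", "transition"):
                    nid = el.get("id")
                    if nid in nodes:
                        problems.append(f"duplicate node id {nid}")
                    nodes.add(nid)
            for arc in page.findall(f"{{{PNML_NS}}}arc"):
                for attr in ("source", "target"):
                    if arc.get(attr) not in nodes:
                        problems.append(
                            f"arc {arc.get('id')}: unresolved {attr} {arc.get(attr)!r}"
                        )
                ins = arc.find(f"{{{PNML_NS}}}inscription/{{{PNML_NS}}}text")
                if ins is not None and (not ins.text.isdigit() or int(ins.text) < 1):
                    problems.append(f"arc {arc.get('id')}: bad inscription {ins.text!r}")
    return problems


# ---------------------------------------------------------------------------
# Native JSON
# ---------------------------------------------------------------------------

JSON_FORMAT = "ode2net-cpn"
JSON_VERSION = 1


def write_json(net: CPNet) -> str:
    """Lossless native serialization; `read_json` inverts it exactly.

    Places are written sorted (a canonical order), so nets inferred from
    reordered but equivalent inputs serialize to identical documents.
    """
    doc = {
        "format": JSON_FORMAT,
        "version": JSON_VERSION,
        "places": sorted(net.places),
        "transitions": [],
    }
    for t in net.transitions:
        entry: dict = {
            "id": t.id,
            "kind": t.kind.value,
            "parameter": t.parameter,
            "pre": {x: w for x, w in sorted(t.pre.items()) if w},
            "post": {x: w for x, w in sorted(t.post.items()) if w},
        }
        if t.kind is Kinetics.MICHAELIAN:
            entry["km_parameter"] = t.km_parameter
            entry["substrate"] = t.substrate
            entry["monomial"] = t.monomial.exponents
        if t.kind is Kinetics.OPAQUE:
            entry["rate"] = format_expression(t.rate)
        doc["transitions"].append(entry)
    return json.dumps(doc, indent=2) + "\n"


def _check_weights(weights, places, where: str) -> dict[str, int]:
    if not isinstance(weights, dict):
        raise SchemaError(f"{where}: weight table must be an object")
    out = {}
    for x, w in weights.items():
        if x not in places:
            raise SchemaError(f"{where}: unknown place {x!r}")
        if not isinstance(w, int) or isinstance(w, bool) or w < 0:
            raise SchemaError(f"{where}: weight for {x} must be a nonnegative integer")
        if w:
            out[x] = w
    return out


def read_json(text: str) -> CPNet:
    """Parse the native JSON format, validating the schema."""
    from .odeparse import parse_expression

    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON: {exc}")
    if not isinstance(doc, dict) or doc.get("format") != JSON_FORMAT:
        raise SchemaError(f"not a {JSON_FORMAT} document")
    places = doc.get("places")
    if not isinstance(places, list) or any(not isinstance(p, str) for p in places):
        raise SchemaError("places must be a list of names")
    place_set = set(places)
    transitions = []
    for i, entry in enumerate(doc.get("transitions", [])):
        where = f"transition #{i}"
        try:
            kind = Kinetics(entry.get("kind"))
        except ValueError:
            raise SchemaError(f"{where}: unknown kind {entry.get('kind')!r}")
        pre = _check_weights(entry.get("pre", {}), place_set, where)
        post = _check_weights(entry.get("post", {}), place_set, where)
        km = entry.get("km_parameter")
        substrate = entry.get("substrate")
        monomial = None
        rate = None
        if kind is Kinetics.MICHAELIAN:
            if not km or not substrate:
                raise SchemaError(f"{where}: michaelian needs km_parameter and substrate")
            mono_raw = entry.get("monomial")
            if mono_raw is None:
                mono_raw = {x: w for x, w in pre.items()}
            monomial = Monomial.from_dict(
                _check_weights(mono_raw, place_set, f"{where} monomial")
            )
        if kind is Kinetics.OPAQUE:
            rate = parse_expression(entry.get("rate", "0"))
        if kind is not Kinetics.OPAQUE and not entry.get("parameter"):
            raise SchemaError(f"{where}: missing parameter")
        transitions.append(Transition(
            id=entry.get("id", f"t{i}"), kind=kind,
            parameter=entry.get("parameter"), pre=pre, post=post,
            km_parameter=km if kind is Kinetics.MICHAELIAN else None,
            substrate=substrate if kind is Kinetics.MICHAELIAN else None,
            monomial=monomial, rate=rate,
        ))
    return CPNet(places=list(places), transitions=transitions)
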