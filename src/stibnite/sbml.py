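"""SBML Level 3 Version 2 export and import.

Covers core constructs (species, parameters, reactions, the three rule
kinds, initial assignments, events) plus the Flux Balance Constraints
package version 1 (flux bounds and linear objectives) and a subset of
the Distributions package (draw csymbols in math, per-symbol
uncertainty elements).

Serialization is canonical: element and attribute order is fixed, and
numbers use the same decimal rendering as the text unparser, so
``export(import(export(m)))`` is byte-identical to ``export(m)``.

Package ``required`` flags follow the package specifications: ``fbc``
is ``false`` (bounds and objectives do not change core math), while
``distrib`` is ``true`` (draw semantics cannot be ignored).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

from lxml import etree

from . import distributions, metadata as meta_mod
from .diagnostics import Diagnostic, DiagnosticSink, LanguageError, Severity
from .fbc import FbcRecord, FluxConstraint, Objective
from .model import (DEFAULT_COMPARTMENT, Event, Model, Parameter,
                    Participant, Reaction, Rule, Species)
from .syntax import (Binary, Call, Expr, Num, Sym, TimeSym, Unary,
                     format_number)

SBML_CORE_NS = "http://www.sbml.org/sbml/level3/version2/core"
FBC_V1_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version1"
DISTRIB_NS = "http://www.sbml.org/sbml/level3/version1/distrib/version1"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
RATEOF_URL = "http://www.sbml.org/sbml/symbols/rateOf"
DISTRIB_URL_PREFIX = "http://www.sbml.org/sbml/symbols/distrib/"

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _c(tag: str) -> str:
    return f"{{{SBML_CORE_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _f(tag: str) -> str:
    return f"{{{FBC_V1_NS}}}{tag}"


def _d(tag: str) -> str:
    return f"{{{DISTRIB_NS}}}{tag}"


@dataclass
class SbmlDocument:
    """A serialized model: the XML tree plus enabled package flags."""

    root: etree._Element
    fbc_enabled: bool = False
    distrib_enabled: bool = False

    level: int = 3
    version: int = 2

    def to_bytes(self) -> bytes:
        return etree.tostring(self.root, pretty_print=True,
                              xml_declaration=True, encoding="UTF-8")

    def to_string(self) -> str:
        return self.to_bytes().decode("utf-8")


def sanitize_id(name: str, taken: Optional[set] = None) -> str:
    """Coerce a name into a valid SId; collisions get numeric suffixes."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not sid or not re.match(r"[A-Za-z_]", sid[0]):
        sid = "_" + sid
    if taken is not None:
        base = sid
        k = 1
        while sid in taken:
            sid = f"{base}_{k}"
            k += 1
        taken.add(sid)
    return sid


# --------------------------------------------------------------------------
# Expression -> MathML
# --------------------------------------------------------------------------

_OP_ELEMENTS = {"+": "plus", "-": "minus", "*": "times", "/": "divide",
                "^": "power", ">": "gt", "<": "lt", ">=": "geq",
                "<=": "leq", "==": "eq", "!=": "neq"}

# canonical function-name -> MathML element; aliases normalized first
_FUNC_ALIASES = {"ceil": "ceiling", "asin": "arcsin", "acos": "arccos",
                 "atan": "arctan", "log10": "log"}
_FUNC_ELEMENTS = {"sin", "cos", "tan", "sinh", "cosh", "tanh", "arcsin",
                  "arccos", "arctan", "exp", "ln", "log", "abs", "floor",
                  "ceiling", "root"}


def math_element(expr: Expr) -> etree._Element:
    """Wrap an expression in a ``<math>`` element (MathML namespace)."""
    math = etree.Element(_m("math"), nsmap={None: MATHML_NS})
    math.append(_expr_to_mathml(expr))
    return math


def _expr_to_mathml(expr: Expr) -> etree._Element:
    if isinstance(expr, Num):
        cn = etree.Element(_m("cn"))
        cn.text = f" {format_number(expr.value)} "
        return cn
    if isinstance(expr, Sym):
        ci = etree.Element(_m("ci"))
        ci.text = f" {expr.name} "
        return ci
    if isinstance(expr, TimeSym):
        cs = etree.Element(_m("csymbol"))
        cs.set("encoding", "text")
        cs.set("definitionURL", TIME_URL)
        cs.text = " time "
        return cs
    if isinstance(expr, Unary):
        apply_ = etree.Element(_m("apply"))
        etree.SubElement(apply_, _m("minus"))
        apply_.append(_expr_to_mathml(expr.child))
        return apply_
    if isinstance(expr, Binary):
        apply_ = etree.Element(_m("apply"))
        etree.SubElement(apply_, _m(_OP_ELEMENTS[expr.op]))
        apply_.append(_expr_to_mathml(expr.left))
        apply_.append(_expr_to_mathml(expr.right))
        return apply_
    if isinstance(expr, Call):
        name = _FUNC_ALIASES.get(expr.callee, expr.callee)
        apply_ = etree.Element(_m("apply"))
        if name == "rateOf":
            cs = etree.SubElement(apply_, _m("csymbol"))
            cs.set("encoding", "text")
            cs.set("definitionURL", RATEOF_URL)
            cs.text = " rateOf "
        elif name in distributions.DISTRIBUTION_NAMES:
            cs = etree.SubElement(apply_, _m("csymbol"))
            cs.set("encoding", "text")
            cs.set("definitionURL", DISTRIB_URL_PREFIX + name)
            cs.text = f" {name} "
        elif name == "pow":
            etree.SubElement(apply_, _m("power"))
        elif name in _FUNC_ELEMENTS:
            etree.SubElement(apply_, _m(name))
        else:
            raise LanguageError(
                f"function '{expr.callee}' has no MathML serialization")
        for arg in expr.args:
            apply_.append(_expr_to_mathml(arg))
        return apply_
    raise LanguageError(f"cannot serialize expression node {expr!r}")


_ELEMENT_OPS = {v: k for k, v in _OP_ELEMENTS.items()}


def mathml_to_expr(node: etree._Element) -> Expr:
    """Parse the MathML dialect this module emits back into an Expr."""
    tag = etree.QName(node).localname
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise LanguageError("<math> must contain exactly one expression")
        return mathml_to_expr(children[0])
    if tag == "cn":
        return Num(float((node.text or "").strip()))
    if tag == "ci":
        return Sym((node.text or "").strip())
    if tag == "csymbol":
        url = node.get("definitionURL", "")
        if url == TIME_URL:
            return TimeSym()
        raise LanguageError(f"unsupported csymbol '{url}'")
    if tag == "apply":
        children = list(node)
        if not children:
            raise LanguageError("empty <apply>")
        head, args = children[0], children[1:]
        head_tag = etree.QName(head).localname
        if head_tag == "csymbol":
            url = head.get("definitionURL", "")
            if url == RATEOF_URL:
                return Call("rateOf",
                            tuple(mathml_to_expr(a) for a in args))
            if url.startswith(DISTRIB_URL_PREFIX):
                name = url[len(DISTRIB_URL_PREFIX):]
                return Call(name, tuple(mathml_to_expr(a) for a in args))
            raise LanguageError(f"unsupported csymbol '{url}'")
        if head_tag == "minus" and len(args) == 1:
            return Unary("-", mathml_to_expr(args[0]))
        if head_tag in _ELEMENT_OPS and len(args) == 2:
            return Binary(_ELEMENT_OPS[head_tag],
                          mathml_to_expr(args[0]), mathml_to_expr(args[1]))
        if head_tag in ("plus", "times") and len(args) >= 2:
            # n-ary fold, left-associative
            op = _ELEMENT_OPS[head_tag]
            expr = mathml_to_expr(args[0])
            for a in args[1:]:
                expr = Binary(op, expr, mathml_to_expr(a))
            return expr
        if head_tag in _FUNC_ELEMENTS:
            return Call(head_tag, tuple(mathml_to_expr(a) for a in args))
        raise LanguageError(f"unsupported MathML operator '{head_tag}'")
    raise LanguageError(f"unsupported MathML element '{tag}'")


def _is_literal(expr: Optional[Expr]) -> Optional[float]:
    """Number (possibly negated) -> value; anything else -> None."""
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Unary) and expr.op == "-" and \
            isinstance(expr.child, Num):
        return -expr.child.value
    return None


def _uses_distrib_math(model: Model) -> bool:
    from .syntax import expr_calls
    for _, expr in model.all_expressions():
        for call in expr_calls(expr):
            if call.callee in distributions.DISTRIBUTION_NAMES:
                return True
    return False


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------


def export_sbml(model: Model) -> SbmlDocument:
    """Serialize a validated Model to an SBML L3V2 document."""
    fbc_on = not model.fbc.is_empty()
    distrib_on = bool(model.uncertainty) or _uses_distrib_math(model)

    nsmap: Dict[Optional[str], str] = {None: SBML_CORE_NS}
    if fbc_on:
        nsmap["fbc"] = FBC_V1_NS
    if distrib_on:
        nsmap["distrib"] = DISTRIB_NS
    root = etree.Element(_c("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    if fbc_on:
        root.set(_f("required"), "false")
    if distrib_on:
        root.set(_d("required"), "true")

    model_id = sanitize_id(model.name) if model.name else "__main"
    mel = etree.SubElement(root, _c("model"))
    mel.set("id", model_id)

    notes = meta_mod.notes_element(model.metadata, SBML_CORE_NS)
    ann = meta_mod.annotation_element(model.metadata, f"meta_{model_id}",
                                      SBML_CORE_NS)
    if ann is not None:
        mel.set("metaid", f"meta_{model_id}")
    if notes is not None:
        mel.append(notes)
    if ann is not None:
        mel.append(ann)

    # compartments
    loc = etree.SubElement(mel, _c("listOfCompartments"))
    comp = etree.SubElement(loc, _c("compartment"))
    comp.set("id", DEFAULT_COMPARTMENT)
    comp.set("spatialDimensions", "3")
    comp.set("size", "1")
    comp.set("constant", "true")

    # species
    if model.species:
        los = etree.SubElement(mel, _c("listOfSpecies"))
        for sp in model.species.values():
            el = etree.SubElement(los, _c("species"))
            el.set("id", sp.id)
            el.set("compartment", sp.compartment)
            lit = _is_literal(sp.initial)
            if sp.initial is None:
                el.set("initialConcentration", "0")
            elif lit is not None:
                el.set("initialConcentration", format_number(lit))
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "true" if sp.boundary else "false")
            el.set("constant", "false")
            _append_uncertainty(el, model, sp.id)

    # parameters (stoichiometry symbols become speciesReference ids)
    plain_params = [p for p in model.parameters.values()
                    if p.id not in model.stoich_symbols]
    if plain_params:
        lop = etree.SubElement(mel, _c("listOfParameters"))
        for par in plain_params:
            el = etree.SubElement(lop, _c("parameter"))
            el.set("id", par.id)
            lit = _is_literal(par.initial)
            if par.initial is None:
                el.set("value", "0")
            elif lit is not None:
                el.set("value", format_number(lit))
            el.set("constant", "true" if par.constant else "false")
            _append_uncertainty(el, model, par.id)

    # initial assignments: every non-literal initial formula
    ias: List[Tuple[str, Expr]] = []
    for sp in model.species.values():
        if sp.initial is not None and _is_literal(sp.initial) is None:
            ias.append((sp.id, sp.initial))
    for par in model.parameters.values():
        if par.initial is not None and _is_literal(par.initial) is None:
            ias.append((par.id, par.initial))
    if ias:
        loia = etree.SubElement(mel, _c("listOfInitialAssignments"))
        for symbol, expr in ias:
            el = etree.SubElement(loia, _c("initialAssignment"))
            el.set("symbol", symbol)
            el.append(math_element(expr))

    # rules
    if model.rules:
        lor = etree.SubElement(mel, _c("listOfRules"))
        for rule in model.rules:
            if rule.kind == "continuous":
                el = etree.SubElement(lor, _c("assignmentRule"))
                el.set("variable", rule.target)
            elif rule.kind == "rate":
                el = etree.SubElement(lor, _c("rateRule"))
                el.set("variable", rule.target)
            else:
                el = etree.SubElement(lor, _c("algebraicRule"))
                if rule.name:
                    el.set("id", rule.name)
            el.append(math_element(rule.formula))

    # reactions
    if model.reactions:
        lorx = etree.SubElement(mel, _c("listOfReactions"))
        for rxn in model.reactions.values():
            el = etree.SubElement(lorx, _c("reaction"))
            el.set("id", rxn.id)
            el.set("reversible", "true" if rxn.reversible else "false")
            for tag, parts in (("listOfReactants", rxn.reactants),
                               ("listOfProducts", rxn.products)):
                if not parts:
                    continue
                side = etree.SubElement(el, _c(tag))
                for part in parts:
                    sr = etree.SubElement(side, _c("speciesReference"))
                    if isinstance(part.stoichiometry, str):
                        sr.set("id", part.stoichiometry)
                    sr.set("species", part.species)
                    if isinstance(part.stoichiometry, float):
                        sr.set("stoichiometry",
                               format_number(part.stoichiometry))
                        sr.set("constant", "true")
                    else:
                        sr.set("constant", "false")
            if rxn.kinetic_law is not None:
                kl = etree.SubElement(el, _c("kineticLaw"))
                kl.append(math_element(rxn.kinetic_law))

    # events
    if model.events:
        loe = etree.SubElement(mel, _c("listOfEvents"))
        for ev in model.events:
            el = etree.SubElement(loe, _c("event"))
            el.set("id", ev.id)
            el.set("useValuesFromTriggerTime", "true")
            trig = etree.SubElement(el, _c("trigger"))
            trig.set("initialValue", "true")
            trig.set("persistent", "true")
            trig.append(math_element(ev.trigger))
            loea = etree.SubElement(el, _c("listOfEventAssignments"))
            for target, expr in ev.assignments:
                ea = etree.SubElement(loea, _c("eventAssignment"))
                ea.set("variable", target)
                ea.append(math_element(expr))

    # fbc v1
    if fbc_on:
        if model.fbc.constraints:
            lofb = etree.SubElement(mel, _f("listOfFluxBounds"))
            for con in model.fbc.constraints:
                fb = etree.SubElement(lofb, _f("fluxBound"))
                fb.set(_f("id"), con.id)
                fb.set(_f("reaction"), con.reaction)
                fb.set(_f("operation"),
                       {"<=": "lessEqual", ">=": "greaterEqual",
                        "=": "equal"}[con.comparator])
                fb.set(_f("value"), format_number(con.bound))
        if model.fbc.objectives:
            loo = etree.SubElement(mel, _f("listOfObjectives"))
            loo.set(_f("activeObjective"), model.fbc.objectives[0].id)
            for obj in model.fbc.objectives:
                ob = etree.SubElement(loo, _f("objective"))
                ob.set(_f("id"), obj.id)
                ob.set(_f("type"), obj.sense)
                lofo = etree.SubElement(ob, _f("listOfFluxObjectives"))
                for reaction, coeff in obj.terms:
                    fo = etree.SubElement(lofo, _f("fluxObjective"))
                    fo.set(_f("reaction"), reaction)
                    fo.set(_f("coefficient"), format_number(coeff))

    return SbmlDocument(root, fbc_enabled=fbc_on, distrib_enabled=distrib_on)


def _append_uncertainty(el: etree._Element, model: Model, symbol: str) -> None:
    rec = model.uncertainty.get(symbol)
    if rec is None or rec.is_empty():
        return
    lou = etree.SubElement(el, _d("listOfUncertainties"))
    unc = etree.SubElement(lou, _d("uncertainty"))
    _TYPE = {"stdev": "standardDeviation"}
    for attr in distributions.SCALAR_ATTRIBUTES:
        if attr in rec.scalars:
            up = etree.SubElement(unc, _d("uncertParameter"))
            up.set(_d("type"), _TYPE.get(attr, attr))
            _set_value_or_var(up, rec.scalars[attr])
    for attr in distributions.INTERVAL_ATTRIBUTES:
        if attr in rec.intervals:
            lo, hi = rec.intervals[attr]
            span = etree.SubElement(unc, _d("uncertSpan"))
            span.set(_d("type"), attr)
            _set_span_bound(span, "Lower", lo)
            _set_span_bound(span, "Upper", hi)
    if rec.distribution is not None:
        up = etree.SubElement(unc, _d("uncertParameter"))
        up.set(_d("type"), "distribution")
        if isinstance(rec.distribution, str):
            up.set(_d("definitionURL"), rec.distribution)
        else:
            up.append(math_element(rec.distribution))
    ep = rec.external_parameter
    if ep is not None:
        if isinstance(ep, tuple):
            span = etree.SubElement(unc, _d("uncertSpan"))
            span.set(_d("type"), "externalParameter")
            _set_span_bound(span, "Lower", ep[0])
            _set_span_bound(span, "Upper", ep[1])
        else:
            up = etree.SubElement(unc, _d("uncertParameter"))
            up.set(_d("type"), "externalParameter")
            if isinstance(ep, str):
                up.set(_d("definitionURL"), ep)
            elif _is_literal(ep) is not None or isinstance(ep, Sym):
                _set_value_or_var(up, ep)
            else:
                up.append(math_element(ep))


def _set_value_or_var(el: etree._Element, expr: Expr) -> None:
    lit = _is_literal(expr)
    if lit is not None:
        el.set(_d("value"), format_number(lit))
    elif isinstance(expr, Sym):
        el.set(_d("var"), expr.name)
    else:
        el.append(math_element(expr))


def _set_span_bound(el: etree._Element, which: str, expr: Expr) -> None:
    lit = _is_literal(expr)
    if lit is not None:
        el.set(_d(f"value{which}"), format_number(lit))
    elif isinstance(expr, Sym):
        el.set(_d(f"var{which}"), expr.name)
    else:
        raise LanguageError("uncertainty span bounds must be numbers "
                            "or symbols")


# --------------------------------------------------------------------------
# Structural validation
# --------------------------------------------------------------------------


def validate_document(doc: SbmlDocument) -> List[Diagnostic]:
    """Structural checks on a document (SIds, references, compartments)."""
    diags: List[Diagnostic] = []
    root = doc.root
    if etree.QName(root).localname != "sbml":
        diags.append(Diagnostic(Severity.ERROR, "root element is not <sbml>"))
        return diags
    mel = root.find(_c("model"))
    if mel is None:
        diags.append(Diagnostic(Severity.ERROR, "missing <model> element"))
        return diags
    ids: List[str] = []
    for el in mel.iter():
        if not isinstance(el.tag, str) or \
                not el.tag.startswith("{" + SBML_CORE_NS):
            continue
        sid = el.get("id")
        if sid is not None:
            ids.append(sid)
            if not _SID_RE.match(sid):
                diags.append(Diagnostic(Severity.ERROR,
                                        f"invalid SId '{sid}'"))
    dup = {i for i in ids if ids.count(i) > 1}
    for d in sorted(dup):
        diags.append(Diagnostic(Severity.ERROR, f"duplicate SId '{d}'"))
    compartments = {c.get("id") for c in
                    mel.findall(f"{_c('listOfCompartments')}/"
                                f"{_c('compartment')}")}
    for sp in mel.findall(f"{_c('listOfSpecies')}/{_c('species')}"):
        comp = sp.get("compartment")
        if comp is None:
            diags.append(Diagnostic(
                Severity.ERROR,
                f"species '{sp.get('id')}' lacks a compartment"))
        elif comp not in compartments:
            diags.append(Diagnostic(
                Severity.ERROR,
                f"species '{sp.get('id')}' references unknown "
                f"compartment '{comp}'"))
    return diags


# --------------------------------------------------------------------------
# Import
# --------------------------------------------------------------------------


def read_document(source: Union[bytes, str]) -> SbmlDocument:
    """Parse XML bytes (or a file path) into an SbmlDocument."""
    if isinstance(source, str) and not source.lstrip().startswith("<"):
        with open(source, "rb") as fh:
            data = fh.read()
    elif isinstance(source, str):
        data = source.encode("utf-8")
    else:
        data = source
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise LanguageError(f"malformed XML: {exc}") from None
    return SbmlDocument(root)


def import_sbml(doc: Union[SbmlDocument, bytes, str],
                sink: Optional[DiagnosticSink] = None) -> Model:
    """Rebuild a Model from the SBML subset this module emits.

    Unsupported constructs (function definitions, units, event delays
    and priorities) are dropped with a warning; a required package
    other than the supported fbc-v1/distrib pair, or an fbc version
    other than 1, is an error.
    """
    if not isinstance(doc, SbmlDocument):
        doc = read_document(doc)
    sink = sink or DiagnosticSink()
    m = Model(diagnostics=sink)
    root = doc.root
    if etree.QName(root).localname != "sbml":
        raise LanguageError("not an SBML document (root is not <sbml>)")

    for prefix, uri in (root.nsmap or {}).items():
        if "/fbc/" in uri and uri != FBC_V1_NS:
            version = uri.rsplit("version", 1)[-1]
            sink.error(f"unsupported package: fbc version {version} "
                       "(only version 1 is supported)")
        elif uri.startswith("http://www.sbml.org/sbml/level3/") and \
                uri not in (SBML_CORE_NS, FBC_V1_NS, DISTRIB_NS) and \
                "/core" not in uri:
            required = root.get(f"{{{uri}}}required", "false")
            if required == "true":
                sink.error(f"unsupported required package: {uri}")
            else:
                sink.warn(f"ignoring unsupported package: {uri}")

    mel = root.find(_c("model"))
    if mel is None:
        return m
    model_id = mel.get("id")
    if model_id and model_id != "__main":
        m.name = model_id

    m.metadata = meta_mod.parse_annotation(mel.find(_c("notes")),
                                           mel.find(_c("annotation")))

    if mel.find(_c("listOfFunctionDefinitions")) is not None:
        sink.warn("function definitions are not supported and were dropped")
    if mel.find(_c("listOfUnitDefinitions")) is not None:
        sink.warn("unit definitions are not supported and were dropped")

    for comp in mel.findall(f"{_c('listOfCompartments')}/{_c('compartment')}"):
        cid = comp.get("id")
        if cid != DEFAULT_COMPARTMENT and comp.get("size") not in ("1", "1.0",
                                                                   None):
            sink.warn(f"compartment '{cid}' has size != 1; species values "
                      "are treated as concentrations in a unit volume")

    for sp in mel.findall(f"{_c('listOfSpecies')}/{_c('species')}"):
        species = Species(sp.get("id"),
                          boundary=sp.get("boundaryCondition") == "true",
                          compartment=sp.get("compartment",
                                             DEFAULT_COMPARTMENT))
        conc = sp.get("initialConcentration", sp.get("initialAmount"))
        if conc is not None:
            species.initial = _number_expr(float(conc))
        m.species[species.id] = species
        _read_uncertainty(sp, m, species.id)

    for par in mel.findall(f"{_c('listOfParameters')}/{_c('parameter')}"):
        parameter = Parameter(par.get("id"),
                              constant=par.get("constant") != "false")
        value = par.get("value")
        if value is not None:
            parameter.initial = _number_expr(float(value))
        m.parameters[parameter.id] = parameter
        _read_uncertainty(par, m, parameter.id)

    for rxn_el in mel.findall(f"{_c('listOfReactions')}/{_c('reaction')}"):
        rxn = Reaction(rxn_el.get("id"),
                       reversible=rxn_el.get("reversible") != "false")
        for tag, out in (("listOfReactants", rxn.reactants),
                         ("listOfProducts", rxn.products)):
            for sr in rxn_el.findall(f"{_c(tag)}/{_c('speciesReference')}"):
                sid = sr.get("id")
                if sid is not None:
                    stoich: Union[float, str] = sid
                    m.stoich_symbols.setdefault(sid, None)
                    m.parameters.setdefault(sid, Parameter(sid))
                else:
                    stoich = float(sr.get("stoichiometry", "1"))
                out.append(Participant(sr.get("species"), stoich))
        kl = rxn_el.find(f"{_c('kineticLaw')}/{_m('math')}")
        if kl is not None:
            rxn.kinetic_law = mathml_to_expr(kl)
        _read_uncertainty(rxn_el, m, rxn.id)
        m.reactions[rxn.id] = rxn

    for ia in mel.findall(f"{_c('listOfInitialAssignments')}/"
                          f"{_c('initialAssignment')}"):
        symbol = ia.get("symbol")
        math = ia.find(_m("math"))
        expr = mathml_to_expr(math) if math is not None else Num(0.0)
        if symbol in m.species:
            m.species[symbol].initial = expr
        else:
            m.parameters.setdefault(symbol, Parameter(symbol)).initial = expr

    for rule_el in mel.findall(_c("listOfRules") + "/*"):
        tag = etree.QName(rule_el).localname
        math = rule_el.find(_m("math"))
        formula = mathml_to_expr(math) if math is not None else Num(0.0)
        if tag == "assignmentRule":
            target = rule_el.get("variable")
            m.rules.append(Rule("continuous", target, formula))
            if target in m.parameters:
                m.parameters[target].constant = False
        elif tag == "rateRule":
            target = rule_el.get("variable")
            m.rules.append(Rule("rate", target, formula))
            if target in m.parameters:
                m.parameters[target].constant = False
        elif tag == "algebraicRule":
            m.rules.append(Rule("algebraic", None, formula,
                                rule_el.get("id")))

    for ev_el in mel.findall(f"{_c('listOfEvents')}/{_c('event')}"):
        if ev_el.find(_c("delay")) is not None:
            sink.warn(f"event '{ev_el.get('id')}' delay dropped")
        if ev_el.find(_c("priority")) is not None:
            sink.warn(f"event '{ev_el.get('id')}' priority dropped")
        trig = ev_el.find(f"{_c('trigger')}/{_m('math')}")
        trigger = mathml_to_expr(trig) if trig is not None else Num(0.0)
        ev = Event(ev_el.get("id", f"_E{len(m.events)}"), trigger)
        for ea in ev_el.findall(f"{_c('listOfEventAssignments')}/"
                                f"{_c('eventAssignment')}"):
            math = ea.find(_m("math"))
            if math is not None:
                target = ea.get("variable")
                ev.assignments.append((target, mathml_to_expr(math)))
                if target in m.parameters:
                    m.parameters[target].constant = False
        m.events.append(ev)

    _read_fbc(mel, m, sink)
    return m


def _number_expr(value: float) -> Expr:
    return Num(value)


def _read_fbc(mel: etree._Element, m: Model, sink: DiagnosticSink) -> None:
    for fb in mel.findall(f"{_f('listOfFluxBounds')}/{_f('fluxBound')}"):
        op = fb.get(_f("operation"))
        comparator = {"lessEqual": "<=", "greaterEqual": ">=",
                      "equal": "="}.get(op)
        if comparator is None:
            sink.warn(f"fluxBound operation '{op}' not supported; dropped")
            continue
        m.fbc.constraints.append(FluxConstraint(
            fb.get(_f("id")), fb.get(_f("reaction")), comparator,
            float(fb.get(_f("value")))))
    loo = mel.find(_f("listOfObjectives"))
    if loo is None:
        return
    active = loo.get(_f("activeObjective"))
    objectives: List[Objective] = []
    for ob in loo.findall(_f("objective")):
        terms = tuple(
            (fo.get(_f("reaction")), float(fo.get(_f("coefficient"), "1")))
            for fo in ob.findall(f"{_f('listOfFluxObjectives')}/"
                                 f"{_f('fluxObjective')}"))
        objectives.append(Objective(ob.get(_f("id")), ob.get(_f("type")),
                                    terms))
    objectives.sort(key=lambda o: 0 if o.id == active else 1)
    m.fbc.objectives = objectives


def _read_uncertainty(el: etree._Element, m: Model, symbol: str) -> None:
    unc = el.find(f"{_d('listOfUncertainties')}/{_d('uncertainty')}")
    if unc is None:
        return
    rec = distributions.UncertaintyRecord()
    _CANON = {"standardDeviation": "stdev"}
    for child in unc:
        tag = etree.QName(child).localname
        utype = child.get(_d("type"))
        if tag == "uncertParameter":
            name = _CANON.get(utype, utype)
            if name in distributions.SCALAR_ATTRIBUTES:
                rec.scalars[name] = _get_value_or_var(child)
            elif name == "distribution":
                url = child.get(_d("definitionURL"))
                math = child.find(_m("math"))
                rec.distribution = url if url is not None else (
                    mathml_to_expr(math) if math is not None else None)
            elif name == "externalParameter":
                url = child.get(_d("definitionURL"))
                math = child.find(_m("math"))
                if url is not None:
                    rec.external_parameter = url
                elif math is not None:
                    rec.external_parameter = mathml_to_expr(math)
                else:
                    rec.external_parameter = _get_value_or_var(child)
        elif tag == "uncertSpan":
            lo = _get_span_bound(child, "Lower")
            hi = _get_span_bound(child, "Upper")
            if utype == "externalParameter":
                rec.external_parameter = (lo, hi)
            elif utype in distributions.INTERVAL_ATTRIBUTES:
                rec.intervals[utype] = (lo, hi)
    if not rec.is_empty():
        m.uncertainty[symbol] = rec


def _get_value_or_var(el: etree._Element) -> Expr:
    value = el.get(_d("value"))
    if value is not None:
        return Num(float(value))
    var = el.get(_d("var"))
    if var is not None:
        return Sym(var)
    math = el.find(_m("math"))
    return mathml_to_expr(math) if math is not None else Num(0.0)


def _get_span_bound(el: etree._Element, which: str) -> Expr:
    value = el.get(_d(f"value{which}"))
    if value is not None:
        return Num(float(value))
    var = el.get(_d(f"var{which}"))
    return Sym(var) if var is not None else Num(0.0)
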