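"""SBML L3V2 export/import: structure, round trips, MathML fidelity."""
from __future__ import annotations

import numpy as np
import pytest

from stibnite import (build_model, export_sbml, import_sbml, loads, unparse,
                      validate_document)
from stibnite.diagnostics import LanguageError
from stibnite.dynamics import compile_model
from stibnite.grammar import parse_expression
from stibnite.sbml import (FBC_V1_NS, SBML_CORE_NS, math_element,
                           mathml_to_expr, read_document)
from tests.conftest import model_signature


def _core(doc, path):
    return doc.root.findall(
        "/".join(f"{{{SBML_CORE_NS}}}{p}" for p in path.split("/")))


class TestExport:
    def test_single_reaction_document_structure(self, models):
        doc = export_sbml(models["listing01"])
        assert len(_core(doc, "model/listOfSpecies/species")) == 2
        assert len(_core(doc, "model/listOfParameters/parameter")) == 1
        reactions = _core(doc, "model/listOfReactions/reaction")
        assert len(reactions) == 1
        kl = reactions[0].find(f"{{{SBML_CORE_NS}}}kineticLaw")
        assert kl is not None

    def test_empty_model_exports_and_validates(self):
        doc = export_sbml(build_model([]))
        assert validate_document(doc) == []

    def test_every_listing_export_validates(self, models):
        for name, m in models.items():
            assert validate_document(export_sbml(m)) == [], name

    def test_boundary_species_flagged(self, models):
        doc = export_sbml(models["listing05"])
        flags = {sp.get("id"): sp.get("boundaryCondition")
                 for sp in _core(doc, "model/listOfSpecies/species")}
        assert flags["A"] == "true"
        assert flags["X"] == "true"
        assert flags["Y"] == "false"

    def test_symbolic_stoichiometry_becomes_species_reference_ids(self,
                                                                  models):
        doc = export_sbml(models["listing12"])
        srs = _core(doc, "model/listOfReactions/reaction/"
                         "listOfReactants/speciesReference") + \
            _core(doc, "model/listOfReactions/reaction/"
                       "listOfProducts/speciesReference")
        ids = {sr.get("id") for sr in srs if sr.get("id")}
        assert ids == {"n", "m"}
        assert len(_core(doc, "model/listOfRules/assignmentRule")) == 1
        assert len(_core(doc, "model/listOfInitialAssignments/"
                              "initialAssignment")) == 1
        # the stoichiometry symbols are not duplicated as parameters
        params = {p.get("id")
                  for p in _core(doc, "model/listOfParameters/parameter")}
        assert ids.isdisjoint(params)

    def test_rules_serialize_by_kind(self, models):
        doc = export_sbml(models["listing13"])
        rules = _core(doc, "model/listOfRules/algebraicRule")
        assert len(rules) == 2
        assert rules[1].get("id") == "alg2"

    def test_fbc_v1_lists(self, models):
        doc = export_sbml(models["listing11"])
        fb = doc.root.findall(f".//{{{FBC_V1_NS}}}fluxBound")
        assert len(fb) == 6
        assert fb[0].get(f"{{{FBC_V1_NS}}}operation") == "greaterEqual"
        objs = doc.root.findall(f".//{{{FBC_V1_NS}}}objective")
        assert len(objs) == 1
        fos = doc.root.findall(f".//{{{FBC_V1_NS}}}fluxObjective")
        assert [(f.get(f"{{{FBC_V1_NS}}}reaction"),
                 f.get(f"{{{FBC_V1_NS}}}coefficient"))
                for f in fos] == [("R16", "1"), ("R03", "1")]

    def test_uncertainty_elements_emitted(self, models):
        doc = export_sbml(models["listing10"])
        ns = "http://www.sbml.org/sbml/level3/version1/distrib/version1"
        ups = doc.root.findall(f".//{{{ns}}}uncertParameter")
        spans = doc.root.findall(f".//{{{ns}}}uncertSpan")
        assert len(ups) == 12  # 10 scalars + distribution + externalParameter
        assert len(spans) == 4


class TestImport:
    def test_import_export_round_trip_preserves_models(self, models):
        for name, m1 in models.items():
            m2 = import_sbml(export_sbml(m1).to_bytes())
            assert not m2.diagnostics.has_errors(), name
            m3 = loads(unparse(m2))
            assert model_signature(m1) == model_signature(m3), name

    def test_second_export_is_byte_identical(self, models):
        for name, m1 in models.items():
            x1 = export_sbml(m1).to_bytes()
            m2 = import_sbml(x1)
            x2 = export_sbml(loads(unparse(m2))).to_bytes()
            assert x1 == x2, name

    def test_minimal_empty_document_imports_to_empty_model(self):
        data = (f'<sbml xmlns="{SBML_CORE_NS}" level="3" version="2">'
                f'<model id="__main"/></sbml>').encode()
        m = import_sbml(data)
        assert m.name is None
        assert not m.species and not m.reactions

    def test_fbc_v2_namespace_is_unsupported(self):
        ns2 = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
        data = (f'<sbml xmlns="{SBML_CORE_NS}" xmlns:fbc="{ns2}" '
                f'level="3" version="2"><model id="m"/></sbml>').encode()
        m = import_sbml(data)
        assert any("version 2" in d.message for d in m.diagnostics.errors)

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(LanguageError, match="malformed"):
            read_document(b"<sbml><model></sbml>")

    def test_unsupported_constructs_warn_and_drop(self):
        data = (f'<sbml xmlns="{SBML_CORE_NS}" level="3" version="2">'
                f'<model id="m"><listOfFunctionDefinitions/>'
                f'<listOfUnitDefinitions/></model></sbml>').encode()
        m = import_sbml(data)
        msgs = " ".join(d.message for d in m.diagnostics.warnings)
        assert "function definitions" in msgs
        assert "unit definitions" in msgs


class TestMathML:
    @pytest.mark.parametrize("text", [
        "k1*A", "k3*B - k4*C", "1 + amp*sin(time*freq)", "k1*S1^n",
        "-(-x)", "a/b + c*d^2", "exp(-k*time) + ln(x)", "rateOf(S1) + 1",
        "x > 3", "normal(0.5, 0.2)",
    ])
    def test_mathml_round_trip_is_identity(self, text):
        expr = parse_expression(text)
        assert mathml_to_expr(math_element(expr)) == expr

    def test_emitted_mathml_evaluates_like_the_source_tree(self):
        """Serialization preserves numeric semantics at random bindings."""
        texts = ["k1*A", "k3*B - k4*C", "a/b + c*d^2",
                 "1 + a*sin(time*b)", "-(x^2) + exp(-y)"]
        m = loads("q -> w; 1\nq = 1\n")  # carrier model for the evaluator
        sys = compile_model(m)
        rng = np.random.default_rng(2024)
        for text in texts:
            expr = parse_expression(text)
            back = mathml_to_expr(math_element(expr))
            from stibnite.syntax import expr_symbols
            for _ in range(100):
                env = {s: float(rng.uniform(0.1, 3.0))
                       for s in expr_symbols(expr)}
                t = float(rng.uniform(0.0, 10.0))
                assert sys.evaluate(back, t, env) == \
                    pytest.approx(sys.evaluate(expr, t, env), rel=1e-12)
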