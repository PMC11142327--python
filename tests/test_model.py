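"""Semantic model building: classification, restrictions, unparse."""
from __future__ import annotations

import itertools

import pytest

from stibnite import (build_model, check_distribution_contexts,
                      check_rateof_usage, loads, parse, unparse)
from tests.conftest import model_signature


class TestClassification:
    def test_branched_pathway_counts(self, models):
        m = models["listing02"]
        assert list(m.species) == ["A", "B", "C", "D"]
        assert sorted(m.parameters) == ["k1", "k2", "k3", "k4"]
        assert len(m.reactions) == 3

    def test_empty_statement_list_gives_empty_anonymous_model(self):
        m = build_model([])
        assert m.name is None
        assert not m.species and not m.parameters and not m.reactions

    def test_symbolic_stoichiometry_declares_parameters(self, models):
        m = models["listing12"]
        assert set(m.stoich_symbols) == {"n", "m"}
        assert "n" in m.parameters and "m" in m.parameters
        j1 = m.reactions["J1"]
        assert j1.reactants[0].stoichiometry == "n"
        assert j1.products[0].stoichiometry == "m"
        rule = m.rule_for("n", "continuous")
        assert rule is not None
        from stibnite.syntax import unparse_expr
        assert unparse_expr(rule.formula) == "k2 / 2"
        assert unparse_expr(m.parameters["m"].initial) == "2 / 3"

    def test_dollar_marks_boundary_species(self, models):
        m = models["listing05"]
        assert m.species["A"].boundary
        assert m.species["X"].boundary
        assert not m.species["Y"].boundary

    def test_unnamed_reactions_are_autonamed_in_source_order(self, models):
        assert list(models["listing02"].reactions) == ["_J0", "_J1", "_J2"]

    def test_species_plus_parameters_cover_all_plain_identifiers(self, models):
        for name, m in models.items():
            ids = set(m.species) | set(m.parameters)
            assert not (set(m.species) & set(m.parameters)), name
            assert set(m.reactions).isdisjoint(ids), name

    def test_uninitialized_symbol_warns_and_defaults(self):
        m = loads("A -> B; k1*A\nA = 1\n")
        assert any("k1" in d.message for d in m.diagnostics.warnings)
        assert not m.diagnostics.has_errors()

    def test_duplicate_initialization_last_wins_with_warning(self):
        m = loads("A -> B; k*A\nA = 1\nA = 7\nk = 1\n")
        from stibnite.syntax import Num
        assert m.species["A"].initial == Num(7.0)
        assert any("more than once" in d.message
                   for d in m.diagnostics.warnings)


class TestRestrictions:
    def test_rate_ruled_reaction_species_requires_boundary_mark(self):
        m = loads("J1: A + B -> C; k1*A*B\nA' = k2*A\n")
        assert any("boundary" in d.message for d in m.diagnostics.errors)

    def test_boundary_marked_rate_rule_is_accepted(self, models):
        assert not models["listing06"].diagnostics.has_errors()

    def test_assignment_and_rate_rule_conflict(self):
        m = loads("x := 2*y\nx' = y\ny = 1\n")
        assert any("mutually exclusive" in d.message
                   for d in m.diagnostics.errors)

    def test_cyclic_assignment_rules_rejected(self):
        m = loads("a := b + 1\nb := a + 1\n")
        assert any("cyclic" in d.message.lower()
                   for d in m.diagnostics.errors)

    def test_unknown_function_is_a_semantic_error(self):
        m = loads("A -> B; frobnicate(A)\nA = 1\n")
        assert any("frobnicate" in d.message for d in m.diagnostics.errors)


class TestRateOfChecks:
    def test_rateof_of_species_and_rate_rule_target_is_clean(self, models):
        assert check_rateof_usage(models["listing08"]) == []

    def test_rateof_of_reaction_is_one_error(self):
        m = loads("J0: A -> B; k*A\nX := rateOf(J0)\nA = 1\nk = 0.1\n")
        diags = check_rateof_usage(m)
        assert len(diags) == 1
        assert "J0" in diags[0].message

    def test_rateof_of_assignment_target_is_an_error(self):
        m = loads("y := 2*z\nx := rateOf(y)\nz = 1\n")
        diags = check_rateof_usage(m)
        assert len(diags) == 1

    def test_model_without_rateof_is_clean(self, models):
        assert check_rateof_usage(models["listing02"]) == []


class TestDistributionContexts:
    def test_draws_in_initials_and_events_are_clean(self, models):
        assert check_distribution_contexts(models["listing09"]) == []

    def test_draw_in_kinetic_law_is_one_error(self):
        m = loads("J: A -> B; uniform(0,1)*A\nA = 1\n")
        diags = check_distribution_contexts(m)
        assert len(diags) == 1

    def test_draw_in_assignment_rule_is_one_error(self):
        m = loads("X := normal(0,1)\n")
        diags = check_distribution_contexts(m)
        assert len(diags) == 1

    def test_draw_in_rate_rule_is_an_error(self):
        m = loads("X' = normal(0,1)\nX = 0\n")
        assert len(check_distribution_contexts(m)) == 1


class TestUnparse:
    def test_unparse_is_a_fixed_point_for_every_listing(self, listings):
        for name, text in listings.items():
            once = unparse(loads(text))
            twice = unparse(loads(once))
            assert once == twice, name

    def test_unparse_reparses_to_identical_model(self, listings):
        for name, text in listings.items():
            m1 = loads(text)
            m2 = loads(unparse(m1))
            assert model_signature(m1) == model_signature(m2), name

    def test_empty_model_unparse_is_empty(self):
        assert unparse(build_model([])) == ""

    def test_fbc_constraints_survive_unparse(self, models):
        text = unparse(models["listing11"])
        assert text.count("constraint c") == 6
        assert "OBJF: maximize R16 + R03" in text

    def test_initial_assignment_order_is_immaterial(self):
        inits = ["k1 = 0.1", "k2 = 0.2", "k3 = 0.15", "k4 = 3.4"]
        base = ("A -> B; k1*A\nB -> C; k2*B\nB -> D; k3*B - k4*C\n"
                "A = 5; B = 0; C = 0; D = 0\n")
        reference = None
        for perm in itertools.permutations(inits):
            sig = model_signature(loads(base + "\n".join(perm) + "\n"))
            reference = reference or sig
            assert sig == reference
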