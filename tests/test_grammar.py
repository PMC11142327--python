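"""Lexer and parser behaviour: tokens, statements, precedence, errors."""
from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from stibnite.diagnostics import LanguageError
from stibnite.grammar import normalize_text, parse, parse_expression, tokenize
from stibnite.syntax import (AlgRuleStmt, Binary, Call, ContAssignStmt,
                             EventStmt, InitAssignStmt, MetadataStmt,
                             ModelBeginStmt, ModelEndStmt, Num, ObjectiveStmt,
                             RateRuleStmt, ReactionStmt, Sym, TimeSym, Unary,
                             UncertaintyStmt, unparse_expr)


class TestTokenizer:
    def test_single_reaction_token_kinds(self):
        kinds = [t.kind for t in tokenize("A −> B; k1*A")]
        assert kinds == ["ID", "ARROW", "ID", "SEMI", "ID", "STAR", "ID"]

    def test_empty_input_gives_no_tokens(self):
        assert tokenize("") == []

    def test_boundary_mark_precedes_identifier(self):
        kinds = [t.kind for t in tokenize("$X −> Y; k1*X")]
        assert kinds[0] == "BOUNDARY"
        assert kinds[1] == "ID"

    def test_unicode_minus_equals_ascii_minus(self):
        assert [t.kind for t in tokenize("a − b")] == \
            [t.kind for t in tokenize("a - b")]

    def test_typographic_quotes_delimit_strings(self):
        (tok,) = tokenize("“hello”")
        assert tok.kind == "STRING" and tok.text == "hello"

    def test_comment_dropped_to_end_of_line(self):
        kinds = [t.kind for t in tokenize("a // comment ; b\nc")]
        assert kinds == ["ID", "NEWLINE", "ID"]

    def test_prime_requires_adjacent_identifier(self):
        assert [t.kind for t in tokenize("A' = 1")][1] == "PRIME"
        with pytest.raises(LanguageError):
            tokenize("A ' = 1")

    def test_unterminated_string_reports_location(self):
        with pytest.raises(LanguageError) as err:
            tokenize('x = "oops')
        assert err.value.loc is not None
        assert err.value.loc.line == 1

    def test_normalized_listing_tokenizes_identically(self, listings):
        for text in listings.values():
            original = [t.kind for t in tokenize(text)]
            ascii_form = [t.kind for t in tokenize(normalize_text(text))]
            assert original == ascii_form


class TestStatementParsing:
    def test_branched_pathway_statement_mix(self, listings):
        stmts = parse(listings["listing02"])
        assert sum(isinstance(s, ReactionStmt) for s in stmts) == 3
        assert sum(isinstance(s, InitAssignStmt) for s in stmts) == 8

    def test_named_algebraic_rule(self):
        (stmt,) = parse("alg2: 0 = S2*k2 – 20")
        assert isinstance(stmt, AlgRuleStmt)
        assert stmt.name == "alg2"

    def test_event_body_is_indented_run(self):
        stmts = parse("if S1 > 10:\n"
                      "  k0 = uniform(2.5, 5.5)\n"
                      "  k1 = 2\n"
                      "S0 = 1\n")
        assert isinstance(stmts[0], EventStmt)
        assert [t for t, _ in stmts[0].assignments] == ["k0", "k1"]
        assert isinstance(stmts[1], InitAssignStmt)

    def test_event_with_empty_body_is_an_error(self):
        with pytest.raises(LanguageError):
            parse("if S1 > 10:\nS0 = 1\n")

    @pytest.mark.parametrize("text, kind", [
        ("X := 1 + amp*sin(time*freq)", ContAssignStmt),
        ("$A' = k2 * A", RateRuleStmt),
        ("model mymodel()", ModelBeginStmt),
        ("end", ModelEndStmt),
        ('model notes "hi"', MetadataStmt),
        ("OBJF: maximize R16 + R03", ObjectiveStmt),
        ("A.mean = 2.4", UncertaintyStmt),
        ('A.distribution is "http://x.org/d"', UncertaintyStmt),
    ])
    def test_statement_variants(self, text, kind):
        (stmt,) = parse(text)
        assert isinstance(stmt, kind)

    def test_reaction_with_stoichiometries(self):
        (stmt,) = parse("2 C -> D + E; k2*C")
        assert stmt.reactants[0].stoichiometry == 2.0
        (stmt,) = parse("J1: n S1 -> m S2; k1*S1^n")
        assert stmt.reactants[0].stoichiometry == "n"
        assert stmt.products[0].stoichiometry == "m"

    def test_reaction_without_rate_law(self):
        (stmt,) = parse("R16: A -> B")
        assert stmt.rate_law is None

    def test_every_listing_parses(self, listings):
        for name, text in listings.items():
            assert parse(text), name

    def test_syntax_error_carries_location_in_bounds(self):
        text = "A = 5\nB = ^\n"
        with pytest.raises(LanguageError) as err:
            parse(text)
        loc = err.value.loc
        assert loc is not None
        assert 1 <= loc.line <= text.count("\n") + 1
        assert loc.column >= 1


class TestExpressions:
    def test_power_binds_tighter_than_times(self):
        expr = parse_expression("k1*S1^n")
        assert expr == Binary("*", Sym("k1"),
                              Binary("^", Sym("S1"), Sym("n")))

    def test_double_negation_evaluates_to_identity(self):
        expr = parse_expression("-(-x)")
        assert expr == Unary("-", Unary("-", Sym("x")))

    def test_forcing_function_shape(self):
        expr = parse_expression("1 + amp*sin (time*freq)")
        assert expr.op == "+"
        product = expr.right
        assert product.op == "*"
        call = product.right
        assert isinstance(call, Call) and call.callee == "sin"
        assert call.args[0] == Binary("*", TimeSym(), Sym("freq"))

    def test_trailing_tokens_rejected(self):
        with pytest.raises(LanguageError):
            parse_expression("a + b c")

    @pytest.mark.parametrize("a", "+-*/^")
    @pytest.mark.parametrize("b", "+-*/^")
    def test_two_operator_combinations_match_python_semantics(self, a, b):
        """Parse trees agree with Python's precedence (oracle: eval).

        Every 3-operand combination of the five binary operators is
        evaluated at fixed operand values through the parsed tree and
        through Python, whose precedence/associativity rules for these
        operators coincide with the language's.
        """
        text = f"x {a} y {b} z"
        values = {"x": 2.0, "y": 3.0, "z": 5.0}
        expected = eval(text.replace("^", "**"), {}, values)
        got = _eval_tree(parse_expression(text), values)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_power_is_right_associative(self):
        assert _eval_tree(parse_expression("2^3^2"), {}) == 512.0

    def test_unary_minus_binds_looser_than_power(self):
        assert _eval_tree(parse_expression("-2^2"), {}) == -4.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.recursive(
        st.one_of(
            st.integers(0, 9).map(lambda n: Num(float(n))),
            st.sampled_from("abc").map(Sym),
            st.just(TimeSym()),
        ),
        lambda inner: st.one_of(
            st.tuples(st.sampled_from("+-*/^"), inner, inner)
            .map(lambda t: Binary(*t)),
            inner.map(lambda e: Unary("-", e)),
            st.tuples(st.sampled_from(["sin", "exp"]), inner)
            .map(lambda t: Call(t[0], (t[1],))),
        ),
        max_leaves=12,
    ))
    def test_unparse_parse_round_trip(self, expr):
        assert parse_expression(unparse_expr(expr)) == expr


def _eval_tree(expr, values):
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Sym):
        return values[expr.name]
    if isinstance(expr, Unary):
        return -_eval_tree(expr.child, values)
    if isinstance(expr, Binary):
        a = _eval_tree(expr.left, values)
        b = _eval_tree(expr.right, values)
        return {"+": a + b, "-": a - b, "*": a * b, "/": a / b,
                "^": a ** b}[expr.op]
    raise AssertionError(expr)
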