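"""Lexer and recursive-descent parser for the Antimony dialect.

The language is line-oriented: statements are separated by newlines or
``;``.  A reaction statement additionally consumes one ``;`` followed by
its kinetic law, e.g. ``A -> B; k1*A``.  Unicode typography that appears
in typeset model text (U+2212 minus, en/em dashes, curly quotes and
apostrophes) is normalized to ASCII before lexing, so ``A −> B`` and
``A -> B`` tokenize identically.

Event statements use an indented block::

    if S1 > 10:
        k0 = uniform(2.5, 5.5)

The event body is the maximal run of statements indented further than
the ``if`` line.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

from .diagnostics import LanguageError, SourceLocation
from .syntax import (
    AlgRuleStmt,
    AstParticipant,
    Binary,
    Call,
    ConstraintStmt,
    ContAssignStmt,
    EventStmt,
    Expr,
    InitAssignStmt,
    MetadataStmt,
    ModelBeginStmt,
    ModelEndStmt,
    Num,
    ObjectiveStmt,
    RateRuleStmt,
    ReactionStmt,
    Stmt,
    Sym,
    TimeSym,
    Unary,
    UncertaintyStmt,
)

# --------------------------------------------------------------------------
# Lexer
# --------------------------------------------------------------------------

# Unicode typography -> ASCII, 1:1 so source columns survive.
_NORMALIZE = str.maketrans({
    "−": "-",   # minus sign
    "–": "-",   # en dash
    "—": "-",   # em dash
    "‘": "'",   # curly single quotes
    "’": "'",
    "“": '"',   # curly double quotes
    "”": '"',
})


def normalize_text(text: str) -> str:
    """Map typographic minus/dash/quote characters to ASCII equivalents."""
    return text.translate(_NORMALIZE)


@dataclass(frozen=True)
class Token:
    kind: str
    text: str
    loc: SourceLocation


_TWO_CHAR = {"->": "ARROW", ":=": "BECOMES", ">=": "GE", "<=": "LE",
             "==": "EQEQ", "!=": "NEQ"}
_ONE_CHAR = {"+": "PLUS", "-": "MINUS", "*": "STAR", "/": "SLASH",
             "^": "CARET", "(": "LPAREN", ")": "RPAREN", "{": "LBRACE",
             "}": "RBRACE", ",": "COMMA", ".": "DOT", ":": "COLON",
             ";": "SEMI", "=": "ASSIGN", ">": "GT", "<": "LT"}

_ID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_NUM_RE = re.compile(r"(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def tokenize(text: str) -> List[Token]:
    """Lex Antimony-dialect text into a token sequence (no EOF token).

    ``//`` comments run to end of line; newlines become NEWLINE tokens;
    ``$`` immediately before an identifier is a BOUNDARY token and ``'``
    immediately after an identifier is a PRIME token.
    """
    text = normalize_text(text)
    tokens: List[Token] = []
    line, col = 1, 1
    i, n = 0, len(text)

    def loc() -> SourceLocation:
        return SourceLocation(line, col)

    while i < n:
        ch = text[i]
        if ch == "\n":
            tokens.append(Token("NEWLINE", "\n", loc()))
            i += 1
            line += 1
            col = 1
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if text.startswith("//", i):
            while i < n and text[i] != "\n":
                i += 1
                col += 1
            continue
        if text.startswith(tuple(_TWO_CHAR), i):
            two = text[i:i + 2]
            tokens.append(Token(_TWO_CHAR[two], two, loc()))
            i += 2
            col += 2
            continue
        if ch == '"':
            start = loc()
            j = text.find('"', i + 1)
            if j == -1 or "\n" in text[i + 1:j]:
                raise LanguageError("unterminated string literal", start)
            tokens.append(Token("STRING", text[i + 1:j], start))
            col += j + 1 - i
            i = j + 1
            continue
        if ch == "$":
            if i + 1 < n and (_ID_RE.match(text, i + 1) or None) and \
                    _ID_RE.match(text, i + 1).start() == i + 1:
                tokens.append(Token("BOUNDARY", "$", loc()))
                i += 1
                col += 1
                continue
            raise LanguageError("'$' must directly precede an identifier", loc())
        if ch == "'":
            if tokens and tokens[-1].kind == "ID" and \
                    tokens[-1].loc.line == line and \
                    tokens[-1].loc.column + len(tokens[-1].text) == col:
                tokens.append(Token("PRIME", "'", loc()))
                i += 1
                col += 1
                continue
            raise LanguageError("stray \"'\" (prime must follow an identifier)", loc())
        m = _NUM_RE.match(text, i)
        if m:
            tokens.append(Token("NUMBER", m.group(), loc()))
            col += len(m.group())
            i = m.end()
            continue
        m = _ID_RE.match(text, i)
        if m:
            tokens.append(Token("ID", m.group(), loc()))
            col += len(m.group())
            i = m.end()
            continue
        if ch in _ONE_CHAR:
            tokens.append(Token(_ONE_CHAR[ch], ch, loc()))
            i += 1
            col += 1
            continue
        raise LanguageError(f"illegal character {ch!r}", loc())
    return tokens


# --------------------------------------------------------------------------
# Expression parsing (Pratt-style precedence climbing)
# --------------------------------------------------------------------------

_EXPR_START = {"NUMBER", "ID", "MINUS", "LPAREN"}
_CMP_OPS = {"GT": ">", "LT": "<", "GE": ">=", "LE": "<=",
            "EQEQ": "==", "NEQ": "!="}


class _Parser:
    def __init__(self, tokens: Sequence[Token]):
        self.tokens = list(tokens)
        self.pos = 0

    # -- token helpers ----------------------------------------------------
    def peek(self, offset: int = 0) -> Optional[Token]:
        j = self.pos + offset
        return self.tokens[j] if j < len(self.tokens) else None

    def at(self, *kinds: str) -> bool:
        t = self.peek()
        return t is not None and t.kind in kinds

    def at_word(self, word: str) -> bool:
        t = self.peek()
        return t is not None and t.kind == "ID" and t.text == word

    def advance(self) -> Token:
        t = self.peek()
        if t is None:
            raise LanguageError("unexpected end of input", self._last_loc())
        self.pos += 1
        return t

    def expect(self, kind: str, what: str = "") -> Token:
        t = self.peek()
        if t is None or t.kind != kind:
            got = f"'{t.text}'" if t else "end of input"
            want = what or kind.lower()
            raise LanguageError(f"expected {want}, got {got}",
                                t.loc if t else self._last_loc())
        return self.advance()

    def _last_loc(self) -> SourceLocation:
        if self.tokens:
            t = self.tokens[min(self.pos, len(self.tokens) - 1)]
            return t.loc
        return SourceLocation(1, 1)

    def skip_newlines(self) -> None:
        while self.at("NEWLINE", "SEMI"):
            self.advance()

    def end_statement(self) -> None:
        """Consume the statement terminator (newline, ';' or EOF)."""
        if self.peek() is None:
            return
        if self.at("NEWLINE", "SEMI"):
            self.advance()
            return
        t = self.peek()
        raise LanguageError(f"unexpected token '{t.text}' at end of statement",
                            t.loc)

    # -- expressions -------------------------------------------------------
    def parse_expr(self) -> Expr:
        left = self.parse_additive()
        if self.at(*_CMP_OPS):
            op = _CMP_OPS[self.advance().kind]
            right = self.parse_additive()
            return Binary(op, left, right)
        return left

    def parse_additive(self) -> Expr:
        left = self.parse_term()
        while self.at("PLUS", "MINUS"):
            op = "+" if self.advance().kind == "PLUS" else "-"
            left = Binary(op, left, self.parse_term())
        return left

    def parse_term(self) -> Expr:
        left = self.parse_unary()
        while self.at("STAR", "SLASH"):
            op = "*" if self.advance().kind == "STAR" else "/"
            left = Binary(op, left, self.parse_unary())
        return left

    def parse_unary(self) -> Expr:
        if self.at("MINUS"):
            self.advance()
            return Unary("-", self.parse_unary())
        return self.parse_power()

    def parse_power(self) -> Expr:
        base = self.parse_atom()
        if self.at("CARET"):
            self.advance()
            return Binary("^", base, self.parse_unary())  # right-assoc
        return base

    def parse_atom(self) -> Expr:
        t = self.peek()
        if t is None:
            raise LanguageError("expected expression", self._last_loc())
        if t.kind == "NUMBER":
            self.advance()
            return Num(float(t.text))
        if t.kind == "LPAREN":
            self.advance()
            inner = self.parse_expr()
            self.expect("RPAREN", "')'")
            return inner
        if t.kind == "ID":
            self.advance()
            if self.at("LPAREN"):
                self.advance()
                args: List[Expr] = []
                if not self.at("RPAREN"):
                    args.append(self.parse_expr())
                    while self.at("COMMA"):
                        self.advance()
                        args.append(self.parse_expr())
                self.expect("RPAREN", "')'")
                return Call(t.text, tuple(args))
            if t.text == "time":
                return TimeSym()
            if t.text == "inf":
                return Num(float("inf"))
            return Sym(t.text)
        raise LanguageError(f"unexpected token '{t.text}' in expression", t.loc)

    # -- statements --------------------------------------------------------
    def parse_statements(self) -> List[Stmt]:
        out: List[Stmt] = []
        self.skip_newlines()
        while self.peek() is not None:
            out.append(self.parse_statement())
            self.skip_newlines()
        return out

    def parse_statement(self) -> Stmt:
        t = self.peek()
        assert t is not None
        if t.kind == "ID":
            if t.text == "model":
                return self._parse_model_lead()
            if t.text == "end" and self._kind(1) in (None, "NEWLINE", "SEMI"):
                self.advance()
                self.end_statement()
                return ModelEndStmt(t.loc)
            if t.text == "constraint":
                return self._parse_constraint()
            if t.text == "if":
                return self._parse_event()
        if t.kind == "ID" and self._kind(1) == "COLON":
            return self._parse_labelled(t.loc)
        if self._arrow_ahead():
            return self._parse_reaction(t.loc)
        if t.kind == "ID":
            k1 = self._kind(1)
            if k1 == "DOT":
                return self._parse_uncertainty(t.loc)
            if k1 == "PRIME":
                return self._parse_rate_rule(t.loc, boundary=False)
            if k1 == "BECOMES":
                name = self.advance().text
                self.advance()
                formula = self.parse_expr()
                self.end_statement()
                return ContAssignStmt(t.loc, name, False, formula)
            if k1 == "ASSIGN":
                name = self.advance().text
                self.advance()
                formula = self.parse_expr()
                self.end_statement()
                return InitAssignStmt(t.loc, name, False, formula)
        if t.kind == "BOUNDARY":
            k2 = self._kind(2)
            if k2 == "PRIME":
                self.advance()
                return self._parse_rate_rule(t.loc, boundary=True)
            if k2 == "BECOMES":
                self.advance()
                name = self.advance().text
                self.advance()
                formula = self.parse_expr()
                self.end_statement()
                return ContAssignStmt(t.loc, name, True, formula)
            if k2 == "ASSIGN":
                self.advance()
                name = self.advance().text
                self.advance()
                formula = self.parse_expr()
                self.end_statement()
                return InitAssignStmt(t.loc, name, True, formula)
        if t.kind == "NUMBER" and t.text == "0" and self._kind(1) == "ASSIGN":
            self.advance()
            self.advance()
            formula = self.parse_expr()
            self.end_statement()
            return AlgRuleStmt(t.loc, None, formula)
        raise LanguageError(f"cannot parse statement starting at '{t.text}'",
                            t.loc)

    def _kind(self, offset: int) -> Optional[str]:
        t = self.peek(offset)
        return t.kind if t else None

    def _arrow_ahead(self) -> bool:
        """True if an ARROW occurs before the next ';'/newline boundary."""
        j = self.pos
        while j < len(self.tokens):
            k = self.tokens[j].kind
            if k == "ARROW":
                return True
            if k in ("SEMI", "NEWLINE"):
                return False
            j += 1
        return False

    # model name() | end  /  model <keyword> "value"
    def _parse_model_lead(self) -> Stmt:
        lead = self.advance()  # 'model'
        name_tok = self.expect("ID", "model name or metadata keyword")
        if self.at("LPAREN"):
            self.advance()
            self.expect("RPAREN", "')'")
            self.end_statement()
            return ModelBeginStmt(lead.loc, name_tok.text)
        keyword = name_tok.text
        if self.at("DOT"):
            self.advance()
            field = self.expect("ID", "metadata field").text
            keyword = f"{keyword}.{field}"
        value = self.expect("STRING", "quoted metadata value").text
        self.end_statement()
        return MetadataStmt(lead.loc, keyword, value)

    def _parse_constraint(self) -> ConstraintStmt:
        lead = self.advance()  # 'constraint'
        name = self.expect("ID", "constraint id").text
        self.expect("COLON", "':'")
        reaction = self.expect("ID", "reaction id").text
        t = self.peek()
        if t is None or t.kind not in ("LE", "GE", "ASSIGN", "EQEQ"):
            raise LanguageError("expected '<=', '>=' or '=' in constraint",
                                t.loc if t else self._last_loc())
        self.advance()
        comparator = {"LE": "<=", "GE": ">=", "ASSIGN": "=", "EQEQ": "="}[t.kind]
        bound_expr = self.parse_expr()
        bound = _const_fold(bound_expr)
        if bound is None:
            raise LanguageError("constraint bound must be a numeric constant",
                                lead.loc)
        self.end_statement()
        return ConstraintStmt(lead.loc, name, reaction, comparator, bound)

    def _parse_event(self) -> EventStmt:
        lead = self.advance()  # 'if'
        trigger = self.parse_expr()
        self.expect("COLON", "':' after event trigger")
        self.expect("NEWLINE", "newline after event trigger")
        assignments: List[Tuple[str, Expr]] = []
        while True:
            self.skip_newlines()
            t = self.peek()
            if t is None or t.loc.column <= lead.loc.column:
                break
            if t.kind != "ID" or self._kind(1) != "ASSIGN":
                raise LanguageError(
                    "event body statements must be assignments", t.loc)
            target = self.advance().text
            self.advance()
            formula = self.parse_expr()
            self.end_statement()
            assignments.append((target, formula))
        if not assignments:
            raise LanguageError("event has an empty body", lead.loc)
        return EventStmt(lead.loc, trigger, tuple(assignments))

    def _parse_labelled(self, loc: SourceLocation) -> Stmt:
        name = self.advance().text
        self.advance()  # ':'
        t = self.peek()
        if t is None:
            raise LanguageError("expected statement after label", loc)
        if t.kind == "ID" and t.text in ("maximize", "minimize"):
            sense = self.advance().text
            formula = self.parse_expr()
            self.end_statement()
            return ObjectiveStmt(loc, name, sense, formula)
        if t.kind == "NUMBER" and t.text == "0" and self._kind(1) == "ASSIGN":
            self.advance()
            self.advance()
            formula = self.parse_expr()
            self.end_statement()
            return AlgRuleStmt(loc, name, formula)
        return self._parse_reaction(loc, name=name)

    def _parse_rate_rule(self, loc: SourceLocation, boundary: bool) -> RateRuleStmt:
        name = self.advance().text
        self.expect("PRIME")
        self.expect("ASSIGN", "'=' after rate-rule target")
        formula = self.parse_expr()
        self.end_statement()
        return RateRuleStmt(loc, name, boundary, formula)

    def _parse_uncertainty(self, loc: SourceLocation) -> UncertaintyStmt:
        target = self.advance().text
        self.advance()  # '.'
        attribute = self.expect("ID", "uncertainty attribute").text
        if self.at_word("is"):
            self.advance()
            uri = self.expect("STRING", "quoted URI").text
            self.end_statement()
            return UncertaintyStmt(loc, target, attribute, uri=uri)
        self.expect("ASSIGN", "'=' or 'is' after uncertainty attribute")
        if self.at("LBRACE"):
            self.advance()
            lo = self.parse_expr()
            self.expect("COMMA", "','")
            hi = self.parse_expr()
            self.expect("RBRACE", "'}'")
            self.end_statement()
            return UncertaintyStmt(loc, target, attribute, pair=(lo, hi))
        scalar = self.parse_expr()
        self.end_statement()
        return UncertaintyStmt(loc, target, attribute, scalar=scalar)

    def _parse_reaction(self, loc: SourceLocation,
                        name: Optional[str] = None) -> ReactionStmt:
        reactants = self._parse_participants()
        self.expect("ARROW", "'->'")
        products = self._parse_participants()
        rate_law: Optional[Expr] = None
        if self.at("SEMI"):
            self.advance()
            if self.at(*_EXPR_START):
                rate_law = self.parse_expr()
        self.end_statement()
        return ReactionStmt(loc, name, tuple(reactants), tuple(products),
                            rate_law)

    def _parse_participants(self) -> List[AstParticipant]:
        parts: List[AstParticipant] = []
        if self.at("ARROW") or self.at("SEMI", "NEWLINE") or self.peek() is None:
            return parts  # empty side (source/sink)
        while True:
            parts.append(self._parse_participant())
            if self.at("PLUS"):
                self.advance()
                continue
            break
        return parts

    def _parse_participant(self) -> AstParticipant:
        boundary = False
        stoich: Union[float, str] = 1.0
        if self.at("BOUNDARY"):
            boundary = True
            self.advance()
        t = self.peek()
        if t is None:
            raise LanguageError("expected species in reaction",
                                self._last_loc())
        if t.kind == "NUMBER" and self._kind(1) in ("ID", "BOUNDARY"):
            stoich = float(t.text)
            self.advance()
        elif t.kind == "ID" and self._kind(1) in ("ID", "BOUNDARY"):
            stoich = t.text
            self.advance()
        if self.at("BOUNDARY"):
            boundary = True
            self.advance()
        species = self.expect("ID", "species identifier").text
        if isinstance(stoich, float) and stoich <= 0:
            raise LanguageError("stoichiometry must be positive", t.loc)
        return AstParticipant(species, stoich, boundary)


def _const_fold(expr: Expr) -> Optional[float]:
    """Evaluate a constant expression; None if it references symbols."""
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Unary):
        v = _const_fold(expr.child)
        return None if v is None else -v
    if isinstance(expr, Binary):
        a, b = _const_fold(expr.left), _const_fold(expr.right)
        if a is None or b is None:
            return None
        try:
            return {"+": a + b, "-": a - b, "*": a * b,
                    "/": a / b if b else float("nan"),
                    "^": a ** b}[expr.op]
        except KeyError:
            return None
    return None


# --------------------------------------------------------------------------
# Public API
# --------------------------------------------------------------------------


def parse(text: str) -> List[Stmt]:
    """Parse Antimony-dialect text into a statement sequence."""
    return _Parser(tokenize(text)).parse_statements()


def parse_expression(text: str) -> Expr:
    """Parse a single expression; trailing tokens are an error."""
    p = _Parser([t for t in tokenize(text) if t.kind != "NEWLINE"])
    expr = p.parse_expr()
    t = p.peek()
    if t is not None:
        raise LanguageError(f"trailing token '{t.text}' after expression",
                            t.loc)
    return expr
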