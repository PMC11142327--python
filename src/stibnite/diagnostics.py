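"""Diagnostics: severities, source locations, and collected messages.

Every error or warning produced while lexing, parsing, building or
exporting a model is a :class:`Diagnostic`.  Tools render them one per
line as ``SEVERITY file:line:col message`` and map severities to exit
status (any ``error`` -> 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional


class Severity(Enum):
    WARNING = "warning"
    ERROR = "error"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class SourceLocation:
    """1-based line/column position in the input text."""

    line: int
    column: int

    def __post_init__(self) -> None:
        if self.line < 1 or self.column < 1:
            raise ValueError("line and column are 1-based")

    def __str__(self) -> str:
        return f"{self.line}:{self.column}"


@dataclass(frozen=True)
class Diagnostic:
    severity: Severity
    message: str
    loc: Optional[SourceLocation] = None

    def render(self, filename: str = "<input>") -> str:
        where = f"{filename}:{self.loc}" if self.loc else filename
        return f"{self.severity.value.upper()} {where} {self.message}"


class LanguageError(Exception):
    """Raised for unrecoverable lexical, syntactic or semantic errors."""

    def __init__(self, message: str, loc: Optional[SourceLocation] = None):
        super().__init__(message)
        self.message = message
        self.loc = loc

    def as_diagnostic(self) -> Diagnostic:
        return Diagnostic(Severity.ERROR, self.message, self.loc)


@dataclass
class DiagnosticSink:
    """Accumulates diagnostics during a build."""

    items: List[Diagnostic] = field(default_factory=list)

    def warn(self, message: str, loc: Optional[SourceLocation] = None) -> None:
        self.items.append(Diagnostic(Severity.WARNING, message, loc))

    def error(self, message: str, loc: Optional[SourceLocation] = None) -> None:
        self.items.append(Diagnostic(Severity.ERROR, message, loc))

    def extend(self, diags: Iterable[Diagnostic]) -> None:
        self.items.extend(diags)

    @property
    def errors(self) -> List[Diagnostic]:
        return [d for d in self.items if d.severity is Severity.ERROR]

    @property
    def warnings(self) -> List[Diagnostic]:
        return [d for d in self.items if d.severity is Severity.WARNING]

    def has_errors(self) -> bool:
        return any(d.severity is Severity.ERROR for d in self.items)
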