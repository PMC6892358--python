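"""Exception hierarchy shared across syntenykit modules."""

from __future__ import annotations


class SyntenyKitError(Exception):
    """Base class for all syntenykit errors."""


class ParseError(SyntenyKitError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line_number is not None:
            prefix += f":{line_number}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ValidationError(SyntenyKitError):
    """Input data violated a domain invariant (e.g. start > end, duplicate ID)."""


class ConfigError(SyntenyKitError):
    """A genome configuration file is missing required settings or inconsistent."""


class OntologyError(SyntenyKitError):
    """Ontology structure problem: unknown term, cycle among is_a/part_of edges."""


class TermNotFoundError(OntologyError):
    """A queried term (by ID or name) does not exist in the named ontology."""
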