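"""Exception hierarchy for abmotif.

Every error raised on a user-facing path carries a short stable ``code`` so
that pipeline callers (and the CLI exit handler) can distinguish failure
classes without parsing messages.
"""

from __future__ import annotations


class AbmotifError(Exception):
    """Base class for all abmotif errors."""

    code: str = "E_GENERIC"

    def __init__(self, message: str, *, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ConfigurationError(AbmotifError):
    """Inconsistent inputs: unknown/duplicate organisms, bad config combos."""

    code = "E_CONFIG"


class InputError(AbmotifError):
    """A value refers to something not present (vertex, organism, file)."""

    code = "E_INPUT"


class ParameterError(AbmotifError):
    """A numeric parameter is outside its documented range."""

    code = "E_PARAM"


class ParseError(AbmotifError):
    """Malformed input file; ``line`` is the 1-based offending line number."""

    code = "E_PARSE"

    def __init__(self, message: str, *, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SizeGuardError(AbmotifError):
    """Exhaustive oracle refused to run on an input beyond its size guard."""

    code = "E_SIZE_GUARD"
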