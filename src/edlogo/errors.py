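"""Exception hierarchy for edlogo.

All user-facing failures derive from :class:`EdlogoError` so the CLI can
map them onto exit code 2 (validation/usage) versus 1 (internal).
"""


class EdlogoError(Exception):
    """Base class for all edlogo errors."""


class FormatError(EdlogoError):
    """A stream does not conform to the expected file format."""


class ValidationError(EdlogoError):
    """Inputs are well-formed but violate a domain invariant."""


class DomainError(EdlogoError):
    """A mathematical precondition is violated (e.g. log of zero)."""


class SymbolLookupError(EdlogoError, KeyError):
    """A requested position or symbol does not exist."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message readable
        return Exception.__str__(self)
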