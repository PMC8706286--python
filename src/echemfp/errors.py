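"""Exception hierarchy.

All domain errors derive from :class:`EchemError` so callers can catch the
package's failures with one clause; each also derives from ``ValueError``
to behave sensibly in generic code.
"""


class EchemError(Exception):
    """Base class for all errors raised by echemfp."""


class InvalidArgumentError(EchemError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(EchemError, ValueError):
    """Input is structurally valid but degenerate (e.g. a constant trace)."""


class CoverageError(EchemError, ValueError):
    """A trace does not cover the requested potential range."""


class FormatError(EchemError, ValueError):
    """A file does not conform to the expected on-disk schema."""
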