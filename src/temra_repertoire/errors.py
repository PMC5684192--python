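"""Exception hierarchy shared across the package.

Every validation failure raised by the library derives from
:class:`TemraError`, so the CLI can map them onto nonzero exit codes
without enumerating call sites.
"""


class TemraError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TemraError, ValueError):
    """A clonotype table does not conform to its declared dialect
    (e.g. a mandatory column is missing)."""


class ValidationError(TemraError, ValueError):
    """An input value violates a documented precondition
    (non-positive count, frequencies not summing to one, ...)."""


class FitDegenerateError(TemraError, RuntimeError):
    """The composition fit is unidentifiable for the given observations
    (every donor sits on the clipped branch of the model)."""
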