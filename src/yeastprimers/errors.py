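"""Exception hierarchy for the primer-design pipeline.

All fatal conditions raise a subclass of :class:`PrimerToolError`; the CLI maps
usage problems to exit status 2 and everything else to exit status 1.
"""


class PrimerToolError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PrimerToolError):
    """A genome or annotation file could not be parsed."""


class ValidationError(PrimerToolError):
    """Inputs are individually well formed but mutually inconsistent."""


class DesignError(PrimerToolError):
    """Primer geometry could not be computed (bad parameters or sequence)."""


class ReportError(PrimerToolError):
    """Output files could not be written consistently."""


class FixtureError(PrimerToolError):
    """A synthetic-genome plan is infeasible."""


class UsageError(PrimerToolError):
    """Command-line arguments or configuration are invalid."""
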