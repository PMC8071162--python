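"""Exception hierarchy for the quantification pipeline.

Every error raised on purpose by this package derives from
:class:`HepaquantError`, so callers (and the CLI) can catch one type.
"""


class HepaquantError(Exception):
    """Base class for all errors raised by hepaquant."""


class FormatError(HepaquantError, ValueError):
    """Malformed or unsupported input file."""


class SpecError(HepaquantError, ValueError):
    """Invalid phantom specification."""


class PlacementError(HepaquantError, ValueError):
    """ROI placement infeasible or outside the allowed region."""


class DomainError(HepaquantError, ValueError):
    """Input outside the mathematical domain of an operation."""


class RangeError(HepaquantError, ValueError):
    """Index range selects an empty or too-short segment."""


class ConfigurationError(HepaquantError, ValueError):
    """Invalid parameter combination."""


class AlignmentError(HepaquantError, ValueError):
    """Paired sequences of unequal length."""


class IdentityError(HepaquantError, ValueError):
    """Records that must belong to one subject do not."""


class DegenerateInputError(HepaquantError, ValueError):
    """Input degenerate for the requested operation (e.g. constant image)."""


class ConvergenceError(HepaquantError, RuntimeError):
    """Iterative method diverged (e.g. the evolving mask emptied)."""
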