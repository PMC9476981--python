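"""Exception hierarchy for the endoflow pipeline.

All errors derive from :class:`EndoflowError` so callers can catch the
package's failures with one clause; the finer classes distinguish bad file
formats from empty inputs, domain violations and degenerate statistics.
"""


class EndoflowError(Exception):
    """Base class for all endoflow errors."""


class FormatError(EndoflowError):
    """A table does not conform to the documented dialect."""


class EmptyInputError(EndoflowError):
    """No usable rows/events after parsing or filtering."""


class DomainError(EndoflowError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class NoPeakError(EndoflowError):
    """Peak detection found nothing above the prominence threshold."""


class InsufficientNucleiError(EndoflowError):
    """Gating retained no events, or too few for the requested analysis."""


class InsufficientDataError(EndoflowError):
    """A statistical routine needs more observations per group."""


class DegenerateDataError(EndoflowError):
    """Input with zero variance where a test requires spread."""


class ContractViolation(EndoflowError):
    """Caller mixed incompatible units of analysis (organs, individuals)."""


class PeakOverlapWarning(UserWarning):
    """A simulated sample/standard ratio sits near a doubling of the standard,
    so the two peak series can merge."""
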