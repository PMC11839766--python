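"""Exception hierarchy for stagescore.

All package errors derive from :class:`StagescoreError` so callers can catch
one base class; most also derive from the matching builtin (``ValueError``,
``KeyError``, ...) so generic handling keeps working.
"""


class StagescoreError(Exception):
    """Base class for all stagescore errors."""


class InvalidAnswerError(StagescoreError, ValueError):
    """A question code lies outside its valid range."""


class InvalidLevelError(StagescoreError, ValueError):
    """A score is not a member of the 12-level half-step grid."""


class InvalidValueError(StagescoreError, ValueError):
    """A numeric argument is non-finite or otherwise unusable."""


class InvalidInputError(StagescoreError, ValueError):
    """Malformed caller input (e.g. an empty sentence)."""


class InvalidParameterError(StagescoreError, ValueError):
    """A configuration parameter is out of its allowed range."""


class EmptyInputError(StagescoreError, ValueError):
    """An operation requiring data received an empty collection."""


class UnparsableResponseError(StagescoreError, ValueError):
    """A backend reply carries no recognizable category."""


class BackendUnavailableError(StagescoreError, RuntimeError):
    """The remote classifier cannot be reached and no cache entry exists."""


class ClassificationFailedError(StagescoreError, RuntimeError):
    """Every run for a sentence failed; no score can be produced."""


class InsufficientItemsError(StagescoreError, ValueError):
    """Fewer sentences than the configured minimum for a respondent score."""


class InvalidWindowError(StagescoreError, ValueError):
    """A regression window contains fewer than two points."""


class InvalidSizeError(StagescoreError, ValueError):
    """A subsample size lies outside [2, N]."""


class InvalidSpecError(StagescoreError, ValueError):
    """A synthetic-data specification is inconsistent."""


class DegenerateTableError(StagescoreError, ValueError):
    """A contingency table admits no chance-corrected agreement (zero
    expected disagreement or a single observed category)."""


class FormatError(StagescoreError, ValueError):
    """A data file violates the expected schema."""


class FixtureNotFoundError(StagescoreError, KeyError):
    """No bundled fixture with the requested name."""
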