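"""Exception types raised across the pipeline.

Each class marks a distinct failure contract so callers can react to
(e.g.) a panel mismatch differently from an unreadable file.
"""


class DnbError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DnbError):
    """File could not be parsed in the declared format."""


class NoPanelOverlapError(DnbError):
    """Input file shares no marker names with the configured panel."""


class NonNumericError(DnbError):
    """Expression table contains non-numeric cells."""


class TransformStateError(DnbError):
    """Operation applied to a matrix in the wrong transform state
    (e.g. arcsinh applied twice)."""


class MissingTimepointError(DnbError):
    """A required stimulation timepoint is absent from a sample."""


class NotPositiveSemidefiniteError(DnbError):
    """A simulation correlation specification is not PSD; the message
    names the offending timepoint."""


class AbsentTruthError(DnbError):
    """Planted truth requested from a cohort that carries none
    (real-data ingest path)."""


class EmptyGroupError(DnbError):
    """A group referenced in a ratio has no members."""


class ZeroDenominatorError(DnbError):
    """Denominator group mean is zero in a group ratio."""
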