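"""Exception hierarchy for the calfsense pipeline.

Each stage raises a specific subclass so CLI exit codes and tests can
discriminate I/O-format problems from data-integrity problems.
"""


class CalfSenseError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CalfSenseError):
    """A file does not conform to the expected CSV schema."""


class IntegrityError(CalfSenseError):
    """Data violates a domain invariant (scales, monotone time, overlaps)."""


class VocabularyError(CalfSenseError):
    """A behavior name is outside the configured ethogram vocabulary."""


class ShapeError(CalfSenseError):
    """Array/series shapes or column sets are inconsistent."""


class ScenarioError(CalfSenseError):
    """A simulation scenario violates its schedule invariants."""


class LabelingError(CalfSenseError):
    """A window cannot be labeled (e.g. no state-tier coverage)."""


class AlignmentError(CalfSenseError):
    """Two annotation tracks cannot be aligned on a common time lattice."""
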