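"""Exception hierarchy.

All raftfilm errors derive from :class:`RaftFilmError` so callers can catch the
package's failures without masking programming errors.  The subclasses mirror
the failure modes of the analysis stages: malformed inputs, queries outside the
recorded range, feature-extraction dead ends, degenerate electrochemical
responses and fit failures.
"""


class RaftFilmError(Exception):
    """Base class for all raftfilm errors."""


class InvalidInputError(RaftFilmError, ValueError):
    """Input data violate a precondition (too short, non-finite, wrong sign...)."""


class OutOfRangeError(RaftFilmError, ValueError):
    """A query (pressure, potential, frequency) falls outside the recorded range."""


class ExtractionError(RaftFilmError, RuntimeError):
    """A feature (limiting area, plateau...) could not be extracted."""


class DegenerateResponseError(RaftFilmError, ValueError):
    """An electrochemical response has no usable capacitive component."""


class NotFoundError(RaftFilmError, RuntimeError):
    """A sought feature (e.g. a zero crossing) does not exist in the data."""


class SpecError(RaftFilmError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class FitFailureError(RaftFilmError, RuntimeError):
    """Nonlinear fit failed to converge; carries the best parameters so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
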