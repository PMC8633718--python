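"""Exception hierarchy for pullpmf.

All package-specific failures derive from :class:`PullPMFError` so callers
can catch one base class at pipeline boundaries.
"""


class PullPMFError(Exception):
    """Base class for all pullpmf errors."""


class EmptyTraceError(PullPMFError):
    """A trace file or trace object contained no usable records."""


class TraceOrderingError(PullPMFError):
    """Trace times are not strictly increasing."""


class StructureError(PullPMFError):
    """Topology/coordinate inconsistency (e.g. atom-count mismatch)."""


class InsufficientDataError(PullPMFError):
    """Too few points/replicas for the requested computation."""


class ParameterError(PullPMFError, ValueError):
    """An invalid parameter value (non-positive spacing, even window, ...)."""


class DataError(PullPMFError):
    """Non-finite or otherwise invalid numeric data."""


class SelectionError(PullPMFError):
    """An atom/residue selector resolved to zero or multiple candidates."""


class ParameterizationError(PullPMFError):
    """A required per-atom parameter (e.g. Lennard-Jones) is missing."""


class ConstructionError(PullPMFError):
    """A synthetic fixture script is geometrically infeasible."""


class NumericalError(PullPMFError):
    """A numerical procedure (e.g. adaptive quadrature) failed to converge."""


class ConfigurationError(PullPMFError):
    """A simulation or pipeline configuration violates its invariants."""


class ValidationError(PullPMFError):
    """Pipeline config validation failed; carries all messages at once."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
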