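"""Exception hierarchy for spinecouple."""


class SpineCoupleError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpineCoupleError):
    """Invalid configuration value; the message names the offending field."""


class CoverageError(SpineCoupleError):
    """A joint lacks an agonist/antagonist fascicle pair for a motion axis."""


class AssemblyError(SpineCoupleError):
    """The constrained stiffness matrix is singular (free mechanism)."""


class SolverError(SpineCoupleError):
    """Static solve failed to converge (or diverged)."""


class MappingError(SpineCoupleError):
    """A load or attachment references a body absent from the FE model."""


class RecruitmentError(SpineCoupleError):
    """Muscle recruitment infeasible; message lists the violated joints."""


class ConstructError(SpineCoupleError):
    """Invalid fixation construct request."""


class PipelineStateError(SpineCoupleError):
    """Pipeline stage invoked without its upstream outputs."""
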