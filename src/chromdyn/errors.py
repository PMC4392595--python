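"""Exception hierarchy shared across the pipeline stages."""


class ChromdynError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(ChromdynError, ValueError):
    """A parameter violates its stated precondition."""


class ValidationError(ChromdynError, ValueError):
    """Input data failed validation (bad coordinates, malformed records)."""


class CapacityError(ChromdynError):
    """Requested placement/packing cannot fit in the genome."""


class PlacementError(ChromdynError):
    """Randomized interval placement found no feasible position."""


class ConsistencyError(ChromdynError):
    """Two inputs that must share a genome or gene universe do not."""


class DegenerateInputError(ChromdynError):
    """Input is structurally valid but too small/degenerate for the statistic."""


class ConfigError(ChromdynError):
    """Pipeline configuration is malformed or names unknown keys."""


class StageDependencyError(ChromdynError):
    """A pipeline stage is missing an upstream artifact."""
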