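"""Exception hierarchy for the capmap pipeline."""


class CapmapError(Exception):
    """Base class for all capmap errors."""


class ConfigError(CapmapError):
    """Invalid configuration or parameter values."""


class SimulationError(CapmapError):
    """Simulation failure (e.g. rejection sampling did not terminate)."""


class GenotypingError(CapmapError):
    """Malformed allele-count input to the genotype caller."""


class PhaseInconsistencyError(CapmapError):
    """A linkage group contains a marker together with its own mirror."""


class MapEstimationError(CapmapError):
    """Multipoint map EM encountered a non-finite likelihood."""


class FormatError(CapmapError):
    """Malformed on-disk file."""
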