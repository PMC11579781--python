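"""Exception hierarchy shared across the package."""


class SugarglassError(Exception):
    """Base class for all package-specific errors."""


class FileFormatError(SugarglassError):
    """A text file does not follow the expected layout (reports the line)."""


class TopologyError(SugarglassError):
    """Topology invariants violated (masses, donors, group definitions...)."""


class ConsistencyError(SugarglassError):
    """Frame/topology or series/series mismatch."""


class GeometryError(SugarglassError):
    """Degenerate or out-of-domain geometry (colinear dihedral, r_max > L/2...)."""


class PackingError(SugarglassError):
    """A synthetic configuration cannot be placed at the requested density."""


class StabilityError(SugarglassError):
    """Integrator / generator parameters outside the stable regime."""


class CoverageError(SugarglassError):
    """Umbrella windows leave a gap along the reaction coordinate."""


class ConvergenceError(SugarglassError):
    """An iterative solver exhausted its iteration budget."""


class ConfigError(SugarglassError):
    """Invalid study or analysis configuration."""
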