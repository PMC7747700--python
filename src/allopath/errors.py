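"""Exception hierarchy shared across the package."""


class AllopathError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AllopathError):
    """A structural or tabular input file could not be parsed."""


class TopologyError(AllopathError):
    """Models of one ensemble disagree on atom count or atom identity."""


class SelectionError(AllopathError):
    """An atom selection resolved to the wrong number of atoms."""


class SpecificationError(AllopathError):
    """A generator spec, criterion or config is internally inconsistent."""


class GeometryError(AllopathError):
    """Degenerate geometry (collinear ring, rank-deficient point set, ...)."""


class FitError(AllopathError):
    """A nonlinear fit failed to converge or the data are degenerate."""


class ConfigError(AllopathError):
    """A pipeline run configuration failed validation."""
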