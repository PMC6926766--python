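"""Package exception hierarchy.

Configuration problems (bad weights, missing coefficient entries, invalid
scenario parameters) raise :class:`ConfigError`; mismatched raster geometry
raises :class:`GeometryMismatchError`; spatial statistics on degenerate
(constant) fields raise :class:`UndefinedStatisticError`.
"""


class EcosecError(Exception):
    """Base class for package errors."""


class ConfigError(EcosecError, ValueError):
    """Invalid configuration: weights, coefficient tables, scenario params."""


class GeometryMismatchError(EcosecError, ValueError):
    """Two rasters do not share shape, cell size and origin."""


class UndefinedStatisticError(EcosecError, ValueError):
    """A spatial statistic is undefined, e.g. zero variance (S^2 = 0)."""
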