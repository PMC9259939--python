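"""Exception hierarchy for the quantification pipeline."""


class IshquantError(Exception):
    """Base class for all package errors."""


class ConfigError(IshquantError):
    """Invalid or inconsistent run/simulation configuration."""


class PlacementError(IshquantError):
    """Nucleus placement failed (requested density is too high)."""


class FormatError(IshquantError):
    """An input file does not match the configured layout."""


class GeometryError(IshquantError):
    """Coordinates and label maps disagree on field geometry."""


class EmptyPopulationError(IshquantError):
    """A population required for a statistic contains no cells."""
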