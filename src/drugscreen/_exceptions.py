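"""Exception hierarchy shared across the package."""


class DrugScreenError(Exception):
    """Base class for all package-specific errors."""


class DesignError(DrugScreenError, ValueError):
    """Invalid assay design (dilution series, plate capacity, grid layout)."""


class ConfigError(DrugScreenError, ValueError):
    """Inconsistent or invalid simulation configuration."""


class SchemaError(DrugScreenError, ValueError):
    """Input table is missing required columns or contains bad tokens."""


class IntegrityError(DrugScreenError, ValueError):
    """Structural violation in an input table (e.g. duplicate wells)."""


class NormalizationError(DrugScreenError, ValueError):
    """A plate cannot be normalized (no usable vehicle wells)."""


class FitError(DrugScreenError, ValueError):
    """Dose-response fitting failed or the fitted curve is unusable."""


class GridError(DrugScreenError, ValueError):
    """Checkerboard grid is incomplete or its margins cannot anchor a CI map."""


class InsufficientDataError(DrugScreenError, ValueError):
    """Too few observations for the requested estimate."""
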