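"""Exception types shared across the package."""


class LstmSimError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedConfigurationError(LstmSimError):
    """An optical configuration that the model does not cover."""


class InfeasibleGeometryError(LstmSimError):
    """A geometric constraint has no solution in the physical range."""


class MeasurementError(LstmSimError):
    """A profile measurement could not be completed (e.g. no half-max crossing)."""


class ConfigError(LstmSimError):
    """Configuration file failed validation; message lists every violation."""
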