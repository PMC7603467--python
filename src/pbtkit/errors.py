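"""Exception hierarchy for the PBTK toolkit."""


class PBTKError(Exception):
    """Base class for all toolkit errors."""


class InvalidPhysiologyError(PBTKError):
    """A physiological value or combination of values is unusable."""


class SchemaError(PBTKError):
    """A species/compound/protocol document violates the expected schema."""


class ModelConstructionError(PBTKError):
    """A PBTK model could not be assembled from its parts."""


class IntegrationError(PBTKError):
    """The ODE solver failed to produce a solution."""


class ObservationError(PBTKError):
    """An observation site is invalid for the model at hand."""


class DegenerateNormalizationError(PBTKError):
    """The dose perturbation left the output unchanged, so the
    dose-normalized sensitivity ratio is undefined."""


class ConfigError(PBTKError):
    """A pipeline configuration is inconsistent or incomplete."""
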