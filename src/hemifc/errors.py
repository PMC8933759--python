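"""Exception hierarchy shared across the pipeline."""


class HemifcError(Exception):
    """Base class for all package-specific errors."""


class AtlasValidationError(HemifcError):
    """An atlas table violates the schema or the pairing invariants."""


class DuplicateRoiIdError(AtlasValidationError):
    pass


class UnknownHemisphereError(AtlasValidationError):
    pass


class PartnerMappingError(AtlasValidationError):
    """Dangling, asymmetric, same-hemisphere or midline partner reference."""


class DegenerateInputError(HemifcError):
    """Input on which the requested statistic is undefined (zero variance,
    too few observations, identical values)."""


class ZeroVarianceRoiError(DegenerateInputError):
    """A time-series column is constant; correlation is undefined."""


class RoiOrderMismatchError(HemifcError):
    pass


class InfeasibleTargetError(HemifcError):
    """An asymmetry target cannot be reached under the design; carries the
    achievable range."""

    def __init__(self, message: str, achievable: tuple[float, float] | None = None):
        super().__init__(message)
        self.achievable = achievable


class CovarianceRepairError(HemifcError):
    """Nearest-correlation repair moved an entry beyond the configured
    tolerance."""
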