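"""Exception hierarchy shared across the extrusion-analysis modules."""


class ExtruMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(ExtruMechError, ValueError):
    """Extruder geometry is unphysical (non-positive radius, pore larger than filter...)."""


class DomainError(ExtruMechError, ValueError):
    """An input lies outside the physical domain of an operation."""


class EmptyTraceError(ExtruMechError, ValueError):
    """No extrusion cycle could be located in a force trace."""


class InsufficientPlateauError(ExtruMechError, ValueError):
    """A cycle segment has too few samples to estimate a plateau force."""


class InsufficientSampleError(ExtruMechError, ValueError):
    """Too few vesicle diameters for a population-level statistic."""


class FitFailureError(ExtruMechError, RuntimeError):
    """Nonlinear or linear fit did not converge / is rank deficient."""


class RankDeficiencyError(FitFailureError):
    """Design matrix for a linear fit has fewer than two distinct x values."""


class UndefinedRatioError(ExtruMechError, ZeroDivisionError):
    """Donor band integral is zero; FRET ratio undefined."""


class InvalidControlsError(ExtruMechError, ValueError):
    """FRET positive control does not exceed the negative control."""


class ConfigurationError(ExtruMechError, ValueError):
    """Pipeline or calibration configuration is inconsistent."""


class ExtrapolationError(ExtruMechError, ValueError):
    """A calibration was queried outside its anchor range without an override."""
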