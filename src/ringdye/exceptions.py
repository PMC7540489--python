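"""Package exception hierarchy."""


class RingDyeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RingDyeError, ValueError):
    """A physical parameter is outside its allowed range."""


class SingularGeometryError(RingDyeError, ValueError):
    """Two point dipoles share the same origin; the point-dipole coupling diverges."""


class DuplicateSiteError(RingDyeError, ValueError):
    """An assembly already contains the site being added."""


class MissingDyeError(RingDyeError, ValueError):
    """An operation requiring a dye site was given a dye-free assembly."""


class CalibrationError(RingDyeError, RuntimeError):
    """Band calibration failed to converge; carries the residual report."""

    def __init__(self, message: str, residual=None):
        super().__init__(message)
        self.residual = residual


class GridMismatchError(RingDyeError, ValueError):
    """Spectra were combined on different wavelength grids."""


class ConfigError(RingDyeError, ValueError):
    """A run configuration failed schema validation."""
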