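"""Exception types shared across the package."""


class CardioDtiError(Exception):
    """Base class for all package errors."""


class ParameterError(CardioDtiError):
    """Invalid parameter value (non-positive S0/SNR, bad radii, ...)."""


class GeometryError(CardioDtiError):
    """Phantom or mask geometry is degenerate (empty annulus, no cavity)."""


class ProtocolError(CardioDtiError):
    """Diffusion protocol unusable (rank-deficient design, bad directions)."""


class FormatError(CardioDtiError):
    """On-disk dataset malformed (bval/bvec/volume count mismatch)."""


class AnalysisError(CardioDtiError):
    """A derived analysis cannot be computed (e.g. <2 usable rings)."""
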