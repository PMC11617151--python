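"""Exception hierarchy shared across the package."""


class LeafchlError(Exception):
    """Base class for all package errors."""


class GridMismatchError(LeafchlError):
    """Two spectra were combined but their wavelength grids differ."""


class InvalidReferenceError(LeafchlError):
    """A white-reference scan contains nonpositive radiance in some band."""


class InvalidSpectrumError(LeafchlError):
    """A spectrum violates the invariants required by an operation."""


class ParameterError(LeafchlError):
    """An operation received an out-of-contract parameter value."""


class NoRedEdgeError(LeafchlError):
    """The spectrum has no rising red edge; inflection-point search is undefined."""


class RegistryError(LeafchlError):
    """The vegetation-index registry is malformed (e.g. duplicate names)."""


class StageError(LeafchlError):
    """A pipeline stage failed; carries the stage name for machine-readable logs."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.message = message
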