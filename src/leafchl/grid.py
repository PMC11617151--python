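"""Canonical spectral wavelength grid.

Field spectroradiometers of the ASD FieldSpec class export radiometric
data on an integer-nanometre grid from 350 to 2500 nm, i.e. 2151 narrow
wavebands with 1 nm spacing.  All spectra in this package live on that
grid (or are resampled onto it at load time), so band indexing is a pure
offset: band ``i`` holds wavelength ``350 + i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["SpectralGrid", "CANONICAL_GRID"]


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform integer-nm wavelength grid.

    Parameters
    ----------
    start_nm, end_nm : int
        Inclusive wavelength bounds in nanometres.
    step_nm : int
        Grid spacing; the canonical instrument grid uses 1 nm.
    """

    start_nm: int = 350
    end_nm: int = 2500
    step_nm: int = 1

    def __post_init__(self):
        if self.step_nm <= 0:
            raise ParameterError("step_nm must be positive")
        if self.end_nm <= self.start_nm:
            raise ParameterError("end_nm must exceed start_nm")
        if (self.end_nm - self.start_nm) % self.step_nm != 0:
            raise ParameterError("grid bounds must be commensurate with step_nm")

    @property
    def n_bands(self) -> int:
        return (self.end_nm - self.start_nm) // self.step_nm + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + 1, self.step_nm)

    def index_of(self, wavelength_nm: float) -> int:
        """Band index holding ``wavelength_nm``; exact-match lookup."""
        offset = wavelength_nm - self.start_nm
        idx, rem = divmod(offset, self.step_nm)
        if rem != 0 or not (0 <= idx < self.n_bands):
            raise ParameterError(
                f"wavelength {wavelength_nm} nm not on grid "
                f"[{self.start_nm}, {self.end_nm}] step {self.step_nm}"
            )
        return int(idx)

    def wavelength_of(self, index: int) -> int:
        if not 0 <= index < self.n_bands:
            raise ParameterError(f"band index {index} outside 0..{self.n_bands - 1}")
        return self.start_nm + index * self.step_nm


#: The 2151-band instrument grid used throughout.
CANONICAL_GRID = SpectralGrid(350, 2500, 1)
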