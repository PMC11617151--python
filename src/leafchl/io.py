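"""Readers and writers for spectra and chlorophyll tables.

Two text dialects are supported for spectra: a wide CSV (first column
``wavelength_nm``, one column per spectrum) and a minimal ASD-export
text dialect (free-form header lines followed by ``wavelength<TAB>value``
rows).  Inputs on a non-canonical grid are resampled by linear
interpolation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .grid import CANONICAL_GRID, SpectralGrid
from .spectra import Spectrum

__all__ = [
    "read_wide_csv",
    "write_wide_csv",
    "read_asd_txt",
    "resample_to_grid",
    "spectra_to_matrix",
]


def resample_to_grid(
    wavelengths: np.ndarray, values: np.ndarray, grid: SpectralGrid = CANONICAL_GRID
) -> np.ndarray:
    """Linear interpolation of (wavelength, value) samples onto ``grid``.

    Raises if the input does not cover the target grid (no extrapolation).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(wavelengths)
    wavelengths, values = wavelengths[order], values[order]
    if wavelengths[0] > grid.start_nm or wavelengths[-1] < grid.end_nm:
        raise ParameterError(
            f"input wavelengths [{wavelengths[0]}, {wavelengths[-1]}] do not "
            f"cover the grid [{grid.start_nm}, {grid.end_nm}]"
        )
    return np.interp(grid.wavelengths, wavelengths, values)


def read_wide_csv(
    path: str | Path, kind: str = "reflectance", grid: SpectralGrid = CANONICAL_GRID
) -> list[Spectrum]:
    """Read spectra from a wide CSV (wavelength_nm + one column per spectrum)."""
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ParameterError("wide CSV must start with a 'wavelength_nm' column")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if len(wl) == grid.n_bands and np.array_equal(wl, grid.wavelengths):
            resampled = vals
        else:
            resampled = resample_to_grid(wl, vals, grid)
        out.append(Spectrum(values=resampled, kind=kind, grid=grid, meta={"id": col}))
    return out


def write_wide_csv(path: str | Path, spectra: list[Spectrum]) -> None:
    if not spectra:
        raise ParameterError("no spectra to write")
    grid = spectra[0].grid
    data = {"wavelength_nm": grid.wavelengths}
    for i, s in enumerate(spectra):
        name = str(s.meta.get("id", f"spectrum_{i}"))
        data[name] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_asd_txt(
    path: str | Path, kind: str = "radiance", grid: SpectralGrid = CANONICAL_GRID
) -> Spectrum:
    """Read one spectrum from a minimal ASD-export text file.

    Header lines (anything that does not parse as two numbers) are skipped;
    data rows are ``wavelength<TAB>value`` (any whitespace accepted).
    """
    wl, vals = [], []
    header: list[str] = []
    for line in Path(path).read_text().splitlines():
        parts = line.replace("\t", " ").split()
        if len(parts) == 2:
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                header.append(line)
                continue
            wl.append(w)
            vals.append(v)
        elif line.strip():
            header.append(line)
    if not wl:
        raise ParameterError(f"no data rows found in {path}")
    wl_arr, val_arr = np.asarray(wl), np.asarray(vals)
    if len(wl_arr) == grid.n_bands and np.array_equal(wl_arr, grid.wavelengths):
        values = val_arr
    else:
        values = resample_to_grid(wl_arr, val_arr, grid)
    return Spectrum(
        values=values, kind=kind, grid=grid,
        meta={"id": Path(path).stem, "header": "\n".join(header)},
    )


def spectra_to_matrix(spectra: list[Spectrum]) -> np.ndarray:
    """Stack spectra (all on one grid) into a (n_spectra, n_bands) matrix."""
    if not spectra:
        raise ParameterError("no spectra given")
    grid = spectra[0].grid
    for s in spectra:
        if s.grid != grid:
            raise ParameterError("spectra are on differing grids")
    return np.vstack([s.values for s in spectra])
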