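"""Spectrum container, reflectance-factor computation, and spectral pretreatments.

A leaf reflectance factor is the per-waveband ratio of leaf radiance to
the mean radiance of the preceding set of white-reference scans.  Prior
to regression analysis, reflectance (rho) is conditioned by six standard
chemometric pretreatments: first and second Savitzky-Golay derivatives,
the base-10 log of inverse reflectance (apparent absorbance) and its two
derivatives, and continuum removal (division by the upper convex hull of
the spectrum, isolating absorption-feature depth).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    GridMismatchError,
    InvalidReferenceError,
    InvalidSpectrumError,
    ParameterError,
)
from .grid import CANONICAL_GRID, SpectralGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SPECTRUM_KINDS",
    "TRANSFORM_KEYS",
    "Spectrum",
    "WhiteReferenceGroup",
    "compute_reflectance",
    "savgol_derivative",
    "log_inverse",
    "continuum_removal",
    "transform_suite",
    "upper_hull_continuum",
]

SPECTRUM_KINDS = (
    "radiance",
    "reflectance",
    "d1",
    "d2",
    "log_inv",
    "log_inv_d1",
    "log_inv_d2",
    "continuum_removed",
)

#: Keys of the seven pretreatment data sets produced by :func:`transform_suite`.
TRANSFORM_KEYS = (
    "reflectance",
    "d1",
    "d2",
    "log_inv",
    "log_inv_d1",
    "log_inv_d2",
    "continuum_removed",
)

#: Floor applied to reflectance before taking logarithms; field spectra can
#: dip to or below zero from instrument noise in strongly absorbing bands.
LOG_FLOOR = 1e-6

#: Savitzky-Golay defaults (window in bands, fitted polynomial order).
SG_WINDOW = 15
SG_POLYORDER = 2


@dataclass
class Spectrum:
    """A wavelength-indexed radiometric vector on a uniform grid.

    ``kind`` records the processing state (radiance, reflectance, or one of
    the pretreatment products); ``meta`` carries design identifiers such as
    experiment, collection, plot, and leaf.
    """

    values: np.ndarray
    kind: str = "reflectance"
    grid: SpectralGrid = CANONICAL_GRID
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidSpectrumError("spectrum values must be 1-D")
        if self.values.shape[0] != self.grid.n_bands:
            raise InvalidSpectrumError(
                f"expected {self.grid.n_bands} bands, got {self.values.shape[0]}"
            )
        if self.kind not in SPECTRUM_KINDS:
            raise InvalidSpectrumError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.values)):
            raise InvalidSpectrumError("reflectance values must be finite")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def at(self, wavelength_nm: float) -> float:
        """Value in the band holding ``wavelength_nm``."""
        return float(self.values[self.grid.index_of(wavelength_nm)])

    def replace(self, values: np.ndarray, kind: str) -> "Spectrum":
        return Spectrum(values=values, kind=kind, grid=self.grid, meta=dict(self.meta))


@dataclass
class WhiteReferenceGroup:
    """A set of white-reference radiance scans bracketing leaf measurements."""

    scans: list

    def __post_init__(self):
        if len(self.scans) == 0:
            raise ParameterError("white reference group needs at least one scan")
        grid = self.scans[0].grid
        for s in self.scans:
            if s.grid != grid:
                raise GridMismatchError("white reference scans on differing grids")

    @property
    def mean_scan(self) -> Spectrum:
        values = np.mean([s.values for s in self.scans], axis=0)
        return Spectrum(values=values, kind="radiance", grid=self.scans[0].grid)


def compute_reflectance(leaf: Spectrum, ref: WhiteReferenceGroup) -> Spectrum:
    """Reflectance factor: leaf radiance over mean white-reference radiance."""
    mean = ref.mean_scan
    if leaf.grid != mean.grid:
        raise GridMismatchError("leaf and reference grids differ")
    if np.any(mean.values <= 0):
        raise InvalidReferenceError("white reference has nonpositive radiance bands")
    out = leaf.replace(leaf.values / mean.values, kind="reflectance")
    return out


def savgol_derivative(
    s: Spectrum,
    order: int = 1,
    window_bands: int = SG_WINDOW,
    poly_order: int = SG_POLYORDER,
) -> Spectrum:
    """Savitzky-Golay derivative with respect to wavelength (per nm, per nm^2).

    Edge bands use the same polynomial fit extended outward, so values near
    350 and 2500 nm remain defined for index formulas.
    """
    if order not in (1, 2):
        raise ParameterError("derivative order must be 1 or 2")
    if window_bands % 2 == 0:
        raise ParameterError("window_bands must be odd")
    if not (window_bands > poly_order >= order):
        raise ParameterError("require window_bands > poly_order >= order")
    if not np.all(np.isfinite(s.values)):
        raise InvalidSpectrumError("cannot differentiate non-finite spectrum")
    deriv = savgol_filter(
        s.values, window_bands, poly_order, deriv=order,
        delta=float(s.grid.step_nm), mode="interp",
    )
    if s.kind == "log_inv":
        kind = "log_inv_d1" if order == 1 else "log_inv_d2"
    else:
        kind = "d1" if order == 1 else "d2"
    return s.replace(deriv, kind=kind)


def log_inverse(s: Spectrum) -> Spectrum:
    """Apparent absorbance: log10(1 / rho), with a small positive floor on rho."""
    if np.all(s.values <= 0):
        raise InvalidSpectrumError("all-nonpositive spectrum has no log-inverse")
    n_bad = int(np.sum(s.values < LOG_FLOOR))
    if n_bad:
        logger.warning("log_inverse: clipping %d nonpositive/low bands to %g", n_bad, LOG_FLOOR)
    clipped = np.clip(s.values, LOG_FLOOR, None)
    return s.replace(-np.log10(clipped), kind="log_inv")


def upper_hull_continuum(wavelengths: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Piecewise-linear upper convex hull evaluated at every wavelength.

    Monotone-chain construction on points already sorted by wavelength;
    handles collinear (e.g. perfectly linear) spectra exactly, where a
    general-position hull code would reject the degenerate input.
    """
    n = len(wavelengths)
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep i2 only if it lies strictly above the chord i1 -> i
            cross = (wavelengths[i2] - wavelengths[i1]) * (values[i] - values[i1]) - (
                wavelengths[i] - wavelengths[i1]
            ) * (values[i2] - values[i1])
            if cross >= 0:  # i2 on or below the chord: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(wavelengths, wavelengths[hull], values[hull])


def continuum_removal(
    s: Spectrum, lo_nm: int | None = None, hi_nm: int | None = None
) -> Spectrum:
    """Divide the spectrum by its upper convex hull over [lo_nm, hi_nm].

    Bands outside the interval keep their (unremoved) reflectance ratioed
    against a hull of 1, i.e. the output equals 1 at and beyond the interval
    endpoints when the full grid is used.  Output values lie in (0, 1].
    """
    lo_nm = s.grid.start_nm if lo_nm is None else lo_nm
    hi_nm = s.grid.end_nm if hi_nm is None else hi_nm
    if not lo_nm < hi_nm:
        raise ParameterError("lo_nm must be below hi_nm")
    i0, i1 = s.grid.index_of(lo_nm), s.grid.index_of(hi_nm)
    if i1 - i0 + 1 < 3:
        raise ParameterError("continuum removal needs at least 3 bands")
    if np.any(s.values[i0 : i1 + 1] <= 0):
        raise InvalidSpectrumError("continuum removal requires positive reflectance")
    wl = s.wavelengths[i0 : i1 + 1].astype(float)
    seg = s.values[i0 : i1 + 1]
    hull = upper_hull_continuum(wl, seg)
    out = np.ones_like(s.values)
    out[i0 : i1 + 1] = np.minimum(seg / hull, 1.0)
    return s.replace(out, kind="continuum_removed")


def transform_suite(
    s: Spectrum,
    window_bands: int = SG_WINDOW,
    poly_order: int = SG_POLYORDER,
) -> Mapping[str, Spectrum]:
    """The seven pretreatment spectral data sets derived from one reflectance
    spectrum: rho itself, its two derivatives, log-inverse reflectance with
    its two derivatives, and the continuum-removed spectrum.  (The eighth
    data set used for modeling, the vegetation-index values, is produced by
    the index engine.)
    """
    if s.kind != "reflectance":
        raise InvalidSpectrumError("transform_suite expects a reflectance spectrum")
    li = log_inverse(s)
    return {
        "reflectance": s,
        "d1": savgol_derivative(s, 1, window_bands, poly_order),
        "d2": savgol_derivative(s, 2, window_bands, poly_order),
        "log_inv": li,
        "log_inv_d1": savgol_derivative(li, 1, window_bands, poly_order),
        "log_inv_d2": savgol_derivative(li, 2, window_bands, poly_order),
        "continuum_removed": continuum_removal(s),
    }
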