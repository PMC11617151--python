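"""Matrix-level spectral pretreatments with a scikit-learn transformer API.

These transformers operate on 2-D arrays of shape (n_spectra, n_bands),
the natural container when hundreds of leaf spectra feed a regression
pipeline; each is a stateless ``TransformerMixin`` so pretreatments can
be composed with scikit-learn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .errors import ParameterError
from .grid import CANONICAL_GRID, SpectralGrid
from .spectra import LOG_FLOOR, SG_POLYORDER, SG_WINDOW, upper_hull_continuum

__all__ = [
    "SavitzkyGolayDerivative",
    "LogInverseReflectance",
    "ContinuumRemover",
    "transform_suite_matrix",
]


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay derivative of each row spectrum w.r.t. wavelength.

    Parameters
    ----------
    order : int, derivative order (1 or 2).
    window_bands : odd int, filter window length in bands.
    poly_order : int, order of the fitted polynomial.
    step_nm : float, grid spacing, so output units are per nm (per nm^2).
    """

    def __init__(self, order: int = 1, window_bands: int = SG_WINDOW,
                 poly_order: int = SG_POLYORDER, step_nm: float = 1.0):
        self.order = order
        self.window_bands = window_bands
        self.poly_order = poly_order
        self.step_nm = step_nm

    def fit(self, X, y=None):
        X = check_array(X)
        if self.order not in (1, 2):
            raise ParameterError("derivative order must be 1 or 2")
        if self.window_bands % 2 == 0 or not (self.window_bands > self.poly_order >= self.order):
            raise ParameterError("require odd window_bands > poly_order >= order")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        return savgol_filter(
            X, self.window_bands, self.poly_order, deriv=self.order,
            delta=self.step_nm, mode="interp", axis=-1,
        )


class LogInverseReflectance(TransformerMixin, BaseEstimator):
    """Apparent absorbance log10(1/rho), flooring rho at a small positive value."""

    def __init__(self, floor: float = LOG_FLOOR):
        self.floor = floor

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        return -np.log10(np.clip(X, self.floor, None))


class ContinuumRemover(TransformerMixin, BaseEstimator):
    """Divide each row spectrum by its upper convex hull over [lo_nm, hi_nm]."""

    def __init__(self, grid: SpectralGrid = CANONICAL_GRID,
                 lo_nm: int | None = None, hi_nm: int | None = None):
        self.grid = grid
        self.lo_nm = lo_nm
        self.hi_nm = hi_nm

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[1] != self.grid.n_bands:
            raise ParameterError(
                f"expected {self.grid.n_bands} bands, got {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        lo = self.grid.start_nm if self.lo_nm is None else self.lo_nm
        hi = self.grid.end_nm if self.hi_nm is None else self.hi_nm
        i0, i1 = self.grid.index_of(lo), self.grid.index_of(hi)
        wl = self.grid.wavelengths[i0 : i1 + 1].astype(float)
        out = np.ones_like(X, dtype=float)
        for r in range(X.shape[0]):
            seg = X[r, i0 : i1 + 1]
            hull = upper_hull_continuum(wl, seg)
            out[r, i0 : i1 + 1] = np.minimum(seg / hull, 1.0)
        return out


def transform_suite_matrix(
    X: np.ndarray,
    grid: SpectralGrid = CANONICAL_GRID,
    window_bands: int = SG_WINDOW,
    poly_order: int = SG_POLYORDER,
) -> dict[str, np.ndarray]:
    """The seven pretreatment data sets for a (n_spectra, n_bands) matrix.

    Matrix counterpart of :func:`leafchl.spectra.transform_suite`.
    """
    X = np.asarray(X, dtype=float)
    d1 = SavitzkyGolayDerivative(1, window_bands, poly_order, grid.step_nm)
    d2 = SavitzkyGolayDerivative(2, window_bands, poly_order, grid.step_nm)
    li = LogInverseReflectance().fit(X).transform(X)
    return {
        "reflectance": X,
        "d1": d1.fit(X).transform(X),
        "d2": d2.fit(X).transform(X),
        "log_inv": li,
        "log_inv_d1": d1.fit(li).transform(li),
        "log_inv_d2": d2.fit(li).transform(li),
        "continuum_removed": ContinuumRemover(grid).fit(X).transform(X),
    }
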