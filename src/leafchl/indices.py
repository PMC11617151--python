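"""Registry and evaluation engine for 148 spectral vegetation indices.

Each index is a declarative definition: a short code, a formula expression
over reflectance (``R700``), first/second Savitzky-Golay derivatives
(``D700``/``DD700``), continuum-removed reflectance (``CR700``), and a
small set of range functions (derivative sums and maxima, band-depth
areas, red-edge inflection estimators).  Definitions are compiled from
``data/indices.json`` at import of :func:`registry`.

The engine is vectorized: expressions are evaluated against per-band
column vectors of a (n_spectra, n_bands) matrix, so computing all 148
indices for thousands of spectra is a handful of array operations per
index.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .errors import NoRedEdgeError, ParameterError, RegistryError
from .grid import CANONICAL_GRID, SpectralGrid
from .spectra import SG_POLYORDER, SG_WINDOW, Spectrum
from .transforms import ContinuumRemover, SavitzkyGolayDerivative

logger = logging.getLogger(__name__)

__all__ = [
    "IndexDefinition",
    "registry",
    "compute_index",
    "compute_all",
    "red_edge_inflection",
    "derivative_area",
    "VegetationIndexCalculator",
]

FORMULA_KINDS = (
    "band_arithmetic",
    "derivative_integral",
    "red_edge_position",
    "continuum_feature",
    "composite_ratio",
)

_TOKEN_RE = re.compile(r"\b(R|D|DD|CR)(\d{3,4})\b")
_RANGE_FN_RE = re.compile(
    r"\b(SUMD1|SUMABSD1|SUMABSD2|SUMR|MAXD1|WLMAXD1|WLMIND1|AREABD|MAXBD)"
    r"\(\s*(\d+)\s*,\s*(\d+)\s*\)"
)


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral vegetation index."""

    name: str
    expression: str
    formula_kind: str
    required_transform: str  # reflectance | d1 | continuum_removed
    required_bands: tuple
    citation: str
    cluster_label: str | None = None

    def __post_init__(self):
        if self.formula_kind not in FORMULA_KINDS:
            raise RegistryError(f"{self.name}: unknown formula kind {self.formula_kind!r}")
        for b in self.required_bands:
            if not (CANONICAL_GRID.start_nm <= b <= CANONICAL_GRID.end_nm):
                raise RegistryError(f"{self.name}: band {b} nm outside 350-2500")


def _bands_from_expression(expression: str) -> tuple:
    bands = {int(m.group(2)) for m in _TOKEN_RE.finditer(expression)}
    for m in _RANGE_FN_RE.finditer(expression):
        bands.update((int(m.group(2)), int(m.group(3))))
    if "REIP_LIN" in expression:
        bands.update((670, 700, 740, 780))
    if "REIP_GAUSS" in expression:
        bands.update((670, 800))
    return tuple(sorted(bands))


def _transform_from_expression(expression: str) -> str:
    if re.search(r"\bCR\d", expression) or "AREABD" in expression or "MAXBD" in expression:
        return "continuum_removed"
    if re.search(r"\bD{1,2}\d", expression) or any(
        fn in expression for fn in ("SUMD1", "SUMABSD1", "SUMABSD2", "MAXD1", "WLMAXD1", "WLMIND1")
    ):
        return "d1"
    return "reflectance"


@lru_cache(maxsize=1)
def registry() -> tuple:
    """The full roster of index definitions, loaded from the data file."""
    text = resources.files("leafchl").joinpath("data/indices.json").read_text()
    raw = json.loads(text)
    defs, seen = [], set()
    for row in raw:
        name = row["name"]
        if name in seen:
            raise RegistryError(f"duplicate index name {name!r}")
        seen.add(name)
        expression = row["expression"]
        defs.append(
            IndexDefinition(
                name=name,
                expression=expression,
                formula_kind=row["formula_kind"],
                required_transform=_transform_from_expression(expression),
                required_bands=_bands_from_expression(expression),
                citation=row.get("citation", ""),
                cluster_label=row.get("cluster_label"),
            )
        )
    return tuple(defs)


def registry_lookup(name: str) -> IndexDefinition:
    for d in registry():
        if d.name == name:
            return d
    raise KeyError(name)


# ---------------------------------------------------------------------------
# red-edge inflection point estimators
# ---------------------------------------------------------------------------

RED_EDGE_LO, RED_EDGE_HI = 670, 800


def _d1_matrix(X: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    sg = SavitzkyGolayDerivative(1, SG_WINDOW, SG_POLYORDER, grid.step_nm)
    return sg.fit(X).transform(X)


def _reip_max_d1(X: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    i0, i1 = grid.index_of(RED_EDGE_LO), grid.index_of(RED_EDGE_HI)
    d1 = _d1_matrix(X, grid)[:, i0 : i1 + 1]
    return grid.wavelengths[i0 + np.argmax(d1, axis=1)].astype(float)


def _reip_linear(X: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    """Four-band linear-interpolation red-edge position (Guyot & Baret)."""
    r670 = X[:, grid.index_of(670)]
    r700 = X[:, grid.index_of(700)]
    r740 = X[:, grid.index_of(740)]
    r780 = X[:, grid.index_of(780)]
    r_edge = (r670 + r780) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        reip = 700.0 + 40.0 * (r_edge - r700) / (r740 - r700)
    return reip


def _reip_gaussian(X: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    """Inverted-Gaussian red-edge model, fit per spectrum over 670-800 nm.

    R(l) = Rs - (Rs - R0) * exp(-(l - l0)^2 / (2 s^2)); the inflection
    wavelength is reported as l0 + s.  Bounded least squares with
    l0 in [680, 780] and s in [5, 60], started at the max-d1 wavelength.
    """
    i0, i1 = grid.index_of(RED_EDGE_LO), grid.index_of(RED_EDGE_HI)
    wl = grid.wavelengths[i0 : i1 + 1].astype(float)
    starts = _reip_max_d1(X, grid)
    out = np.empty(X.shape[0])
    for r in range(X.shape[0]):
        seg = X[r, i0 : i1 + 1]
        rs0, r00 = float(seg.max()), float(seg.min())

        def resid(p, seg=seg):
            rs, r0, l0, sig = p
            return rs - (rs - r0) * np.exp(-((wl - l0) ** 2) / (2 * sig**2)) - seg

        x0 = [rs0, r00, float(np.clip(starts[r] - 30.0, 680.0, 780.0)), 30.0]
        try:
            fit = least_squares(
                resid, x0,
                bounds=([0.0, 0.0, 680.0, 5.0], [2.0, 2.0, 780.0, 60.0]),
            )
            out[r] = fit.x[2] + fit.x[3]
        except Exception:  # fit failure -> undefined value
            out[r] = np.nan
    return out


def red_edge_inflection(s: Spectrum, method: str = "max_d1") -> float:
    """Red-edge inflection-point wavelength (nm) of one reflectance spectrum.

    Methods: ``max_d1`` (argmax of the smoothed first derivative),
    ``linear_interpolation`` (four-band Guyot estimator), ``gaussian_fit``
    (inverted-Gaussian model, returns l0 + sigma).
    """
    if s.at(780) <= s.at(670):
        raise NoRedEdgeError("spectrum has no rising red edge (rho780 <= rho670)")
    X = s.values[None, :]
    if method == "max_d1":
        return float(_reip_max_d1(X, s.grid)[0])
    if method == "linear_interpolation":
        return float(_reip_linear(X, s.grid)[0])
    if method == "gaussian_fit":
        return float(_reip_gaussian(X, s.grid)[0])
    raise ParameterError(f"unknown red-edge method {method!r}")


def derivative_area(s: Spectrum, lo_nm: int, hi_nm: int) -> float:
    """Trapezoid integral of the first derivative of reflectance over [lo, hi].

    Uses central differences rather than the smoothing filter so the sum
    telescopes to the net reflectance rise across the interval.
    """
    if not lo_nm < hi_nm:
        raise ParameterError("lo_nm must be below hi_nm")
    i0, i1 = s.grid.index_of(lo_nm), s.grid.index_of(hi_nm)
    d1 = np.gradient(s.values, float(s.grid.step_nm))[i0 : i1 + 1]
    return float(np.trapezoid(d1, dx=s.grid.step_nm))


# ---------------------------------------------------------------------------
# expression evaluation
# ---------------------------------------------------------------------------


class _EvalContext:
    """Lazy per-matrix feature store backing expression evaluation."""

    def __init__(self, X: np.ndarray, grid: SpectralGrid):
        self.X = np.asarray(X, dtype=float)
        self.grid = grid
        self._cache: dict[str, np.ndarray] = {}

    def _get(self, key: str, maker) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = maker()
        return self._cache[key]

    @property
    def d1(self):
        return self._get("d1", lambda: _d1_matrix(self.X, self.grid))

    @property
    def d2(self):
        sg = SavitzkyGolayDerivative(2, SG_WINDOW, SG_POLYORDER, self.grid.step_nm)
        return self._get("d2", lambda: sg.fit(self.X).transform(self.X))

    @property
    def cr(self):
        cr = ContinuumRemover(self.grid)
        return self._get("cr", lambda: cr.fit(self.X).transform(self.X))

    def _sl(self, lo: int, hi: int) -> slice:
        return slice(self.grid.index_of(lo), self.grid.index_of(hi) + 1)

    def namespace(self, expression: str) -> dict:
        g = self.grid
        env: dict = {
            "SQRT": np.sqrt, "ABS": np.abs, "LOG10": np.log10, "EXP": np.exp,
            "SUMR": lambda lo, hi: self.X[:, self._sl(lo, hi)].sum(axis=1),
            "SUMD1": lambda lo, hi: self.d1[:, self._sl(lo, hi)].sum(axis=1),
            "SUMABSD1": lambda lo, hi: np.abs(self.d1[:, self._sl(lo, hi)]).sum(axis=1),
            "SUMABSD2": lambda lo, hi: np.abs(self.d2[:, self._sl(lo, hi)]).sum(axis=1),
            "MAXD1": lambda lo, hi: self.d1[:, self._sl(lo, hi)].max(axis=1),
            "WLMAXD1": lambda lo, hi: g.wavelengths[
                g.index_of(lo) + np.argmax(self.d1[:, self._sl(lo, hi)], axis=1)
            ].astype(float),
            "WLMIND1": lambda lo, hi: g.wavelengths[
                g.index_of(lo) + np.argmin(self.d1[:, self._sl(lo, hi)], axis=1)
            ].astype(float),
            "AREABD": lambda lo, hi: (1.0 - self.cr[:, self._sl(lo, hi)]).sum(axis=1),
            "MAXBD": lambda lo, hi: (1.0 - self.cr[:, self._sl(lo, hi)]).max(axis=1),
            "REIP_LIN": lambda: _reip_linear(self.X, g),
            "REIP_GAUSS": lambda: _reip_gaussian(self.X, g),
        }
        for m in _TOKEN_RE.finditer(expression):
            prefix, band = m.group(1), int(m.group(2))
            token = f"{prefix}{band}"
            if token in env:
                continue
            idx = g.index_of(band)
            source = {"R": self.X, "D": self.d1, "DD": self.d2, "CR": self.cr}[prefix]
            env[token] = source[:, idx]
        return env

    def evaluate(self, defn: IndexDefinition) -> np.ndarray:
        expr = defn.expression
        if expr == "REIP_LIN":
            expr = "REIP_LIN()"
        if expr == "REIP_GAUSS":
            expr = "REIP_GAUSS()"
        env = self.namespace(defn.expression)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            result = eval(expr, {"__builtins__": {}}, env)  # noqa: S307 - closed DSL
        result = np.asarray(result, dtype=float)
        if result.ndim == 0:
            result = np.full(self.X.shape[0], float(result))
        return np.where(np.isfinite(result), result, np.nan)


def compute_index(defn: IndexDefinition, s) -> float | np.ndarray:
    """Evaluate one index for a reflectance ``Spectrum`` or (n, bands) matrix.

    Undefined values (zero denominators, failed fits) come back as NaN.
    """
    if isinstance(s, Spectrum):
        ctx = _EvalContext(s.values[None, :], s.grid)
        return float(ctx.evaluate(defn)[0])
    X = check_array(s)
    return _EvalContext(X, CANONICAL_GRID).evaluate(defn)


def compute_all(s, grid: SpectralGrid = CANONICAL_GRID) -> pd.DataFrame:
    """Evaluate every registry index; one column per index, one row per spectrum.

    Undefined values are encoded as NaN and counted in the log; downstream
    regressions exclude them pairwise.
    """
    if isinstance(s, Spectrum):
        X, grid = s.values[None, :], s.grid
    else:
        X = check_array(s)
    ctx = _EvalContext(X, grid)
    cols = {}
    n_undefined = 0
    for defn in registry():
        vals = ctx.evaluate(defn)
        n_undefined += int(np.sum(~np.isfinite(vals)))
        cols[defn.name] = vals
    if n_undefined:
        logger.warning("compute_all: %d undefined index values flagged as NaN", n_undefined)
    return pd.DataFrame(cols)


class VegetationIndexCalculator(TransformerMixin, BaseEstimator):
    """Transformer mapping reflectance matrices to the 148-index feature set."""

    def __init__(self, grid: SpectralGrid = CANONICAL_GRID):
        self.grid = grid

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[1] != self.grid.n_bands:
            raise ParameterError(f"expected {self.grid.n_bands} bands, got {X.shape[1]}")
        self.n_features_in_ = X.shape[1]
        self.index_names_ = [d.name for d in registry()]
        return self

    def transform(self, X):
        return compute_all(check_array(X), grid=self.grid).to_numpy()

    def get_feature_names_out(self, input_features=None):
        return np.asarray([d.name for d in registry()], dtype=object)
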