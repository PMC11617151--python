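"""Single-index linear models, the 14-algorithm regression zoo, and
statistical comparison of model errors.

Every (chlorophyll metric x spectral data set) pair is a "realization";
with six metrics and eight spectral sets each estimator is trained on 48
realizations, scored as percent RMSE (100 * RMSE / mean of the observed
target) and r^2 on both the training and testing partitions.  Dynamic
hyperparameters are chosen by repeated k-fold cross-validated grid
search maximizing negative RMSE; ties break to the first candidate in
grid order.  Model errors are compared by main-effects ANOVA on RMSE%
plus Tukey HSD with a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import BayesianRidge, Lasso, LassoLars, Ridge
from sklearn.model_selection import GridSearchCV, RepeatedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .assembly import PairedDataset, standardize
from .chlorophyll import CHL_METRICS
from .errors import ParameterError
from .spectra import TRANSFORM_KEYS

logger = logging.getLogger(__name__)

__all__ = [
    "SPECTRAL_SETS",
    "ESTIMATOR_IDS",
    "EvalResult",
    "SearchSpec",
    "make_estimator",
    "default_grid",
    "eval_index_linear",
    "fit_with_search",
    "run_realizations",
    "anova_tukey",
    "rmse_pct",
]

#: The eight spectral data sets (seven pretreatments + the index values).
SPECTRAL_SETS = TRANSFORM_KEYS + ("svi",)

_RANDOMIZED = {"DecisionTreeRegressor", "GradientBoostingRegressor",
               "RandomForestRegressor", "AdaBoostRegressor", "MLPRegressor"}

# estimator id -> (class, static hyperparameters)
_ZOO = {
    "Ridge": (Ridge, {"tol": 1e-4}),
    "Lasso": (Lasso, {}),
    "LassoLars": (LassoLars, {"eps": 1e-4, "max_iter": 1_000_000}),
    "BayesianRidge": (BayesianRidge, {"tol": 1e-4}),
    "KernelRidge": (KernelRidge, {}),
    "SVR": (SVR, {"tol": 1e-4}),
    "KNeighborsRegressor": (KNeighborsRegressor, {}),
    "PLSRegression": (PLSRegression, {"scale": False}),
    "GaussianProcessRegressor": (GaussianProcessRegressor, {}),
    "DecisionTreeRegressor": (DecisionTreeRegressor, {}),
    "GradientBoostingRegressor": (GradientBoostingRegressor, {}),
    "RandomForestRegressor": (RandomForestRegressor, {}),
    "AdaBoostRegressor": (AdaBoostRegressor, {}),
    "MLPRegressor": (MLPRegressor, {"solver": "lbfgs", "max_iter": 2000}),
}

ESTIMATOR_IDS = tuple(_ZOO)

# Dynamic grids: the printed roster names which hyperparameters are tuned;
# the candidate values are this package's reconstruction (log grids over
# six decades for regularization, 1..20 for components/neighbors, standard
# depth/leaf grids for trees), all overridable per search.
_DEFAULT_GRIDS = {
    "Ridge": {"alpha": np.logspace(-3, 3, 7).tolist()},
    "Lasso": {"alpha": np.logspace(-4, 2, 7).tolist()},
    "LassoLars": {"alpha": np.logspace(-4, 2, 7).tolist()},
    "BayesianRidge": {},
    "KernelRidge": {"alpha": np.logspace(-3, 3, 7).tolist()},
    "SVR": {"C": np.logspace(-2, 3, 6).tolist()},
    "KNeighborsRegressor": {"n_neighbors": list(range(1, 21))},
    "PLSRegression": {"n_components": list(range(1, 21))},
    "GaussianProcessRegressor": {},
    "DecisionTreeRegressor": {"max_depth": [2, 4, 8, None],
                              "min_samples_split": [2, 10],
                              "min_samples_leaf": [1, 5]},
    "GradientBoostingRegressor": {"learning_rate": [0.01, 0.1, 0.3],
                                  "max_depth": [2, 3, 5]},
    "RandomForestRegressor": {"n_estimators": [100, 300],
                              "min_samples_split": [2, 10],
                              "min_samples_leaf": [1, 5]},
    "AdaBoostRegressor": {"n_estimators": [50, 200],
                          "learning_rate": [0.1, 1.0]},
    "MLPRegressor": {"hidden_layer_sizes": [(16,), (64,), (32, 16)],
                     "alpha": [1e-4, 1e-2, 1.0]},
}


def default_grid(estimator_id: str) -> dict:
    if estimator_id not in _DEFAULT_GRIDS:
        raise ParameterError(f"unknown estimator {estimator_id!r}")
    return {k: list(v) for k, v in _DEFAULT_GRIDS[estimator_id].items()}


def make_estimator(estimator_id: str, random_state: int | None = None):
    """Instantiate a zoo member with its static hyperparameters."""
    if estimator_id not in _ZOO:
        raise ParameterError(f"unknown estimator {estimator_id!r}")
    cls, static = _ZOO[estimator_id]
    kwargs = dict(static)
    if estimator_id in _RANDOMIZED:
        kwargs["random_state"] = random_state
    return cls(**kwargs)


@dataclass(frozen=True)
class SearchSpec:
    """Hyperparameter-search configuration for one estimator."""

    estimator_id: str
    grid: dict | None = None       # None -> package default grid
    cv_splits: int = 5
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.cv_splits < 2 or self.cv_repeats < 1:
            raise ParameterError("need cv_splits >= 2 and cv_repeats >= 1")


@dataclass
class EvalResult:
    """Goodness of fit of one estimator on one realization and phase."""

    chl_metric: str
    spectral_set: str
    estimator: str
    phase: str                 # "train" | "test"
    rmse_pct: float
    r2: float
    hyperparameters: dict = dc_field(default_factory=dict)
    n: int = 0
    flagged: bool = False


def rmse_pct(y_true, y_pred) -> float:
    """RMSE as a percent of the mean observed value."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rmse = np.sqrt(np.mean((y_true - y_pred) ** 2))
    return float(100.0 * rmse / np.mean(y_true))


def _r2(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    ss_res = np.sum((y_true - np.asarray(y_pred)) ** 2)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan


def eval_index_linear(index_values, chl_values) -> dict:
    """Simple linear regression of chlorophyll on one spectral index.

    NaN-flagged index values are excluded pairwise.  Returns slope,
    intercept, r^2, RMSE% (normalized by the mean of the fitted
    chlorophyll values) and the pair count; zero index variance flags
    the result undefined.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(chl_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ParameterError("need at least 3 complete (index, chlorophyll) pairs")
    if np.var(x) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan,
                "rmse_pct": np.nan, "n": int(x.size), "flagged": True}
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2), "rmse_pct": rmse_pct(y, pred),
            "n": int(x.size), "flagged": False}


def fit_with_search(spec: SearchSpec, X: np.ndarray, y: np.ndarray):
    """Fit one zoo member, grid-searching its dynamic hyperparameters.

    Repeated k-fold cross validation on the training data scores each
    candidate by negative RMSE; the best candidate is refit on the full
    training set.  Estimators with no dynamic grid (BayesianRidge,
    GaussianProcessRegressor) are fit directly.  Returns (fitted model,
    chosen hyperparameters).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = default_grid(spec.estimator_id) if spec.grid is None else dict(spec.grid)
    for key, values in grid.items():
        if len(values) == 0:
            raise ParameterError(f"empty grid for hyperparameter {key!r}")
    if "n_components" in grid:
        # PLS components cannot exceed the feature count or fold size
        cap = min(X.shape[1], X.shape[0] * (spec.cv_splits - 1) // spec.cv_splits)
        grid["n_components"] = [c for c in grid["n_components"] if c <= cap] or [1]
    base = make_estimator(spec.estimator_id, random_state=spec.seed)
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if not grid:
            model = clone(base).fit(X, y)
            return model, {}
        cv = RepeatedKFold(n_splits=spec.cv_splits, n_repeats=spec.cv_repeats,
                           random_state=spec.seed)
        search = GridSearchCV(base, grid, scoring="neg_root_mean_squared_error",
                              cv=cv, refit=True, n_jobs=None)
        search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


def prepare_feature_sets(features: pd.DataFrame, grid, svi: pd.DataFrame | None = None,
                         sets: tuple = SPECTRAL_SETS) -> dict:
    """Compute the requested spectral data sets from a reflectance matrix."""
    from .indices import compute_all
    from .transforms import transform_suite_matrix

    X = features.to_numpy(dtype=float)
    needed = [k for k in sets if k != "svi"]
    out = {}
    if needed:
        suite = transform_suite_matrix(X, grid=grid)
        out.update({k: suite[k] for k in needed})
    if "svi" in sets:
        out["svi"] = (svi if svi is not None else compute_all(X, grid=grid)).to_numpy(dtype=float)
    return out


def run_realizations(
    train: PairedDataset,
    test: PairedDataset,
    estimators: tuple = ESTIMATOR_IDS,
    spectral_sets: tuple = SPECTRAL_SETS,
    chl_metrics: tuple = CHL_METRICS,
    grids: dict | None = None,
    cv_splits: int = 5,
    cv_repeats: int = 10,
    seed: int = 0,
    svi_train: pd.DataFrame | None = None,
    svi_test: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate every (metric x spectral set x estimator) realization.

    Features are standardized with training-set parameters; NaN index
    values are imputed with the training-column mean before scaling.
    Failures of individual members are recorded as flagged rows and the
    run continues.  Output has one row per realization and phase.
    """
    from .grid import CANONICAL_GRID

    grid_obj = CANONICAL_GRID if train.features.shape[1] == CANONICAL_GRID.n_bands else None
    if grid_obj is None:
        from .grid import SpectralGrid
        # features may be a reduced band set; infer from column names R###
        wls = [int(c[1:]) for c in train.features.columns]
        step = wls[1] - wls[0]
        grid_obj = SpectralGrid(wls[0], wls[-1], step)
    fs_train = prepare_feature_sets(train.features, grid_obj, svi=svi_train, sets=spectral_sets)
    fs_test = prepare_feature_sets(test.features, grid_obj, svi=svi_test, sets=spectral_sets)

    rows = []
    for metric in chl_metrics:
        y_tr = train.targets[metric].to_numpy(dtype=float)
        y_te = test.targets[metric].to_numpy(dtype=float)
        for sset in spectral_sets:
            Xtr = fs_train[sset].copy()
            Xte = fs_test[sset].copy()
            col_mean = np.nanmean(Xtr, axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            Xtr = np.where(np.isfinite(Xtr), Xtr, col_mean)
            Xte = np.where(np.isfinite(Xte), Xte, col_mean)
            Xtr_s, Xte_s, _ = standardize(Xtr, Xte)
            for est in estimators:
                spec = SearchSpec(
                    est,
                    grid=None if grids is None else grids.get(est),
                    cv_splits=cv_splits, cv_repeats=cv_repeats, seed=seed,
                )
                try:
                    model, chosen = fit_with_search(spec, Xtr_s, y_tr)
                    for phase, Xp, yp in (("train", Xtr_s, y_tr), ("test", Xte_s, y_te)):
                        pred = np.ravel(model.predict(Xp))
                        rows.append(EvalResult(metric, sset, est, phase,
                                               rmse_pct(yp, pred), _r2(yp, pred),
                                               chosen, len(yp)))
                except Exception as exc:  # member failure: flag and continue
                    logger.warning("realization (%s, %s, %s) failed: %s",
                                   metric, sset, est, exc)
                    for phase in ("train", "test"):
                        rows.append(EvalResult(metric, sset, est, phase,
                                               np.nan, np.nan, {}, 0, flagged=True))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# ANOVA and Tukey comparison of model errors
# ---------------------------------------------------------------------------


def _compact_letters(levels: list, sig: dict) -> dict:
    """Compact letter display from pairwise significance decisions."""
    groups: list[set] = []
    for lev in levels:
        placed = False
        for g in groups:
            if all(not sig.get(frozenset((lev, other)), False) for other in g):
                g.add(lev)
                placed = True
        if not placed:
            g = {lev}
            for other in levels:
                if other == lev:
                    continue
                if not sig.get(frozenset((lev, other)), False) and all(
                    not sig.get(frozenset((other, k)), False) for k in g
                ):
                    g.add(other)
            groups.append(g)
    letters = {lev: "" for lev in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lev in g:
            letters[lev] += letter
    return letters


def anova_tukey(
    results: pd.DataFrame,
    factors: tuple = ("estimator", "spectral_set", "chl_metric"),
    response: str = "rmse_pct",
    alpha: float = 0.05,
) -> dict:
    """Main-effects ANOVA on RMSE% plus Tukey HSD letter groupings.

    Returns ``{"anova": DataFrame(factor, df, F, p), "tukey": {factor:
    DataFrame(level, mean, letters)}}``.  A factor with any level
    observed fewer than twice raises, naming the factor.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = results.dropna(subset=[response]).copy()
    for factor in factors:
        counts = data[factor].value_counts()
        if counts.size < 2:
            raise ParameterError(f"factor {factor!r} needs at least 2 levels")
        if (counts < 2).any():
            raise ParameterError(f"factor {factor!r} is unreplicated in some level")

    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    anova_rows = []
    if np.var(data[response].to_numpy()) == 0:
        # degenerate: zero total variation -> no factor effect
        for factor in factors:
            anova_rows.append({"factor": factor,
                               "df": data[factor].nunique() - 1,
                               "F": 0.0, "p": 1.0})
    else:
        model = ols(formula, data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for factor in factors:
            row = table.loc[f"C({factor})"]
            f_val = row["F"]
            anova_rows.append({
                "factor": factor, "df": int(row["df"]),
                "F": 0.0 if not np.isfinite(f_val) else float(f_val),
                "p": 1.0 if not np.isfinite(row["PR(>F)"]) else float(row["PR(>F)"]),
            })
    tukey_out = {}
    for factor in factors:
        levels = sorted(data[factor].unique(),
                        key=lambda l: data.loc[data[factor] == l, response].mean())
        if np.var(data[response].to_numpy()) == 0:
            sig: dict = {}
        else:
            hsd = pairwise_tukeyhsd(data[response], data[factor], alpha=alpha)
            res = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
            sig = {
                frozenset((row["group1"], row["group2"])): bool(row["reject"])
                for _, row in res.iterrows()
            }
        letters = _compact_letters(levels, sig)
        tukey_out[factor] = pd.DataFrame({
            "level": levels,
            "mean": [data.loc[data[factor] == l, response].mean() for l in levels],
            "letters": [letters[l] for l in levels],
        })
    return {"anova": pd.DataFrame(anova_rows), "tukey": tukey_out}
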