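"""Pair spectra with chlorophyll and assemble analysis datasets.

The level of averaging prior to analysis ("data scale") matters: at
*sample* scale each tissue sample is paired with its leaf's spectrum
(the spectrum duplicated across the leaf's samples); *leaf* scale
averages the samples per leaf; *plot* scale averages chlorophyll over
the plot's samples and spectra over the plot's leaves, per collection;
*entry* scale averages by genotype within collection, eliminating
replication.  Train/test partitioning is either by experiment
(2019-2020 style data for training, 2021-2022 style for testing) or a
seeded random split without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .chlorophyll import CHL_METRICS
from .errors import ParameterError
from .grid import CANONICAL_GRID, SpectralGrid

logger = logging.getLogger(__name__)

__all__ = ["SCALES", "PairedDataset", "SplitSpec", "aggregate", "split",
           "standardize", "combine"]

SCALES = ("sample", "leaf", "plot", "entry")

_GROUP_KEYS = {
    "leaf": ["experiment_id", "collection_id", "plot_id", "leaf_id"],
    "plot": ["experiment_id", "collection_id", "plot_id"],
    "entry": ["experiment_id", "collection_id", "entry_id"],
}


@dataclass
class PairedDataset:
    """Row-aligned features (spectra or index values) and chlorophyll targets."""

    scale: str
    ids: pd.DataFrame        # identifier columns, one row per observation
    features: pd.DataFrame   # spectral features, one column per band/index
    targets: pd.DataFrame    # the six chlorophyll metrics

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ParameterError(f"unknown scale {self.scale!r}")
        if not (len(self.ids) == len(self.features) == len(self.targets)):
            raise ParameterError("ids, features, targets must be row-aligned")
        if self.ids["row_id"].duplicated().any():
            raise ParameterError("duplicated row identifiers")

    @property
    def n(self) -> int:
        return len(self.ids)

    def take(self, positions: np.ndarray) -> "PairedDataset":
        return PairedDataset(
            scale=self.scale,
            ids=self.ids.iloc[positions].reset_index(drop=True),
            features=self.features.iloc[positions].reset_index(drop=True),
            targets=self.targets.iloc[positions].reset_index(drop=True),
        )

    def with_features(self, features: pd.DataFrame) -> "PairedDataset":
        if len(features) != self.n:
            raise ParameterError("replacement features not row-aligned")
        return PairedDataset(self.scale, self.ids.copy(), features.reset_index(drop=True),
                             self.targets.copy())


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partitioning rule."""

    strategy: str = "random"           # "random" | "by_experiment"
    train_fraction: float = 0.8
    seed: int = 0
    train_experiment: str = "exp1"

    def __post_init__(self):
        if self.strategy not in ("random", "by_experiment"):
            raise ParameterError(f"unknown split strategy {self.strategy!r}")
        if self.strategy == "random" and not (0.0 < self.train_fraction < 1.0):
            raise ParameterError("train_fraction must be in (0, 1)")


def _band_columns(grid: SpectralGrid) -> list:
    return [f"R{w}" for w in grid.wavelengths]


def aggregate(
    records: pd.DataFrame,
    leaf_meta: pd.DataFrame,
    reflectance: np.ndarray,
    scale: str = "plot",
    grid: SpectralGrid = CANONICAL_GRID,
) -> PairedDataset:
    """Pair chlorophyll records with leaf spectra and average to ``scale``.

    ``leaf_meta`` holds one row per measured leaf, aligned with the rows
    of ``reflectance``; records resolve to spectra through ``leaf_id``.
    Orphan records (no spectrum for their leaf) are logged and dropped.
    """
    if scale not in SCALES:
        raise ParameterError(f"unknown scale {scale!r}")
    leaf_index = pd.Series(np.arange(len(leaf_meta)), index=leaf_meta["leaf_id"])
    rows = leaf_index.reindex(records["leaf_id"])
    orphans = rows.isna()
    if orphans.any():
        logger.warning("aggregate: dropping %d orphan records with no spectrum", orphans.sum())
        records = records.loc[~orphans.to_numpy()].reset_index(drop=True)
        rows = rows.dropna()
    rows = rows.to_numpy(dtype=int)
    bands = _band_columns(grid)
    metrics = list(CHL_METRICS)

    if scale == "sample":
        ids = records[["sample_id", "leaf_id", "plot_id", "entry_id",
                       "collection_id", "experiment_id"]].copy()
        ids.insert(0, "row_id", records["sample_id"])
        features = pd.DataFrame(reflectance[rows], columns=bands)
        targets = records[metrics].reset_index(drop=True)
        return PairedDataset(scale, ids.reset_index(drop=True), features, targets)

    keys = _GROUP_KEYS[scale]
    chl = records.groupby(keys, sort=True)[metrics].mean().reset_index()
    # spectra average over distinct leaves of the group (not per sample, so
    # multi-sample leaves are not double-weighted)
    leaf_cols = [c for c in keys if c in leaf_meta.columns]
    spec_df = leaf_meta[leaf_cols].copy()
    spec_df["_row"] = np.arange(len(leaf_meta))
    merged = chl[keys].merge(spec_df, on=leaf_cols, how="left")
    grouped_rows = merged.groupby(keys, sort=True)["_row"]
    features = np.vstack([
        reflectance[idx.to_numpy(dtype=int)].mean(axis=0)
        for _, idx in grouped_rows
    ])
    # grouped_rows iterates in the same sorted key order as chl
    ids = chl[keys].copy()
    ids.insert(0, "row_id", chl[keys].astype(str).agg("|".join, axis=1))
    return PairedDataset(
        scale, ids.reset_index(drop=True),
        pd.DataFrame(features, columns=bands), chl[metrics].reset_index(drop=True),
    )


def combine(datasets: list) -> PairedDataset:
    """Concatenate row-aligned datasets from several experiments."""
    if not datasets:
        raise ParameterError("nothing to combine")
    scale = datasets[0].scale
    if any(d.scale != scale for d in datasets):
        raise ParameterError("cannot combine datasets at different scales")
    return PairedDataset(
        scale,
        pd.concat([d.ids for d in datasets], ignore_index=True),
        pd.concat([d.features for d in datasets], ignore_index=True),
        pd.concat([d.targets for d in datasets], ignore_index=True),
    )


def split(ds: PairedDataset, spec: SplitSpec) -> tuple[PairedDataset, PairedDataset]:
    """Disjoint, exhaustive train/test partition of a dataset."""
    if ds.n < 2:
        raise ParameterError("need at least 2 rows to split")
    if spec.strategy == "by_experiment":
        is_train = (ds.ids["experiment_id"] == spec.train_experiment).to_numpy()
        if is_train.all() or not is_train.any():
            raise ParameterError("by_experiment split needs both experiments present")
        return ds.take(np.flatnonzero(is_train)), ds.take(np.flatnonzero(~is_train))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(ds.n)
    n_train = int(np.floor(spec.train_fraction * ds.n))
    return ds.take(np.sort(perm[:n_train])), ds.take(np.sort(perm[n_train:]))


def standardize(
    train_features: pd.DataFrame | np.ndarray,
    test_features: pd.DataFrame | np.ndarray | None = None,
):
    """Center/scale features by the training set's mean and sd.

    The scaler is fit on the training features only and applied to both,
    so no test-set information leaks into the scaling.  Constant training
    features map to zero (warned).  Returns (train_scaled, test_scaled,
    fitted scaler); test_scaled is None when no test set is given.
    """
    Xtr = np.asarray(train_features, dtype=float)
    if Xtr.ndim != 2 or Xtr.shape[0] < 2:
        raise ParameterError("need a 2-D training matrix with more than one row")
    scaler = StandardScaler().fit(Xtr)
    n_const = int(np.sum(scaler.var_ == 0))
    if n_const:
        logger.warning("standardize: %d constant feature(s) mapped to 0", n_const)
    out_tr = scaler.transform(Xtr)
    out_te = None
    if test_features is not None:
        out_te = scaler.transform(np.asarray(test_features, dtype=float))
    return out_tr, out_te, scaler


def write_manifest(path, train: PairedDataset, test: PairedDataset) -> None:
    """Partition manifest (row id + role) so a run is reproducible from disk."""
    rows = pd.concat([
        pd.DataFrame({"row_id": train.ids["row_id"], "role": "train"}),
        pd.DataFrame({"row_id": test.ids["row_id"], "role": "test"}),
    ], ignore_index=True)
    rows.to_csv(path, index=False)
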