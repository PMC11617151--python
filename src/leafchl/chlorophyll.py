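"""Chlorophyll laboratory-data handling.

Plate-reader chlorophyll concentrations (ug/mL in the methanol extract)
are converted to two bases: per unit leaf area (ug/cm^2, the natural
basis for comparison to reflectance) and per unit dry tissue mass
(mg/g).  Each tissue sample is two 0.283 cm^2 leaf-punch disks, i.e.
0.566 cm^2 of leaf.  The module also provides per-group interquartile
outlier filtering and paired-sample repeatability statistics.

Records are carried as a pandas DataFrame with the column dictionary in
:data:`RECORD_COLUMNS`; derived metric columns are the six chlorophyll
metrics in :data:`CHL_METRICS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "LabConstants",
    "CHL_METRICS",
    "RECORD_COLUMNS",
    "to_area_basis",
    "to_mass_basis",
    "derive_metrics",
    "remove_outliers",
    "repeatability",
]


@dataclass(frozen=True)
class LabConstants:
    """Laboratory constants of the extraction protocol."""

    disk_area_cm2: float = 0.283      # one leaf punch
    extract_volume_ml: float = 1.0    # assay extract volume (config field)
    drying_temp_c: float = 22.2       # metadata only

    @property
    def sample_area_cm2(self) -> float:
        # two disks per tissue sample
        return 2.0 * self.disk_area_cm2


#: The six chlorophyll metrics: Chl a, Chl b, and Chl a+b on each basis.
CHL_METRICS = (
    "chl_a_area", "chl_b_area", "chl_ab_area",   # ug / cm^2
    "chl_a_mass", "chl_b_mass", "chl_ab_mass",   # mg / g
)

#: Input column dictionary for a chlorophyll record table.
RECORD_COLUMNS = {
    "sample_id": "unique tissue-sample identifier",
    "leaf_id": "leaf the sample was punched from",
    "plot_id": "field plot",
    "entry_id": "genotype (entry)",
    "collection_id": "data-collection event",
    "experiment_id": "field experiment (e.g. exp1 = 2019-2020)",
    "conc_a": "chlorophyll a concentration in extract, ug/mL",
    "conc_b": "chlorophyll b concentration in extract, ug/mL",
    "extract_volume": "extract volume, mL",
    "tissue_mass": "dry tissue mass of the sample, mg",
}


def to_area_basis(conc: float, extract_volume: float, area: float) -> float:
    """Pigment mass in the extract divided by sampled leaf area -> ug/cm^2."""
    conc = np.asarray(conc, dtype=float)
    if np.any(np.asarray(area) <= 0) or np.any(np.asarray(extract_volume) <= 0):
        raise ParameterError("area and extract volume must be positive")
    return conc * extract_volume / area


def to_mass_basis(conc: float, extract_volume: float, tissue_mass: float) -> float:
    """Pigment mass (ug) over dry tissue mass (mg) -> mg/g (numerically ug/mg)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(np.asarray(tissue_mass) <= 0):
        raise ParameterError("tissue mass must be positive")
    if np.any(np.asarray(extract_volume) <= 0):
        raise ParameterError("extract volume must be positive")
    return conc * extract_volume / tissue_mass


def derive_metrics(records: pd.DataFrame, constants: LabConstants = LabConstants()) -> pd.DataFrame:
    """Append the six derived chlorophyll metric columns to a record table."""
    out = records.copy()
    vol = out["extract_volume"] if "extract_volume" in out else constants.extract_volume_ml
    area = constants.sample_area_cm2
    out["chl_a_area"] = to_area_basis(out["conc_a"], vol, area)
    out["chl_b_area"] = to_area_basis(out["conc_b"], vol, area)
    out["chl_ab_area"] = out["chl_a_area"] + out["chl_b_area"]
    out["chl_a_mass"] = to_mass_basis(out["conc_a"], vol, out["tissue_mass"])
    out["chl_b_mass"] = to_mass_basis(out["conc_b"], vol, out["tissue_mass"])
    out["chl_ab_mass"] = out["chl_a_mass"] + out["chl_b_mass"]
    return out


def remove_outliers(
    records: pd.DataFrame,
    metric: str,
    k: float = 1.5,
    group_cols: tuple = ("experiment_id", "collection_id"),
    min_group: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interquartile-fence outlier filter within (experiment, collection) groups.

    Records with ``metric`` outside [Q1 - k*IQR, Q3 + k*IQR] of their group
    are removed.  Groups smaller than ``min_group`` pass through untouched
    with a logged warning.  Returns (filtered records, removal log).
    """
    if metric not in records.columns:
        raise ParameterError(f"metric column {metric!r} not in records")
    if records.empty:
        return records.copy(), pd.DataFrame(columns=[*records.columns, "reason"])
    keep_masks, removals = [], []
    for key, grp in records.groupby(list(group_cols), sort=False):
        if len(grp) < min_group:
            logger.warning("outlier filter: group %s has %d < %d records, passed through",
                           key, len(grp), min_group)
            keep_masks.append(pd.Series(True, index=grp.index))
            continue
        q1, q3 = grp[metric].quantile([0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        ok = grp[metric].between(lo, hi)
        keep_masks.append(ok)
        for idx in grp.index[~ok]:
            removals.append({
                **records.loc[idx].to_dict(),
                "reason": f"{metric}={records.loc[idx, metric]:.4g} outside "
                          f"[{lo:.4g}, {hi:.4g}] in group {key}",
            })
    keep = pd.concat(keep_masks).reindex(records.index, fill_value=True)
    log = pd.DataFrame(removals)
    if len(log):
        logger.info("outlier filter removed %d of %d records on %s", len(log), len(records), metric)
    return records[keep].copy(), log


def repeatability(pairs: np.ndarray) -> dict:
    """Paired-sample repeatability: r^2 of sample2 on sample1 and RMSD%.

    RMSD% is the root mean squared difference between paired values,
    normalized by the grand mean of all paired values, times 100.

    Parameters
    ----------
    pairs : array-like of shape (n, 2)
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ParameterError("need at least 3 finite (sample1, sample2) pairs")
    if not np.all(np.isfinite(pairs)):
        raise ParameterError("pairs must be finite")
    x, y = pairs[:, 0], pairs[:, 1]
    rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
    grand_mean = float(np.mean(pairs))
    rmsd_pct = 100.0 * rmsd / grand_mean if grand_mean != 0 else np.nan
    if np.var(x) == 0:
        logger.warning("repeatability: zero variance in sample1, r^2 undefined")
        return {"r2": np.nan, "rmsd_pct": rmsd_pct, "n": len(x)}
    res = stats.linregress(x, y)
    return {"r2": float(res.rvalue**2), "rmsd_pct": rmsd_pct, "n": len(x)}
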