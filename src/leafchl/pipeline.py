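"""End-to-end orchestration of the analysis workflow.

Stages: simulate (or load) -> spectral transforms -> index table ->
dataset assembly and split -> estimator evaluation + ANOVA/Tukey ->
clustered permutation importance -> report.  Each stage writes its
artifacts as CSV/JSON into the run directory and appends a structured
log entry with input/output row counts; the run manifest (config,
seed, package versions) makes any run reproducible from disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import SplitSpec, aggregate, combine, split, write_manifest
from .chlorophyll import CHL_METRICS
from .config import PipelineConfig
from .errors import StageError
from .evaluation import (
    ESTIMATOR_IDS,
    SPECTRAL_SETS,
    anova_tukey,
    run_realizations,
)
from .grid import CANONICAL_GRID, SpectralGrid
from .importance import ClusteredPermutationImportance, linkage_to_newick
from .indices import compute_all
from .simulate import (
    DESIGN_2019_2020,
    DESIGN_2021_2022,
    GEN_EXP1,
    GEN_EXP2,
    generate_trial,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _subsample_columns(features: pd.DataFrame, step: int) -> pd.DataFrame:
    if step <= 1:
        return features
    return features.iloc[:, ::step]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory. Any stage failure aborts
    with a :class:`StageError` naming the stage, after writing an error
    record to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    def log_stage(name, **counts):
        entry = {"stage": name, "time": time.time(), **counts}
        stage_log.append(entry)
        logger.info("stage %s: %s", name, counts)

    def fail(stage, exc):
        record = {"stage": stage, "error": str(exc)}
        (out / "error.json").write_text(json.dumps(record))
        raise StageError(stage, str(exc)) from exc

    rng_seed = config.seed

    # --- simulate / load -------------------------------------------------
    try:
        if config.simulate:
            def thin(design):
                n_coll = max(1, round(design.n_collections * config.generator.scale_collections))
                target = design.target_plot_n
                if target is not None:
                    target = max(1, round(target * n_coll / design.n_collections))
                return dataclasses.replace(design, n_collections=n_coll,
                                           target_plot_n=target)

            gen1 = dataclasses.replace(
                GEN_EXP1, spectral_noise_sd=config.generator.spectral_noise_sd,
                paired_rmsd_pct=config.generator.paired_rmsd_pct)
            gen2 = dataclasses.replace(
                GEN_EXP2, spectral_noise_sd=config.generator.spectral_noise_sd,
                paired_rmsd_pct=config.generator.paired_rmsd_pct)
            trials = [
                generate_trial(thin(DESIGN_2019_2020), gen1, seed=rng_seed),
                generate_trial(thin(DESIGN_2021_2022), gen2, seed=rng_seed + 1),
            ]
            records = pd.concat([t.records for t in trials], ignore_index=True)
            leaf_meta = pd.concat([t.leaf_meta for t in trials], ignore_index=True)
            reflectance = np.vstack([t.reflectance for t in trials])
            records.to_csv(out / "chlorophyll_records.csv", index=False)
            leaf_meta.to_csv(out / "leaf_meta.csv", index=False)
        else:
            from .io import read_wide_csv, spectra_to_matrix

            spectra = read_wide_csv(config.spectra_csv)
            reflectance = spectra_to_matrix(spectra)
            records = pd.read_csv(config.chlorophyll_csv)
            leaf_meta = records.drop_duplicates("leaf_id")[
                ["leaf_id", "plot_id", "entry_id", "collection_id", "experiment_id"]
            ].reset_index(drop=True)
        log_stage("simulate", n_records=len(records), n_spectra=len(reflectance))
    except StageError:
        raise
    except Exception as exc:
        fail("simulate", exc)

    # --- indices ----------------------------------------------------------
    try:
        svi = compute_all(reflectance)
        svi.insert(0, "leaf_id", leaf_meta["leaf_id"].to_numpy())
        svi.to_csv(out / "index_values.csv", index=False)
        svi = svi.drop(columns="leaf_id")
        log_stage("indices", n_rows=len(svi), n_indices=svi.shape[1])
    except Exception as exc:
        fail("indices", exc)

    # --- assemble ---------------------------------------------------------
    try:
        ds = aggregate(records, leaf_meta, reflectance, scale=config.scale)
        spec = SplitSpec(strategy=config.split.strategy,
                         train_fraction=config.split.train_fraction,
                         seed=rng_seed,
                         train_experiment=config.split.train_experiment)
        train, test = split(ds, spec)
        write_manifest(out / "partition_manifest.csv", train, test)
        log_stage("assemble", n=ds.n, n_train=train.n, n_test=test.n)
    except Exception as exc:
        fail("assemble", exc)

    # --- evaluate ---------------------------------------------------------
    try:
        ev = config.evaluate
        estimators = tuple(ev.estimators or ESTIMATOR_IDS)
        spectral_sets = tuple(ev.spectral_sets or SPECTRAL_SETS)
        metrics = tuple(ev.chl_metrics or CHL_METRICS)
        tr, te = train, test
        svi_tr = svi_te = None
        if ev.band_step_nm > 1:
            tr = train.with_features(_subsample_columns(train.features, ev.band_step_nm))
            te = test.with_features(_subsample_columns(test.features, ev.band_step_nm))
            if "svi" in spectral_sets:
                svi_tr = compute_all(train.features.to_numpy())
                svi_te = compute_all(test.features.to_numpy())
        results = run_realizations(
            tr, te, estimators=estimators, spectral_sets=spectral_sets,
            chl_metrics=metrics, cv_splits=ev.cv_splits, cv_repeats=ev.cv_repeats,
            seed=rng_seed, svi_train=svi_tr, svi_test=svi_te,
        )
        results_out = results.copy()
        results_out["hyperparameters"] = results_out["hyperparameters"].map(json.dumps)
        results_out.to_csv(out / "evaluation_results.csv", index=False)
        test_rows = results[results["phase"] == "test"]
        factors = tuple(f for f in ("estimator", "spectral_set", "chl_metric")
                        if test_rows[f].nunique() >= 2)
        if factors:
            stats = anova_tukey(test_rows, factors=factors)
            stats["anova"].to_csv(out / "anova.csv", index=False)
            for factor, table in stats["tukey"].items():
                table.to_csv(out / f"tukey_{factor}.csv", index=False)
        else:
            pd.DataFrame(columns=["factor", "df", "F", "p"]).to_csv(
                out / "anova.csv", index=False)
        log_stage("evaluate", n_rows=len(results))
    except Exception as exc:
        fail("evaluate", exc)

    # --- importance -------------------------------------------------------
    try:
        imp_cfg = config.importance
        if imp_cfg.features == "svi":
            feats = compute_all(train.features.to_numpy())
            feats = pd.concat([feats, compute_all(test.features.to_numpy())],
                              ignore_index=True)
            names = list(feats.columns)
            X = feats.to_numpy()
            X = np.where(np.isfinite(X), X, np.nanmean(X, axis=0))
        else:
            feats = pd.concat([train.features, test.features], ignore_index=True)
            feats = _subsample_columns(feats, imp_cfg.band_step_nm)
            names = list(feats.columns)
            X = feats.to_numpy()
        y = pd.concat([train.targets, test.targets], ignore_index=True)[
            "chl_ab_area"].to_numpy()
        cpi = ClusteredPermutationImportance(
            cutoff=imp_cfg.cutoff, n_clusters=imp_cfg.n_clusters,
            n_iterations=imp_cfg.n_iterations, random_state=rng_seed,
        ).fit(X, y, feature_names=names)
        cpi.importances_.to_csv(out / "importance_samples.csv", index=False)
        cpi.summary_.to_csv(out / "importance_summary.csv", index=False)
        pd.DataFrame(cpi.linkage_, columns=["left", "right", "height", "count"]) \
            .to_csv(out / "linkage.csv", index=False)
        kept = [names[i] for i in cpi.kept_features_]
        (out / "dendrogram.nwk").write_text(linkage_to_newick(cpi.linkage_, kept))
        log_stage("importance", n_clusters=cpi.clusters_.n_clusters,
                  n_iterations=imp_cfg.n_iterations)
    except Exception as exc:
        fail("importance", exc)

    # --- report / manifest -------------------------------------------------
    try:
        log_stage("report", n_artifacts=len(list(out.iterdir())) + 1)
        cfg_json = config.model_dump_json()
        manifest = {
            "version": __version__,
            "seed": rng_seed,
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "stages": stage_log,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as exc:
        fail("report", exc)
    return out
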