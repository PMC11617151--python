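"""Synthetic cotton chlorophyll trials.

No field accessions ship with this package, so every pipeline stage is
exercised on synthetic experiments that emulate the two study designs:

* ``exp1`` (2019-2020 style): 6 entries x 2 planting dates x 3 irrigation
  levels x 3 replicates = 108 plots, 9 collections, 3 leaves per plot,
  2 tissue samples per leaf (972 plot-collection units, 2916 leaves,
  5832 samples).
* ``exp2`` (2021-2022 style): 379 entries x 2 replicates = 758 plots,
  6 collections, 1 leaf per plot, 1 sample per leaf, randomly thinned to
  572 plot-collection units (field attrition).

Leaf chlorophyll marginals are log-normal, parameterized by the
experiment's median/IQR (positivity plus right skew); design factors
act as multiplicative (log-additive) effects whose variances sum to the
marginal log-variance.  Reflectance spectra come from a phenomenological
forward model — Gaussian pigment absorptions in blue and red, a logistic
red edge whose center shifts to longer wavelengths with chlorophyll, a
NIR plateau, and water absorptions in the SWIR — not a radiative-transfer
model; it is transparent, fast, and monotone in the ways the analysis
needs (red-band reflectance falls and the red edge moves right as
chlorophyll rises).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chlorophyll import LabConstants, derive_metrics
from .errors import ParameterError
from .grid import CANONICAL_GRID, SpectralGrid
from .spectra import Spectrum

__all__ = [
    "TrialDesign",
    "GeneratorParams",
    "ForwardModelParams",
    "Trial",
    "DESIGN_2019_2020",
    "DESIGN_2021_2022",
    "GEN_EXP1",
    "GEN_EXP2",
    "generate_spectrum",
    "generate_spectra",
    "generate_trial",
    "make_single_index_truth",
    "make_benchmark_suite",
]


@dataclass(frozen=True)
class TrialDesign:
    """Structural constants of one field experiment."""

    experiment_id: str
    n_entries: int
    n_planting_dates: int
    n_irrigation_levels: int
    n_replicates: int
    n_collections: int
    leaves_per_plot: int
    samples_per_leaf: int
    target_plot_n: int | None = None  # post-attrition plot-collection count

    def __post_init__(self):
        for name in ("n_entries", "n_planting_dates", "n_irrigation_levels",
                     "n_replicates", "n_collections", "leaves_per_plot", "samples_per_leaf"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if (self.target_plot_n is not None
                and self.target_plot_n > self.n_plots * self.n_collections):
            raise ParameterError("target_plot_n exceeds designed unit count")

    @property
    def n_plots(self) -> int:
        return (self.n_entries * self.n_planting_dates
                * self.n_irrigation_levels * self.n_replicates)

    @property
    def n_units(self) -> int:
        """Plot-collection units after any attrition."""
        if self.target_plot_n is not None:
            return self.target_plot_n
        return self.n_plots * self.n_collections


DESIGN_2019_2020 = TrialDesign("exp1", n_entries=6, n_planting_dates=2,
                               n_irrigation_levels=3, n_replicates=3,
                               n_collections=9, leaves_per_plot=3, samples_per_leaf=2)

DESIGN_2021_2022 = TrialDesign("exp2", n_entries=379, n_planting_dates=1,
                               n_irrigation_levels=1, n_replicates=2,
                               n_collections=6, leaves_per_plot=1, samples_per_leaf=1,
                               target_plot_n=572)


@dataclass(frozen=True)
class GeneratorParams:
    """Distributional parameters of one synthetic experiment.

    ``chl_ab_iqr`` is the target interquartile range of area-basis
    Chl a+b (ug/cm^2); the log-normal median defaults to the geometric
    mean of the quartiles.  ``paired_rmsd_pct`` is the target
    root-mean-square difference between paired tissue samples, as a
    percent of the mean; the common per-sample assay error is set from
    it, plus small pigment-specific errors (Chl b noisier than Chl a,
    as in plate-reader practice).
    """

    chl_ab_iqr: tuple = (32.3, 40.4)
    chl_ab_median: float | None = None
    ab_ratio: float = 5.5                 # Chl a : Chl b
    ab_ratio_sd_log: float = 0.08
    paired_rmsd_pct: float = 9.0
    pigment_specific_sd: tuple = (0.02, 0.10)  # extra rel. error for (a, b)
    spectral_noise_sd: float = 0.004
    water_range: tuple = (0.8, 1.2)       # relative leaf water content
    tissue_mass_mean_mg: float = 3.2
    tissue_mass_sd_mg: float = 0.25
    # variance shares of the log-chlorophyll design effects; must sum to 1
    effect_shares: dict = field(default_factory=lambda: {
        "entry": 0.20, "date": 0.05, "irrigation": 0.20,
        "plot": 0.10, "collection": 0.25, "leaf": 0.20,
    })

    def __post_init__(self):
        if not self.chl_ab_iqr[0] < self.chl_ab_iqr[1]:
            raise ParameterError("IQR bounds must be ordered")
        if self.paired_rmsd_pct < 0:
            raise ParameterError("paired RMSD target must be >= 0")
        if abs(sum(self.effect_shares.values()) - 1.0) > 1e-9:
            raise ParameterError("effect variance shares must sum to 1")

    @property
    def log_median(self) -> float:
        m = self.chl_ab_median
        if m is None:
            m = float(np.sqrt(self.chl_ab_iqr[0] * self.chl_ab_iqr[1]))
        return float(np.log(m))

    @property
    def log_sd(self) -> float:
        # quartiles of a log-normal sit at exp(mu +/- 0.6745 sigma)
        q1, q3 = self.chl_ab_iqr
        return float(np.log(q3 / q1) / (2 * 0.674489750196082))


GEN_EXP1 = GeneratorParams(chl_ab_iqr=(32.3, 40.4), ab_ratio=5.5)
GEN_EXP2 = GeneratorParams(chl_ab_iqr=(40.7, 63.6), ab_ratio=3.6)


@dataclass(frozen=True)
class ForwardModelParams:
    """Phenomenological leaf reflectance model parameters.

    Pigment absorptions are Gaussians in absorbance units per ug/cm^2,
    so the red trough saturates at moderate chlorophyll (as real leaves
    do), while the logistic red-edge center keeps shifting to longer
    wavelengths with chlorophyll — the red edge stays the informative
    region across the whole chlorophyll range.
    """

    vis_baseline: float = 0.36
    nir_plateau: float = 0.48
    uv_depth: float = 0.35               # baseline roll-off below ~400 nm
    # (center nm, width nm, pigment, absorbance per ug/cm^2)
    pigment_features: tuple = (
        (430.0, 22.0, "a", 0.050),
        (460.0, 24.0, "b", 0.065),
        (645.0, 26.0, "b", 0.050),
        (662.0, 26.0, "a", 0.080),
    )
    red_edge_shift: float = 35.0         # nm of asymptotic red-edge shift
    red_edge_halfsat: float = 30.0       # ug/cm^2 at half shift
    red_edge_base: float = 700.0
    red_edge_slope: float = 7.0          # logistic width, nm
    # (center nm, width nm, absorbance at unit relative water content)
    water_features: tuple = (
        (970.0, 25.0, 0.03),
        (1200.0, 30.0, 0.06),
        (1450.0, 35.0, 0.55),
        (1940.0, 45.0, 0.95),
        (2500.0, 120.0, 0.40),
    )
    swir_dry_slope: float = 1.2e-4       # per nm decline beyond 1300 nm

    def red_edge_center(self, chl_ab: np.ndarray) -> np.ndarray:
        chl_ab = np.asarray(chl_ab, dtype=float)
        return self.red_edge_base + self.red_edge_shift * chl_ab / (chl_ab + self.red_edge_halfsat)


FORWARD_DEFAULT = ForwardModelParams()


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((wl - center) ** 2) / (2.0 * width**2))


def generate_spectra(
    chl_a_area,
    chl_b_area,
    water=1.0,
    params: ForwardModelParams = FORWARD_DEFAULT,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    grid: SpectralGrid = CANONICAL_GRID,
) -> np.ndarray:
    """Forward-model reflectance for arrays of pigment values -> (n, n_bands)."""
    chl_a = np.atleast_1d(np.asarray(chl_a_area, dtype=float))
    chl_b = np.atleast_1d(np.asarray(chl_b_area, dtype=float))
    water = np.broadcast_to(np.atleast_1d(np.asarray(water, dtype=float)), chl_a.shape)
    if np.any(chl_a < 0) or np.any(chl_b < 0):
        raise ParameterError("pigment values must be >= 0")
    wl = grid.wavelengths.astype(float)

    absorb = np.zeros((chl_a.size, wl.size))
    for center, width, pigment, coeff in params.pigment_features:
        pig = chl_a if pigment == "a" else chl_b
        absorb += np.outer(pig, coeff * _gauss(wl, center, width))
    vis_base = params.vis_baseline * (1.0 - params.uv_depth * _gauss(wl, 350.0, 45.0))
    rho_vis = vis_base[None, :] * np.exp(-absorb)

    water_abs = np.zeros((chl_a.size, wl.size))
    for center, width, coeff in params.water_features:
        water_abs += np.outer(water, coeff * _gauss(wl, center, width))
    dry = 1.0 - params.swir_dry_slope * np.clip(wl - 1300.0, 0.0, None)
    rho_nir = params.nir_plateau * dry[None, :] * np.exp(-water_abs)

    center = params.red_edge_center(chl_a + chl_b)
    w = 1.0 / (1.0 + np.exp(-(wl[None, :] - center[:, None]) / params.red_edge_slope))
    rho = (1.0 - w) * rho_vis + w * rho_nir
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        rho = rho + rng.normal(0.0, noise_sd, rho.shape)
    return np.clip(rho, 1e-4, 0.99)


def generate_spectrum(
    chl_a_area: float,
    chl_b_area: float,
    water: float = 1.0,
    params: ForwardModelParams = FORWARD_DEFAULT,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Spectrum:
    """Single synthetic reflectance :class:`Spectrum` on the canonical grid."""
    rng = np.random.default_rng(seed)
    vals = generate_spectra(chl_a_area, chl_b_area, water, params, noise_sd, rng)[0]
    return Spectrum(values=vals, kind="reflectance",
                    meta={"chl_a_area": chl_a_area, "chl_b_area": chl_b_area})


@dataclass
class Trial:
    """One generated experiment: chlorophyll records plus leaf spectra."""

    design: TrialDesign
    records: pd.DataFrame          # one row per tissue sample, with metrics
    leaf_meta: pd.DataFrame        # one row per leaf (ids + latent values)
    reflectance: np.ndarray        # (n_leaves, n_bands), row-aligned to leaf_meta
    grid: SpectralGrid = CANONICAL_GRID


def generate_trial(
    design: TrialDesign,
    gparams: GeneratorParams = GEN_EXP1,
    fparams: ForwardModelParams = FORWARD_DEFAULT,
    seed: int | None = 0,
    constants: LabConstants = LabConstants(),
) -> Trial:
    """Generate a complete synthetic experiment.

    All randomness flows from one seed through independent child
    generators per stage (design effects, attrition, leaf noise,
    measurement error, spectra), so each stage is reproducible on its
    own and the output is byte-identical under a fixed seed.
    """
    root = np.random.SeedSequence(seed)
    rng_eff, rng_attr, rng_leaf, rng_meas, rng_spec = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    s = gparams.log_sd
    shares = gparams.effect_shares
    eff = {
        "entry": rng_eff.normal(0, s * np.sqrt(shares["entry"]), design.n_entries),
        "date": rng_eff.normal(0, s * np.sqrt(shares["date"]), design.n_planting_dates),
        "irrigation": rng_eff.normal(0, s * np.sqrt(shares["irrigation"]), design.n_irrigation_levels),
        "collection": rng_eff.normal(0, s * np.sqrt(shares["collection"]), design.n_collections),
    }
    # center each factor so the marginal stays log-normal(median, s)
    eff = {k: v - v.mean() for k, v in eff.items()}

    plots = pd.MultiIndex.from_product(
        [range(design.n_entries), range(design.n_planting_dates),
         range(design.n_irrigation_levels), range(design.n_replicates)],
        names=["entry", "date", "irrigation", "rep"],
    ).to_frame(index=False)
    plots["plot_id"] = [
        f"{design.experiment_id}-E{e:03d}D{d}I{i}R{r}"
        for e, d, i, r in plots[["entry", "date", "irrigation", "rep"]].to_numpy()
    ]
    plots["plot_eff"] = rng_eff.normal(0, s * np.sqrt(shares["plot"]), len(plots))

    units = plots.loc[plots.index.repeat(design.n_collections)].reset_index(drop=True)
    units["collection"] = np.tile(np.arange(design.n_collections), len(plots))
    if design.target_plot_n is not None:
        keep = rng_attr.choice(len(units), size=design.target_plot_n, replace=False)
        units = units.iloc[np.sort(keep)].reset_index(drop=True)

    n_leaves = len(units) * design.leaves_per_plot
    leaves = units.loc[units.index.repeat(design.leaves_per_plot)].reset_index(drop=True)
    leaves["leaf"] = np.tile(np.arange(design.leaves_per_plot), len(units))
    leaves["leaf_id"] = [
        f"{p}-C{c}-L{l}" for p, c, l in leaves[["plot_id", "collection", "leaf"]].to_numpy()
    ]
    log_chl = (
        gparams.log_median
        + eff["entry"][leaves["entry"]]
        + eff["date"][leaves["date"]]
        + eff["irrigation"][leaves["irrigation"]]
        + eff["collection"][leaves["collection"]]
        + leaves["plot_eff"].to_numpy()
        + rng_leaf.normal(0, s * np.sqrt(shares["leaf"]), n_leaves)
    )
    leaves["chl_ab_latent"] = np.exp(log_chl)
    ratio = np.exp(rng_leaf.normal(np.log(gparams.ab_ratio), gparams.ab_ratio_sd_log, n_leaves))
    leaves["chl_a_latent"] = leaves["chl_ab_latent"] * ratio / (1.0 + ratio)
    leaves["chl_b_latent"] = leaves["chl_ab_latent"] / (1.0 + ratio)
    leaves["water"] = rng_leaf.uniform(*gparams.water_range, n_leaves)

    # tissue samples: common assay error per sample plus pigment-specific error
    k = design.samples_per_leaf
    samples = leaves.loc[leaves.index.repeat(k)].reset_index(drop=True)
    samples["sample"] = np.tile(np.arange(k), n_leaves)
    samples["sample_id"] = [
        f"{lid}-S{j}" for lid, j in samples[["leaf_id", "sample"]].to_numpy()
    ]
    n_samp = len(samples)
    sigma_common = gparams.paired_rmsd_pct / 100.0 / np.sqrt(2.0)
    common = rng_meas.normal(0.0, sigma_common, n_samp)
    eps_a = rng_meas.normal(0.0, gparams.pigment_specific_sd[0], n_samp)
    eps_b = rng_meas.normal(0.0, gparams.pigment_specific_sd[1], n_samp)
    a_meas = samples["chl_a_latent"].to_numpy() * (1.0 + common) * (1.0 + eps_a)
    b_meas = samples["chl_b_latent"].to_numpy() * (1.0 + common) * (1.0 + eps_b)
    a_meas, b_meas = np.clip(a_meas, 0.0, None), np.clip(b_meas, 0.0, None)
    tissue_mass = np.clip(
        rng_meas.normal(gparams.tissue_mass_mean_mg, gparams.tissue_mass_sd_mg, n_samp),
        0.5, None,
    )
    records = pd.DataFrame({
        "sample_id": samples["sample_id"],
        "leaf_id": samples["leaf_id"],
        "plot_id": samples["plot_id"],
        "entry_id": [f"{design.experiment_id}-G{e:03d}" for e in samples["entry"]],
        "collection_id": samples["collection"],
        "experiment_id": design.experiment_id,
        "conc_a": a_meas * constants.sample_area_cm2 / constants.extract_volume_ml,
        "conc_b": b_meas * constants.sample_area_cm2 / constants.extract_volume_ml,
        "extract_volume": constants.extract_volume_ml,
        "tissue_mass": tissue_mass,
    })
    records = derive_metrics(records, constants)

    X = generate_spectra(
        leaves["chl_a_latent"].to_numpy(), leaves["chl_b_latent"].to_numpy(),
        leaves["water"].to_numpy(), fparams, gparams.spectral_noise_sd, rng_spec,
    )
    leaf_meta = leaves[[
        "leaf_id", "plot_id", "collection", "entry",
        "chl_ab_latent", "chl_a_latent", "chl_b_latent", "water",
    ]].rename(columns={"collection": "collection_id"}).copy()
    leaf_meta["entry_id"] = [f"{design.experiment_id}-G{e:03d}" for e in leaf_meta.pop("entry")]
    leaf_meta["experiment_id"] = design.experiment_id
    return Trial(design=design, records=records, leaf_meta=leaf_meta, reflectance=X)


def make_single_index_truth(
    X: np.ndarray, index_name: str, slope: float = 2.0, intercept: float = 30.0
) -> np.ndarray:
    """Target that is an exact linear function of one vegetation index.

    Used for recovery checks: a single-index linear model on the
    generative index must fit this target perfectly.
    """
    from .indices import compute_index, registry_lookup

    vals = compute_index(registry_lookup(index_name), X)
    return slope * np.asarray(vals) + intercept


def make_benchmark_suite(seed: int = 0) -> dict:
    """Small fixed fixtures for unit and oracle tests."""
    rng = np.random.default_rng(seed)

    hull_grid = SpectralGrid(350, 354, 1)
    hull_toy = Spectrum(
        values=np.array([1.0, 0.9, 0.95, 0.4, 0.8]), kind="reflectance", grid=hull_grid
    )

    wl = CANONICAL_GRID.wavelengths.astype(float)
    logistic = 0.05 + 0.45 / (1.0 + np.exp(-(wl - 720.0) / 8.0))
    red_edge = Spectrum(values=logistic, kind="reflectance")

    ols_points = np.array([(1.0, 2.0), (2.0, 3.0), (3.0, 5.0), (4.0, 6.0)])

    n, per_block = 300, 5
    base = rng.normal(size=(n, 3))
    blocks = []
    for b in range(3):
        blocks.append(base[:, [b]] + 0.05 * rng.normal(size=(n, per_block)))
    features = np.hstack(blocks)
    target = features[:, 0].copy()  # signal lives in block 0

    return {
        "hull_toy": hull_toy,
        "red_edge_spectrum": red_edge,
        "ols_points": ols_points,
        "block_features": features,
        "block_target": target,
        "block_labels": np.repeat(np.arange(3), per_block),
    }
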