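"""Synthetic input bundles with known ground truth.

The generator emulates the *structure* of the global source datasets the
pipeline consumes — spatially autocorrelated continuous fields, an
uncertainty layer correlated with its mean, categorical land-cover layers
drawn by quantile-thresholding smoothed latent fields (so they are
spatially clumped and mutually exclusive), clustered fire counts, and
nested fine / mid / coarse grid resolutions — without mimicking the
geography of any real product.

Because the fine layers are generated first, the exact per-coarse-cell
availability fraction implied by them is known; it is recorded in
``SyntheticBundle.truth`` via an independent block-arithmetic path
(reshape-based counting with spherical band weights), so the resampling
cascade can be validated against it exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import geotiff
from .forest_potential import CLOSED_FOREST, NONWOODY, OPEN_FOREST
from .raster_core import Grid, GridGeometry, GridTransform

# slope / landform category codes used by the water-quality scenario
SLOPE_FLAT, SLOPE_MODERATE, SLOPE_STEEP = 1, 2, 3
LANDFORM_UPLAND, LANDFORM_FLOODPLAIN = 1, 2

_EXCLUSIVE_FRACTIONS = (
    "forest_fraction",
    "water_fraction",
    "bare_fraction",
    "ice_fraction",
    "cropland_fraction",
    "builtup_fraction",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    The defaults describe a moderately forested temperate 2 x 2 degree
    domain: about half the land could carry closed forest, a third is
    already forested, croplands and settlements are clumped, and fires
    cluster in a few flammable patches.  ``fine_factor`` and
    ``mid_factor`` are cells per coarse-cell side (the 30 m / 500 m /
    1 km analogues); ``fine_factor`` must be a multiple of ``mid_factor``
    so the grids nest.
    """

    seed: int = 0
    west: float = 10.0
    south: float = 42.0
    width_deg: float = 2.0
    height_deg: float = 2.0
    n_coarse: int = 16
    fine_factor: int = 8
    mid_factor: int = 2
    spatial_correlation_length: float = 0.15  # degrees
    # continuous tree-cover evidence (%)
    mean_tree_cover: float = 55.0
    tree_cover_spread: float = 18.0
    sd_scale: float = 10.0
    # biomass classification fractions
    closed_fraction: float = 0.5
    open_fraction: float = 0.25
    # biomass-product uncertainty index
    walker_ui_scale: float = 1.2
    walker_ui_log_sd: float = 0.8
    # mutually exclusive fine land-cover fractions
    forest_fraction: float = 0.35
    cropland_fraction: float = 0.12
    water_fraction: float = 0.04
    builtup_fraction: float = 0.03
    bare_fraction: float = 0.03
    ice_fraction: float = 0.01
    # overlapping fine layers
    wetland_fraction: float = 0.05
    peatland_fraction: float = 0.03
    oilpalm_fraction: float = 0.02
    albedo_negative_fraction: float = 0.05
    # fires per mid pixel over the counting window
    fire_rate: float = 0.6
    # net sequestration flux, tCO2e / ha / yr (albedo-adjusted 30-yr mean)
    flux_mean: float = 11.0
    flux_sd: float = 3.0
    # people per coarse pixel, lognormal
    population_log_mean: float = 7.5
    population_log_sd: float = 1.2
    # one-degree forest loss / gain totals, lognormal spread
    loss_gain_log_sd: float = 0.8
    n_countries: int = 5

    def __post_init__(self) -> None:
        if self.fine_factor < 1 or self.mid_factor < 1:
            raise ValueError("nesting factors must be >= 1")
        if self.fine_factor % self.mid_factor:
            raise ValueError("fine_factor must be a multiple of mid_factor")
        for name in _EXCLUSIVE_FRACTIONS + (
            "wetland_fraction",
            "peatland_fraction",
            "oilpalm_fraction",
            "albedo_negative_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(getattr(self, n) for n in _EXCLUSIVE_FRACTIONS)
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"mutually exclusive land-cover fractions sum to {total:.3f} > 1"
            )
        if self.closed_fraction + self.open_fraction > 1.0 + 1e-12:
            raise ValueError("closed_fraction + open_fraction must not exceed 1")


@dataclass
class SyntheticBundle:
    """A complete, internally consistent synthetic input bundle."""

    config: SyntheticConfig
    # coarse evidence layers
    tree_cover_mean: Grid
    tree_cover_sd: Grid
    biomass_class: Grid
    walker_ui: Grid
    # mid / fine screening inputs
    fire_count: Grid
    cropland_agreement: Grid
    oil_palm: Grid
    # fine exclusion layers
    existing_forest: Grid
    water: Grid
    bare: Grid
    ice: Grid
    builtup: Grid
    wetland: Grid
    peatland: Grid
    albedo_negative: Grid
    # sensitivity-variant alternatives
    existing_forest_alt: Grid
    cropland_single: Grid
    # accounting overlays
    flux: Grid
    population: Grid
    forest_loss: dict[tuple[int, int], float]
    forest_gain: dict[tuple[int, int], float]
    # scenario inputs
    scenario_masks: dict[str, Grid]
    slope_class: Grid
    landform: Grid
    forest_cover_coarse: Grid
    # generator ground truth (independent block arithmetic)
    truth: dict[str, np.ndarray]

    def geometries(self) -> dict[str, GridGeometry]:
        return {
            "coarse": self.tree_cover_mean.geometry,
            "mid": self.fire_count.geometry,
            "fine": self.existing_forest.geometry,
        }


def _geometry(cfg: SyntheticConfig, cells_per_side: int) -> GridGeometry:
    n = cfg.n_coarse * cells_per_side
    return GridGeometry(
        GridTransform(
            origin_lon=cfg.west,
            origin_lat=cfg.south + cfg.height_deg,
            px_width=cfg.width_deg / n,
            px_height=cfg.height_deg / n,
        ),
        (n, n),
    )


def _latent(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Standardized Gaussian random field with correlation length sigma_px."""
    z = rng.standard_normal(shape)
    if sigma_px > 0:
        z = gaussian_filter(z, sigma_px, mode="reflect")
    s = z.std()
    if s > 0:
        z = (z - z.mean()) / s
    return z


def _quantile_partition(
    scores: dict[str, np.ndarray], fractions: dict[str, float], shape: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Assign each cell to at most one category, matching target fractions.

    Categories claim cells greedily in a fixed order: each takes its
    ``round(fraction * n_total)`` highest-scoring cells among those still
    unclaimed, so the realized global fractions are exact to one cell and
    the patches inherit the latent fields' spatial clumping.
    """
    n_total = shape[0] * shape[1]
    unclaimed = np.ones(n_total, dtype=bool)
    out: dict[str, np.ndarray] = {}
    for name, frac in fractions.items():
        want = int(round(frac * n_total))
        mask = np.zeros(n_total, dtype=bool)
        if want > 0:
            s = scores[name].ravel().copy()
            s[~unclaimed] = -np.inf
            take = np.argsort(s, kind="stable")[::-1][:want]
            take = take[np.isfinite(s[take])]
            mask[take] = True
            unclaimed &= ~mask
        out[name] = mask.reshape(shape)
    return out


def _band_weights(geom: GridGeometry) -> np.ndarray:
    """Spherical band weight per row: sin(lat_top) - sin(lat_bottom)."""
    lat = np.radians(geom.lat_edges())
    return np.sin(lat[:-1]) - np.sin(lat[1:])


def _block_mean(values: np.ndarray, factor: int, row_weights: np.ndarray) -> np.ndarray:
    """Area-weighted mean over factor x factor blocks (independent of the
    resampling engine; used for ground truth)."""
    nr, nc = values.shape
    v = values.reshape(nr // factor, factor, nc // factor, factor)
    w = row_weights.reshape(nr // factor, factor)
    num = np.einsum("rack,ra->rc", v, w)
    den = factor * w.sum(axis=1)[:, None]
    return num / den


def _block_max(values: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = values.shape
    return values.reshape(nr // factor, factor, nc // factor, factor).max(axis=(1, 3))


def _center_pick(values: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour aggregation: the fine cell containing each coarse
    cell center (floor convention on the shared edge)."""
    idx = np.arange(values.shape[0] // factor) * factor + factor // 2
    jdx = np.arange(values.shape[1] // factor) * factor + factor // 2
    return values[np.ix_(idx, jdx)]


def generate_bundle(config: SyntheticConfig = SyntheticConfig()) -> SyntheticBundle:
    """Generate a full synthetic bundle; same config => bit-identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g_coarse = _geometry(cfg, 1)
    g_mid = _geometry(cfg, cfg.mid_factor)
    g_fine = _geometry(cfg, cfg.fine_factor)
    px_coarse = g_coarse.transform.px_width
    px_mid = g_mid.transform.px_width
    px_fine = g_fine.transform.px_width
    corr = cfg.spatial_correlation_length

    def grid(values, geom, res_class, categorical=False, nodata=None):
        return Grid(values, geom.transform, nodata=nodata, res_class=res_class,
                    categorical=categorical)

    # --- coarse evidence layers -------------------------------------------
    z_tc = _latent(rng, g_coarse.shape, corr / px_coarse)
    tree_cover = np.clip(cfg.mean_tree_cover + cfg.tree_cover_spread * z_tc, 0.0, 100.0)
    z_sd = _latent(rng, g_coarse.shape, corr / px_coarse)
    # sd rises with the mean (heteroscedastic, like the source product)
    tree_sd = cfg.sd_scale * (0.3 + 0.7 * tree_cover / 100.0) * np.exp(0.3 * z_sd)

    z_cls = _latent(rng, g_coarse.shape, corr / px_coarse)
    class_score = 0.75 * z_tc + 0.66 * z_cls
    order = np.argsort(class_score.ravel(), kind="stable")[::-1]
    n_cells = class_score.size
    n_closed = int(round(cfg.closed_fraction * n_cells))
    n_open = int(round(cfg.open_fraction * n_cells))
    biomass = np.full(n_cells, NONWOODY, dtype=np.int16)
    biomass[order[:n_closed]] = CLOSED_FOREST
    biomass[order[n_closed : n_closed + n_open]] = OPEN_FOREST
    biomass = biomass.reshape(g_coarse.shape)

    z_ui = _latent(rng, g_coarse.shape, corr / px_coarse)
    walker_ui = cfg.walker_ui_scale * np.exp(
        cfg.walker_ui_log_sd * (0.87 * z_ui - 0.5 * z_tc)
    )

    # --- fire counts (clustered Poisson on the mid grid) ------------------
    z_fire = _latent(rng, g_mid.shape, 2 * corr / px_mid)
    intensity = cfg.fire_rate * np.exp(1.2 * z_fire - 0.72)
    fire = rng.poisson(intensity).astype(np.int32)

    # --- mutually exclusive fine land cover -------------------------------
    scores = {
        name: _latent(rng, g_fine.shape, corr / px_fine)
        for name in ("forest", "water", "bare", "ice", "cropland", "builtup")
    }
    # existing forest tracks forest potential so exclusions bite where the
    # mask is, as in real landscapes
    z_tc_fine = np.repeat(np.repeat(z_tc, cfg.fine_factor, 0), cfg.fine_factor, 1)
    scores["forest"] = 0.7 * scores["forest"] + 0.7 * z_tc_fine
    cats = _quantile_partition(
        scores,
        {
            "forest": cfg.forest_fraction,
            "water": cfg.water_fraction,
            "bare": cfg.bare_fraction,
            "ice": cfg.ice_fraction,
            "cropland": cfg.cropland_fraction,
            "builtup": cfg.builtup_fraction,
        },
        g_fine.shape,
    )

    # cropland agreement count 0..6: >=3 exactly on cropland cells
    agree = np.zeros(g_fine.shape, dtype=np.int16)
    n_crop = int(cats["cropland"].sum())
    agree[cats["cropland"]] = 3 + rng.binomial(3, 0.6, size=n_crop)
    off = ~cats["cropland"]
    agree[off] = rng.binomial(2, 0.05, size=int(off.sum()))

    def overlay(fraction: float, sigma_scale: float = 1.0) -> np.ndarray:
        z = _latent(rng, g_fine.shape, sigma_scale * corr / px_fine)
        if fraction <= 0:
            return np.zeros(g_fine.shape, dtype=bool)
        thr = np.quantile(z, 1.0 - fraction)
        return z > thr

    oil_palm = overlay(cfg.oilpalm_fraction)
    wetland = overlay(cfg.wetland_fraction)
    peatland = overlay(cfg.peatland_fraction)
    albedo_neg = overlay(cfg.albedo_negative_fraction, sigma_scale=2.0)

    # sensitivity-variant alternatives: same landscapes, perturbed edges
    z_alt = _latent(rng, g_fine.shape, corr / px_fine)
    alt_forest_score = scores["forest"] + 0.25 * z_alt
    n_forest = int(cats["forest"].sum())
    alt_forest = np.zeros(g_fine.shape, dtype=bool)
    if n_forest:
        take = np.argsort(alt_forest_score.ravel(), kind="stable")[::-1][:n_forest]
        alt_forest.ravel()[take] = True
    z_alt2 = _latent(rng, g_fine.shape, corr / px_fine)
    single_crop_score = scores["cropland"] + 0.25 * z_alt2
    single_crop = np.zeros(g_fine.shape, dtype=bool)
    if n_crop:
        take = np.argsort(single_crop_score.ravel(), kind="stable")[::-1][:n_crop]
        single_crop.ravel()[take] = True

    # --- accounting overlays ----------------------------------------------
    fine_w = _band_weights(g_fine)
    albedo_frac_coarse = _block_mean(albedo_neg.astype(float), cfg.fine_factor, fine_w)
    z_flux = _latent(rng, g_coarse.shape, corr / px_coarse)
    flux = cfg.flux_mean + cfg.flux_sd * z_flux - 14.0 * albedo_frac_coarse
    z_pop = _latent(rng, g_coarse.shape, corr / px_coarse)
    population = np.exp(cfg.population_log_mean + cfg.population_log_sd * z_pop)

    loss: dict[tuple[int, int], float] = {}
    gain: dict[tuple[int, int], float] = {}
    lat0 = int(np.floor(cfg.south))
    lon0 = int(np.floor(cfg.west))
    for la in range(lat0, int(np.ceil(cfg.south + cfg.height_deg))):
        for lo in range(lon0, int(np.ceil(cfg.west + cfg.width_deg))):
            loss[(la, lo)] = float(np.exp(rng.normal(0.0, cfg.loss_gain_log_sd)))
            gain[(la, lo)] = float(np.exp(rng.normal(0.0, cfg.loss_gain_log_sd)))

    # --- scenario inputs ---------------------------------------------------
    # blocky "countries" constant within coarse cells so country-attribute
    # masks commute with the cascade
    country_scores = np.stack(
        [_latent(rng, g_coarse.shape, 4 * corr / px_coarse) for _ in range(cfg.n_countries)]
    )
    country_id = np.argmax(country_scores, axis=0)

    def country_mask(p_yes: float) -> np.ndarray:
        yes = rng.random(cfg.n_countries) < p_yes
        coarse_mask = yes[country_id]
        return np.repeat(np.repeat(coarse_mask, cfg.mid_factor, 0), cfg.mid_factor, 1)

    high_rights = country_mask(0.6)
    secure_tenure = country_mask(0.55)
    restoration_goals = country_mask(0.65)
    z_live = _latent(rng, g_mid.shape, 2 * corr / px_mid)
    low_livelihood = z_live > np.quantile(z_live, 0.25)  # keep ~75%
    z_pa = _latent(rng, g_mid.shape, 2 * corr / px_mid)
    protected = z_pa > np.quantile(z_pa, 0.90)  # ~10% protected

    z_slope = _latent(rng, g_fine.shape, corr / px_fine)
    slope_pct = 40.0 * np.abs(z_slope)
    slope_class = np.where(
        slope_pct < 20.0, SLOPE_FLAT, np.where(slope_pct <= 35.0, SLOPE_MODERATE, SLOPE_STEEP)
    ).astype(np.int16)
    z_land = _latent(rng, g_fine.shape, 2 * corr / px_fine)
    landform = np.where(
        z_land > np.quantile(z_land, 0.85), LANDFORM_FLOODPLAIN, LANDFORM_UPLAND
    ).astype(np.int16)

    forest_cover_coarse = _block_mean(cats["forest"].astype(float), cfg.fine_factor, fine_w)

    # --- ground truth (independent block arithmetic) ----------------------
    truth = _ground_truth(
        cfg, g_fine, tree_cover, tree_sd, biomass, walker_ui, fire, agree,
        oil_palm, cats, wetland, peatland, albedo_neg,
    )

    b = np.uint8
    return SyntheticBundle(
        config=cfg,
        tree_cover_mean=grid(tree_cover, g_coarse, "coarse"),
        tree_cover_sd=grid(tree_sd, g_coarse, "coarse"),
        biomass_class=grid(biomass, g_coarse, "coarse", categorical=True),
        walker_ui=grid(walker_ui, g_coarse, "coarse"),
        fire_count=grid(fire, g_mid, "mid"),
        cropland_agreement=grid(agree, g_fine, "fine", categorical=True),
        oil_palm=grid(oil_palm.astype(b), g_fine, "fine"),
        existing_forest=grid(cats["forest"].astype(b), g_fine, "fine"),
        water=grid(cats["water"].astype(b), g_fine, "fine"),
        bare=grid(cats["bare"].astype(b), g_fine, "fine"),
        ice=grid(cats["ice"].astype(b), g_fine, "fine"),
        builtup=grid(cats["builtup"].astype(b), g_fine, "fine"),
        wetland=grid(wetland.astype(b), g_fine, "fine"),
        peatland=grid(peatland.astype(b), g_fine, "fine"),
        albedo_negative=grid(albedo_neg.astype(b), g_fine, "fine"),
        existing_forest_alt=grid(alt_forest.astype(b), g_fine, "fine"),
        cropland_single=grid(single_crop.astype(b), g_fine, "fine"),
        flux=grid(flux, g_coarse, "coarse"),
        population=grid(population, g_coarse, "coarse"),
        forest_loss=loss,
        forest_gain=gain,
        scenario_masks={
            "high_rights": grid(high_rights.astype(b), g_mid, "mid"),
            "secure_tenure": grid(secure_tenure.astype(b), g_mid, "mid"),
            "restoration_goals": grid(restoration_goals.astype(b), g_mid, "mid"),
            "low_livelihood_conflict": grid(low_livelihood.astype(b), g_mid, "mid"),
            "protected_areas": grid(protected.astype(b), g_mid, "mid"),
        },
        slope_class=grid(slope_class, g_fine, "fine", categorical=True),
        landform=grid(landform, g_fine, "fine", categorical=True),
        forest_cover_coarse=grid(forest_cover_coarse, g_coarse, "coarse"),
        truth=truth,
    )


def _ground_truth(
    cfg, g_fine, tree_cover, tree_sd, biomass, walker_ui, fire, agree,
    oil_palm, cats, wetland, peatland, albedo_neg,
) -> dict[str, np.ndarray]:
    """Exact per-coarse-cell availability implied by the generated layers,
    under the default screening criteria, computed by direct block
    arithmetic (no resampling engine involved)."""
    f = cfg.fine_factor
    with np.errstate(divide="ignore", invalid="ignore"):
        ui_b = np.where(tree_cover > 0, 3.92 * tree_sd / tree_cover, np.inf)
    composite = (
        (tree_cover > 60.0) & (biomass == CLOSED_FOREST) & (ui_b < 3.0) & (walker_ui < 3.0)
    )
    fire_coarse = _block_max(fire, cfg.mid_factor)
    crop_coarse = _center_pick(agree, f)
    palm_coarse = _center_pick(oil_palm.astype(np.uint8), f)
    fire_excl = (fire_coarse >= 2) & (crop_coarse < 3) & (palm_coarse == 0)
    fp = composite & ~fire_excl

    impl = cats["forest"] | cats["water"] | cats["bare"] | cats["ice"]
    constr = impl | (agree >= 3) | cats["builtup"] | wetland | peatland | albedo_neg
    w = _band_weights(g_fine)
    avail_max = np.where(fp, 1.0 - _block_mean(impl.astype(float), f, w), 0.0)
    avail_con = np.where(fp, 1.0 - _block_mean(constr.astype(float), f, w), 0.0)
    return {
        "forest_potential": fp.astype(np.uint8),
        "maximum": avail_max,
        "constrained": avail_con,
    }


def worked_example_bundle() -> SyntheticBundle:
    """A tiny fixed, hand-checkable bundle: 2 x 2 coarse cells, fine
    factor 4 (8 x 8 fine grid), mid factor 2.

    Layout (coarse cells named by row, col):

    * (0,0): tree cover 80, closed, low UI — forest potential; the west
      half of its fine block is existing forest (8 of 16 cells excluded).
    * (0,1): tree cover 70, closed, low UI; 2 fires but its center pixel
      is cropland (agreement 4) so the fire screen is exempted; its fine
      block has 4 cropland cells (precautionary exclusion only).
    * (1,0): tree cover 50 — fails the 60% screen.
    * (1,1): tree cover 90 but sd 80 (UI 3.48) — fails the UI screen.
    """
    cfg = SyntheticConfig(
        seed=0, west=10.0, south=42.0, width_deg=1.0, height_deg=1.0,
        n_coarse=2, fine_factor=4, mid_factor=2,
    )
    g_coarse = _geometry(cfg, 1)
    g_mid = _geometry(cfg, 2)
    g_fine = _geometry(cfg, 4)

    tree_cover = np.array([[80.0, 70.0], [50.0, 90.0]])
    tree_sd = np.array([[5.0, 5.0], [5.0, 80.0]])
    biomass = np.full((2, 2), CLOSED_FOREST, dtype=np.int16)
    walker_ui = np.full((2, 2), 1.0)

    fire = np.zeros((4, 4), dtype=np.int32)
    fire[0, 2] = 2  # inside coarse (0,1)

    forest = np.zeros((8, 8), dtype=np.uint8)
    forest[0:4, 0:2] = 1  # west half of coarse (0,0)

    agree = np.zeros((8, 8), dtype=np.int16)
    # 4 cropland cells in coarse (0,1), covering its center pixel (2,6)
    # so the fire exemption applies under nearest-neighbour rescaling
    agree[1:3, 5:7] = 4

    zeros_f = np.zeros((8, 8), dtype=np.uint8)

    def fine(v, categorical=False):
        return Grid(v, g_fine.transform, nodata=None, res_class="fine",
                    categorical=categorical)

    cats = {
        "forest": forest.astype(bool),
        "water": zeros_f.astype(bool),
        "bare": zeros_f.astype(bool),
        "ice": zeros_f.astype(bool),
        "cropland": agree >= 3,
        "builtup": zeros_f.astype(bool),
    }
    truth = _ground_truth(
        cfg, g_fine, tree_cover, tree_sd, biomass, walker_ui, fire, agree,
        zeros_f.astype(bool), cats, zeros_f.astype(bool), zeros_f.astype(bool),
        zeros_f.astype(bool),
    )
    mid_ones = np.ones((4, 4), dtype=np.uint8)
    return SyntheticBundle(
        config=cfg,
        tree_cover_mean=Grid(tree_cover, g_coarse.transform, res_class="coarse"),
        tree_cover_sd=Grid(tree_sd, g_coarse.transform, res_class="coarse"),
        biomass_class=Grid(biomass, g_coarse.transform, res_class="coarse", categorical=True),
        walker_ui=Grid(walker_ui, g_coarse.transform, res_class="coarse"),
        fire_count=Grid(fire, g_mid.transform, res_class="mid"),
        cropland_agreement=fine(agree, categorical=True),
        oil_palm=fine(zeros_f),
        existing_forest=fine(forest),
        water=fine(zeros_f),
        bare=fine(zeros_f),
        ice=fine(zeros_f),
        builtup=fine(zeros_f),
        wetland=fine(zeros_f),
        peatland=fine(zeros_f),
        albedo_negative=fine(zeros_f),
        existing_forest_alt=fine(forest),
        cropland_single=fine((agree >= 3).astype(np.uint8)),
        flux=Grid(np.full((2, 2), 10.0), g_coarse.transform, res_class="coarse"),
        population=Grid(np.full((2, 2), 1000.0), g_coarse.transform, res_class="coarse"),
        forest_loss={(42, 10): 1.0},
        forest_gain={(42, 10): 1.0},
        scenario_masks={
            "high_rights": Grid(mid_ones, g_mid.transform, res_class="mid"),
            "secure_tenure": Grid(mid_ones, g_mid.transform, res_class="mid"),
            "restoration_goals": Grid(mid_ones, g_mid.transform, res_class="mid"),
            "low_livelihood_conflict": Grid(mid_ones, g_mid.transform, res_class="mid"),
            "protected_areas": Grid(mid_ones, g_mid.transform, res_class="mid"),
        },
        slope_class=fine(np.full((8, 8), SLOPE_FLAT, dtype=np.int16), categorical=True),
        landform=fine(np.full((8, 8), LANDFORM_UPLAND, dtype=np.int16), categorical=True),
        forest_cover_coarse=Grid(
            _block_mean(forest.astype(float), 4, _band_weights(g_fine)),
            g_coarse.transform, res_class="coarse",
        ),
        truth=truth,
    )


_RASTER_FIELDS = (
    "tree_cover_mean", "tree_cover_sd", "biomass_class", "walker_ui",
    "fire_count", "cropland_agreement", "oil_palm", "existing_forest",
    "water", "bare", "ice", "builtup", "wetland", "peatland",
    "albedo_negative", "existing_forest_alt", "cropland_single", "flux",
    "population", "slope_class", "landform", "forest_cover_coarse",
)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> Path:
    """Write a bundle as a directory of GeoTIFFs plus a JSON manifest and a
    loss/gain CSV; truth fractions are written as GeoTIFFs too."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries: dict[str, dict] = {}
    for name in _RASTER_FIELDS:
        g: Grid = getattr(bundle, name)
        fn = f"{name}.tif"
        geotiff.write_geotiff(out / fn, g)
        entries[name] = {"file": fn, "res_class": g.res_class, "kind": "input"}
    for name, g in bundle.scenario_masks.items():
        fn = f"scenario_{name}.tif"
        geotiff.write_geotiff(out / fn, g)
        entries[f"scenario:{name}"] = {"file": fn, "res_class": g.res_class,
                                       "kind": "scenario_mask"}
    coarse_t = bundle.tree_cover_mean.transform
    for name in ("forest_potential", "maximum", "constrained"):
        fn = f"truth_{name}.tif"
        geotiff.write_geotiff(
            out / fn,
            Grid(bundle.truth[name].astype(float), coarse_t, res_class="coarse"),
        )
        entries[f"truth:{name}"] = {"file": fn, "res_class": "coarse", "kind": "truth"}
    rows = [
        {"lat0": la, "lon0": lo, "loss": bundle.forest_loss[(la, lo)],
         "gain": bundle.forest_gain[(la, lo)]}
        for (la, lo) in sorted(bundle.forest_loss)
    ]
    pd.DataFrame(rows).to_csv(out / "loss_gain.csv", index=False)
    entries["loss_gain"] = {"file": "loss_gain.csv", "res_class": "one_degree",
                            "kind": "table"}
    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "layers": entries,
    }
    geotiff.write_manifest(out / "manifest.json", manifest)
    return out


def read_bundle(bundle_dir: str | Path) -> SyntheticBundle:
    """Reconstruct a bundle from :func:`write_bundle` output."""
    d = Path(bundle_dir)
    manifest = geotiff.read_manifest(d / "manifest.json")
    cfg = SyntheticConfig(**manifest["config"])
    layers = manifest["layers"]

    def load(key: str) -> Grid:
        return geotiff.read_geotiff(d / layers[key]["file"])

    kwargs = {name: load(name) for name in _RASTER_FIELDS}
    scenario_masks = {
        key.split(":", 1)[1]: load(key) for key in layers if key.startswith("scenario:")
    }
    truth = {
        key.split(":", 1)[1]: load(key).values for key in layers if key.startswith("truth:")
    }
    lg = pd.read_csv(d / layers["loss_gain"]["file"])
    loss = {(int(r.lat0), int(r.lon0)): float(r.loss) for r in lg.itertuples()}
    gain = {(int(r.lat0), int(r.lon0)): float(r.gain) for r in lg.itertuples()}
    return SyntheticBundle(
        config=cfg, forest_loss=loss, forest_gain=gain,
        scenario_masks=scenario_masks, truth=truth, **kwargs,
    )
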