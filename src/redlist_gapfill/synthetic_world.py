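"""Seeded synthetic oceans and species pools.

The pipeline's real-world inputs are occurrence databases, trait compendia,
Red List statuses, protected-area polygons and bathymetry. This module
generates miniature stand-ins with the statistical structure the downstream
stages assume:

* a rectangular equal-area grid with a smooth depth field and a random
  protected-cell mask;
* a species pool whose 12 predictors (growth rate K, maximum length,
  reproduction mode, min/max depth, fertilization mode, body shape, trophic
  level, climate niche, water-column position, price category, aquarium
  interest) are clustered within families, emulating taxonomic conservatism;
* occurrence points drawn from a species-specific bivariate kernel so convex
  hulls are compact and kernel width controls range size;
* a latent threat process: the probability of being truly Threatened follows
  a logistic model in (log) range size, (log) body size and growth rate, the
  three attributes that dominate extinction-risk prediction for marine
  fishes. A configurable fraction of species has its true status masked to
  DDNE (Data Deficient / Not Evaluated), and per-trait missingness is
  applied completely at random (optionally clustered by family).

All randomness flows from a single master seed, split per stage with
``numpy.random.SeedSequence`` in a fixed order (depth, protection, families,
traits, occurrences, threat, status masking, trait missingness), so each
stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import MultiPoint

from .range_builder import GridSpec

#: The 12 predictor columns used by imputation and classification.
CONTINUOUS_TRAITS = ["growth_k", "max_length_cm", "depth_min_m", "depth_max_m", "trophic_level"]
CATEGORICAL_TRAITS = [
    "reproduction_mode",
    "fertilization_mode",
    "body_shape",
    "climate_niche",
    "water_column",
    "price_category",
    "aquarium_interest",
]
PREDICTORS = CONTINUOUS_TRAITS + CATEGORICAL_TRAITS

_TRAIT_LEVELS = {
    "reproduction_mode": ["dioecism", "protandry", "protogyny", "hermaphroditism", "parthenogenesis"],
    "fertilization_mode": ["external", "oviduct", "mouth", "brood_pouch", "other"],
    "body_shape": ["fusiform", "elongated", "compressed", "eel-like"],
    "climate_niche": ["tropical", "subtropical", "temperate", "polar"],
    "water_column": ["demersal", "benthopelagic", "pelagic", "reef"],
    "price_category": ["low", "medium", "high", "very_high"],
    "aquarium_interest": ["none", "commercial", "highly_commercial"],
}

THREATENED = "Threatened"
NON_THREATENED = "NonThreatened"
DDNE = "DDNE"


class ConfigurationError(ValueError):
    """Raised for invalid world or species generator configuration."""


@dataclass(frozen=True)
class WorldConfig:
    grid_rows: int = 60
    grid_cols: int = 60
    cell_km: float = 10.0
    pa_fraction: float = 0.08
    depth_range_m: tuple[float, float] = (5.0, 4000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if not 0.0 <= self.pa_fraction <= 1.0:
            raise ConfigurationError("pa_fraction must lie in [0, 1]")
        if self.depth_range_m[0] < 0 or self.depth_range_m[0] > self.depth_range_m[1]:
            raise ConfigurationError("depth_range_m must be nonnegative and ordered")


@dataclass(frozen=True)
class ThreatModel:
    """Logistic latent-threat process on standardized covariates.

    logit P(Threatened) = intercept + b_range*z(log area) + b_size*z(log length)
    + b_growth*z(K). The defaults give a strongly imbalanced pool (roughly one
    Threatened species in ten) in which small-ranged, large, slow-growing
    species carry most of the risk — the attribute pattern that drives
    extinction-risk prediction in marine fishes.
    """

    intercept: float = -2.5
    beta_range: float = -1.5
    beta_size: float = 1.0
    beta_growth: float = -1.0


@dataclass(frozen=True)
class SpeciesGenConfig:
    n_species: int = 300
    n_families: int = 20
    threat_model: ThreatModel = field(default_factory=ThreatModel)
    ddne_fraction: float = 0.38
    missingness_rates: dict[str, float] | float = 0.10
    occ_per_species: tuple[int, int] = (6, 40)
    family_missingness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise ConfigurationError("n_species must be nonnegative")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be positive")
        if not 0.0 <= self.ddne_fraction <= 1.0:
            raise ConfigurationError("ddne_fraction must lie in [0, 1]")
        if self.occ_per_species[0] < 2 or self.occ_per_species[0] > self.occ_per_species[1]:
            raise ConfigurationError("occ_per_species must satisfy 2 <= min <= max")
        rates = self.missingness_rates
        values = rates.values() if isinstance(rates, dict) else [rates]
        if any(not 0.0 <= r <= 1.0 for r in values):
            raise ConfigurationError("missingness rates must lie in [0, 1]")


@dataclass
class World:
    grid: GridSpec
    depth: np.ndarray  # (rows, cols) maximal depth per cell, metres
    pa_mask: np.ndarray  # (rows, cols) bool, True = protected
    config: WorldConfig


@dataclass
class SpeciesPool:
    """Per-species traits, taxonomy, occurrences and status labels.

    ``species`` is indexed by ``species_id`` and carries family, genus, the
    12 predictors, ``true_status``, ``observed_status`` and the generator's
    latent ``threat_prob``. ``occurrences`` is long-format
    (species_id, x, y) in grid km. ``missing_mask`` marks entries of the
    predictor block that were blanked by the missingness process.
    """

    species: pd.DataFrame
    occurrences: pd.DataFrame
    missing_mask: pd.DataFrame

    def __len__(self) -> int:
        return len(self.species)

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.species.to_csv(out / "species.csv")
        self.occurrences.to_csv(out / "occurrences.csv", index=False)
        self.missing_mask.to_csv(out / "missing_mask.csv")

    @classmethod
    def from_dir(cls, in_dir) -> "SpeciesPool":
        p = Path(in_dir)
        species = pd.read_csv(p / "species.csv", index_col=0)
        species.index = species.index.astype(str)
        occ = pd.read_csv(p / "occurrences.csv", dtype={"species_id": str})
        mask = pd.read_csv(p / "missing_mask.csv", index_col=0).astype(bool)
        mask.index = mask.index.astype(str)
        return cls(species=species, occurrences=occ, missing_mask=mask)


# ----------------------------------------------------------------- world

def _smooth_field(rng: np.random.Generator, rows: int, cols: int, passes: int = 4) -> np.ndarray:
    """Spatially autocorrelated field in [0, 1] via repeated 3x3 box smoothing."""
    f = rng.random((rows, cols))
    for _ in range(passes):
        padded = np.pad(f, 1, mode="edge")
        f = (
            padded[:-2, :-2] + padded[:-2, 1:-1] + padded[:-2, 2:]
            + padded[1:-1, :-2] + padded[1:-1, 1:-1] + padded[1:-1, 2:]
            + padded[2:, :-2] + padded[2:, 1:-1] + padded[2:, 2:]
        ) / 9.0
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.full_like(f, 0.5)


def build_world(config: WorldConfig) -> World:
    """Build a toy ocean: grid, smooth bathymetry, random protected mask."""
    ss = np.random.SeedSequence(config.seed)
    depth_rng, pa_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    grid = GridSpec(config.grid_rows, config.grid_cols, config.cell_km)
    d0, d1 = config.depth_range_m
    depth = d0 + _smooth_field(depth_rng, grid.rows, grid.cols) * (d1 - d0)
    pa_mask = pa_rng.random((grid.rows, grid.cols)) < config.pa_fraction
    return World(grid=grid, depth=depth, pa_mask=pa_mask, config=config)


# ----------------------------------------------------------------- species

def _family_trait_means(rng: np.random.Generator, n_families: int) -> pd.DataFrame:
    """Family-level centroids: continuous means and one preferred level per
    categorical trait. Between-family spread deliberately exceeds the
    within-family spread used later."""
    fam = pd.DataFrame(index=[f"F{k:03d}" for k in range(n_families)])
    fam["log_growth_k"] = rng.normal(np.log(0.4), 0.6, n_families)
    fam["log_length"] = rng.normal(np.log(30.0), 0.8, n_families)
    fam["trophic"] = rng.normal(3.2, 0.5, n_families)
    # Depth windows live in quantile space of the world's bathymetry so a
    # species' known depth range overlaps a sensible share of the seascape.
    fam["dmin_q"] = rng.uniform(0.0, 0.5, n_families)
    fam["width_q"] = rng.uniform(0.3, 0.8, n_families)
    for trait, levels in _TRAIT_LEVELS.items():
        fam[f"pref_{trait}"] = rng.integers(0, len(levels), n_families)
    return fam


_WITHIN_SD = {"log_growth_k": 0.18, "log_length": 0.25, "trophic": 0.18, "dmin_q": 0.05, "width_q": 0.06}
_PREF_PROB = 0.75  # chance a species inherits its family's preferred level


def _draw_traits(
    rng: np.random.Generator,
    fam_means: pd.DataFrame,
    families: np.ndarray,
    depth_field: np.ndarray,
) -> pd.DataFrame:
    n = len(families)
    fm = fam_means.loc[families].reset_index(drop=True)
    out = pd.DataFrame(index=range(n))
    out["growth_k"] = np.exp(rng.normal(fm["log_growth_k"], _WITHIN_SD["log_growth_k"]))
    out["max_length_cm"] = np.exp(rng.normal(fm["log_length"], _WITHIN_SD["log_length"]))
    out["trophic_level"] = np.clip(rng.normal(fm["trophic"], _WITHIN_SD["trophic"]), 2.0, 4.8)
    qlo = np.clip(rng.normal(fm["dmin_q"], _WITHIN_SD["dmin_q"]), 0.0, 0.6)
    width = np.clip(rng.normal(fm["width_q"], _WITHIN_SD["width_q"]), 0.2, 0.95)
    qhi = np.minimum(qlo + width, 1.0)
    out["depth_min_m"] = np.quantile(depth_field, qlo)
    out["depth_max_m"] = np.quantile(depth_field, qhi)
    for trait, levels in _TRAIT_LEVELS.items():
        pref = fm[f"pref_{trait}"].to_numpy()
        use_pref = rng.random(n) < _PREF_PROB
        random_lvl = rng.integers(0, len(levels), n)
        idx = np.where(use_pref, pref, random_lvl)
        out[trait] = np.asarray(levels, dtype=object)[idx]
    return out


def _draw_occurrences(
    rng: np.random.Generator, grid: GridSpec, n_species: int, occ_range: tuple[int, int]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bivariate-normal occurrence clouds; returns the long table and each
    species' hull area (km², the range-size covariate of the threat model)."""
    recs = []
    hull_area = np.empty(n_species)
    w, h = grid.width_km, grid.height_km
    # Log-uniform kernel widths span small endemics to near-basin species.
    sigma = np.exp(rng.uniform(np.log(0.02 * min(w, h)), np.log(0.25 * min(w, h)), n_species))
    counts = rng.integers(occ_range[0], occ_range[1] + 1, n_species)
    cx = rng.uniform(0, w, n_species)
    cy = rng.uniform(0, h, n_species)
    for i in range(n_species):
        pts = rng.normal([cx[i], cy[i]], sigma[i], size=(counts[i], 2))
        pts[:, 0] = np.clip(pts[:, 0], 0.0, w)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, h)
        # Guarantee >= 2 distinct points even after clipping collapses some.
        if np.unique(pts, axis=0).shape[0] < 2:
            pts[0] = [max(cx[i] - grid.cell_km, 0.0), cy[i]]
            pts[-1] = [min(cx[i] + grid.cell_km, w), cy[i]]
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        hull_area[i] = max(hull.area, grid.cell_area_km2)  # floor: one cell
        for x, y in pts:
            recs.append((i, x, y))
    occ = pd.DataFrame(recs, columns=["species_idx", "x", "y"])
    return occ, hull_area


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def sample_species(world: World, config: SpeciesGenConfig) -> SpeciesPool:
    """Draw a species pool over a built world.

    Traits are clustered within families; the latent threat probability
    follows the configured logistic model in standardized log hull area,
    log maximum length and growth rate; ``observed_status`` masks
    ``true_status`` to DDNE for ``ddne_fraction`` of species; per-trait
    missingness blanks predictor entries.
    """
    ss = np.random.SeedSequence(config.seed)
    fam_rng, trait_rng, occ_rng, threat_rng, status_rng, miss_rng = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    n = config.n_species
    ids = [f"sp{i:05d}" for i in range(n)]
    if n == 0:
        species = pd.DataFrame(
            columns=["family", "genus", *PREDICTORS, "threat_prob", "true_status", "observed_status"]
        )
        species.index.name = "species_id"
        occurrences = pd.DataFrame(columns=["species_id", "x", "y"])
        mask = pd.DataFrame(columns=PREDICTORS, dtype=bool)
        return SpeciesPool(species, occurrences, mask)

    fam_means = _family_trait_means(fam_rng, config.n_families)
    families = fam_means.index.to_numpy()[fam_rng.integers(0, config.n_families, n)]
    # Genera nest within families: each species lands in one of a few
    # family-specific genus slots.
    genus_slots = fam_rng.integers(2, 6, config.n_families)
    slot_of = dict(zip(fam_means.index, genus_slots))
    genus = np.array(
        [f"{fam}_g{trait_rng.integers(0, slot_of[fam])}" for fam in families], dtype=object
    )

    traits = _draw_traits(trait_rng, fam_means, families, world.depth)
    occ, hull_area = _draw_occurrences(occ_rng, world.grid, n, config.occ_per_species)
    occ["species_id"] = [ids[i] for i in occ["species_idx"]]
    occurrences = occ[["species_id", "x", "y"]].copy()

    tm = config.threat_model
    logit = (
        tm.intercept
        + tm.beta_range * _zscore(np.log(hull_area))
        + tm.beta_size * _zscore(np.log(traits["max_length_cm"].to_numpy()))
        + tm.beta_growth * _zscore(traits["growth_k"].to_numpy())
    )
    threat_prob = 1.0 / (1.0 + np.exp(-logit))
    true_threat = threat_rng.random(n) < threat_prob
    true_status = np.where(true_threat, THREATENED, NON_THREATENED)

    n_ddne = int(round(config.ddne_fraction * n))
    ddne_idx = status_rng.choice(n, size=n_ddne, replace=False)
    observed = true_status.copy().astype(object)
    observed[ddne_idx] = DDNE

    species = traits.copy()
    species.insert(0, "family", families)
    species.insert(1, "genus", genus)
    species["hull_area_km2"] = hull_area
    species["threat_prob"] = threat_prob
    species["true_status"] = true_status
    species["observed_status"] = observed
    species.index = pd.Index(ids, name="species_id")

    rates = config.missingness_rates
    if not isinstance(rates, dict):
        rates = {t: float(rates) for t in PREDICTORS}
    mask = pd.DataFrame(False, index=species.index, columns=PREDICTORS)
    for trait in PREDICTORS:
        r = rates.get(trait, 0.0)
        if r <= 0:
            continue
        if config.family_missingness:
            # Taxonomically clustered gaps: whole families go unmeasured.
            fam_miss = {f: miss_rng.random() < r for f in fam_means.index}
            hit = np.array([fam_miss[f] for f in families])
        else:
            hit = miss_rng.random(n) < r
        mask[trait] = hit
        col = species[trait].copy()
        col[hit] = np.nan if trait in CONTINUOUS_TRAITS else pd.NA
        species[trait] = col
    return SpeciesPool(species=species, occurrences=occurrences, missing_mask=mask)


# ----------------------------------------------------------------- text I/O

def save_world(world: World, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "depth.csv", world.depth, delimiter=",", fmt="%.3f")
    np.savetxt(out / "pa_mask.csv", world.pa_mask.astype(int), delimiter=",", fmt="%d")
    with open(out / "world.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "grid_rows": world.config.grid_rows,
                "grid_cols": world.config.grid_cols,
                "cell_km": world.config.cell_km,
                "pa_fraction": world.config.pa_fraction,
                "depth_range_m": list(world.config.depth_range_m),
                "seed": world.config.seed,
            },
            fh,
        )


def load_world(in_dir) -> World:
    p = Path(in_dir)
    with open(p / "world.yaml") as fh:
        raw = yaml.safe_load(fh)
    cfg = WorldConfig(
        grid_rows=raw["grid_rows"],
        grid_cols=raw["grid_cols"],
        cell_km=raw["cell_km"],
        pa_fraction=raw["pa_fraction"],
        depth_range_m=tuple(raw["depth_range_m"]),
        seed=raw["seed"],
    )
    depth = np.loadtxt(p / "depth.csv", delimiter=",", ndmin=2)
    pa = np.loadtxt(p / "pa_mask.csv", delimiter=",", ndmin=2).astype(bool)
    grid = GridSpec(cfg.grid_rows, cfg.grid_cols, cfg.cell_km)
    return World(grid=grid, depth=depth, pa_mask=pa, config=cfg)


def world_config_from_yaml(path) -> WorldConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["depth_range_m"] = tuple(raw.get("depth_range_m", (5.0, 4000.0)))
    return WorldConfig(**raw)
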