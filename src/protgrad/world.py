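"""Synthetic-world generator: gridded cell tables with known statistical structure.

The generator emulates the kind of 0.5° x 0.5° global summary grid the
analysis consumes: each cell carries its geometric area, a terrestrial
fraction from a smooth land/ocean field, a region label, 15 covariates with a
configurable cross-correlation structure plus smooth latitudinal gradients,
and a protected fraction assigned by one of four protection regimes:

* ``fraction``       — every class of the driver gradient is protected at the
  same *rate* (fraction-representative network);
* ``quota``          — every class of the driver gradient receives the same
  absolute protected *area* (quota-representative network);
* ``preferential`` / ``opportunistic`` — the cell protected fraction is a
  logistic function of designated driver covariates with signed effect sizes
  plus noise (biased networks);
* ``mixed``          — a convex combination of the above, so recovery tests
  can plant a known dominance order among drivers.

Covariates are produced by monotone transforms of a joint latent Gaussian
field, so requested latent correlations keep their sign on the observed
(rank) scale, and marginals are realistically skewed (log-normal population,
bounded suitability, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .histograms import (
    DEFAULT_INTERIOR_CLASSES,
    DEFAULT_TRUNCATION,
    TERRESTRIAL_MIN_FRACTION,
    class_layout,
)
from .variables import CANONICAL_VARIABLES, VARIABLE_ORDER

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

REGIMES = ("fraction", "quota", "preferential", "opportunistic", "mixed")

#: Default signed effect sizes (on the standardized latent scale) per regime.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "preferential": {"tourism": 1.2, "frontiers": -0.8, "animal_richness": 0.8},
    "opportunistic": {"isolation": 1.5, "population": -1.0, "cropland_suitability": -0.8},
}

#: Default latent correlations; includes the observed positive association
#: between species richness and cropland suitability.
DEFAULT_CORR: dict[tuple[str, str], float] = {
    ("animal_richness", "plant_richness"): 0.5,
    ("animal_richness", "cropland_suitability"): 0.3,
    ("plant_richness", "cropland_suitability"): 0.4,
    ("population", "isolation"): -0.5,
    ("population", "cropland_suitability"): 0.3,
    ("temperature", "precipitation"): 0.3,
    ("precipitation", "ppt_pet"): 0.6,
    ("elevation", "slope"): 0.5,
}

#: Amplitude of the smooth latitudinal gradient added to each latent field
#: (multiplied by cos(latitude), peaking at the equator).
_GRADIENT_AMPLITUDE: dict[str, float] = {
    "temperature": 1.8, "precipitation": 0.8, "ppt_pet": 0.6,
    "elevation": 0.0, "slope": 0.0, "soil_fertility": 0.3,
    "tourism": 0.0, "frontiers": 0.0, "biomass": 0.9,
    "animal_richness": 1.0, "plant_richness": 1.0,
    "population": 0.3, "isolation": -0.3, "coasts": 0.0,
    "cropland_suitability": 0.4,
}


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


#: Monotone-increasing marginal transform latent -> observed covariate.
_TRANSFORMS = {
    "temperature": lambda z: 15.0 + 10.0 * z,                    # degC
    "precipitation": lambda z: 800.0 * np.exp(0.6 * z),          # mm
    "ppt_pet": lambda z: 0.8 * np.exp(0.5 * z),                  # unitless
    "elevation": lambda z: 600.0 * np.exp(0.7 * z),              # m
    "slope": lambda z: 5.0 * np.exp(0.6 * z),                    # degrees
    "soil_fertility": lambda z: 10.0 * np.exp(0.4 * z),          # cmolc/kg
    "tourism": lambda z: 0.01 * np.exp(0.8 * z),                 # photos/inh
    "frontiers": lambda z: 300.0 * np.exp(0.7 * z),              # km
    "biomass": lambda z: 80.0 * np.exp(0.8 * z),                 # Mg/ha
    "animal_richness": lambda z: 50.0 + 400.0 * _sigmoid(z),     # species
    "plant_richness": lambda z: 500.0 + 3000.0 * _sigmoid(z),    # species
    "population": lambda z: np.exp(9.0 + 1.5 * z),               # inhabitants
    "isolation": lambda z: 600.0 * np.exp(0.8 * z),              # minutes
    "coasts": lambda z: 400.0 * np.exp(0.6 * z),                 # km
    "cropland_suitability": lambda z: 100.0 * _sigmoid(0.9 * z), # 0-100
}

BASE_COLUMNS = (
    "cell_id", "lat", "lon", "cell_area_km2",
    "terrestrial_fraction", "protected_fraction", "region",
)


@dataclass
class WorldConfig:
    """Configuration of one synthetic world.

    Defaults describe the standard study grid used throughout the test
    suite: a 5,000-cell 0.5° grid, seven longitudinal regions, a mostly
    terrestrial land field, 10% overall protection.
    """

    seed: int = 0
    lat_range: tuple[float, float] = (-30.0, 20.0)
    lon_range: tuple[float, float] = (0.0, 25.0)
    resolution: float = 0.5
    n_regions: int = 7
    regime: str = "opportunistic"
    target_protected_fraction: float = 0.10
    effect_sizes: Mapping[str, float] | None = None
    covariate_corr: Mapping[tuple[str, str], float] | None = None
    noise_sd: float = 0.25
    quota_driver: str = "temperature"
    mixture_weights: Mapping[str, float] | None = None
    terrestrial_fraction_model: Mapping[str, float] = field(
        default_factory=lambda: {
            "mean": 0.8, "amplitude": 0.25,
            "lon_period": 70.0, "lat_period": 55.0, "noise_sd": 0.1,
        }
    )

    def validate(self) -> None:
        for name, (a, b) in (("lat_range", self.lat_range), ("lon_range", self.lon_range)):
            if b <= a:
                raise ConfigError(f"{name} must be increasing, got {(a, b)}")
            span = b - a
            if abs(span / self.resolution - round(span / self.resolution)) > 1e-9:
                raise ConfigError(f"resolution {self.resolution} does not divide {name} span {span}")
        if not (-90.0 <= self.lat_range[0] and self.lat_range[1] <= 90.0):
            raise ConfigError("lat_range must lie within [-90, 90]")
        if not (0.0 < self.target_protected_fraction < 1.0):
            raise ConfigError("target_protected_fraction must be in (0, 1)")
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.quota_driver not in CANONICAL_VARIABLES:
            raise ConfigError(f"unknown quota_driver {self.quota_driver!r}")
        for name in (self.effect_sizes or {}):
            if name not in CANONICAL_VARIABLES:
                raise ConfigError(f"unknown covariate {name!r} in effect_sizes")
        _build_sigma(self.covariate_corr)  # raises if not embeddable / PSD

    @property
    def region_labels(self) -> list[str]:
        return [f"region_{i + 1}" for i in range(self.n_regions)]


def cell_area(lat_center, resolution: float = 0.5):
    """Area (km²) of a lat/lon cell: spherical band R²·Δλ·(sin φ_top − sin φ_bot).

    Strictly decreasing in |latitude|; accepts scalars or arrays.
    """
    lat = np.asarray(lat_center, dtype=float)
    if resolution <= 0:
        raise ConfigError("resolution must be > 0")
    half = resolution / 2.0
    if np.any(np.abs(lat) + half > 90.0 + 1e-12):
        raise ConfigError(f"cell at latitude {lat_center} extends beyond a pole")
    top = np.radians(lat + half)
    bot = np.radians(lat - half)
    area = EARTH_RADIUS_KM ** 2 * math.radians(resolution) * (np.sin(top) - np.sin(bot))
    return float(area) if np.isscalar(lat_center) else area


def _build_sigma(corr: Mapping[tuple[str, str], float] | None) -> np.ndarray:
    """Latent correlation matrix over the canonical variables; rejects non-PSD."""
    if corr is None:
        corr = DEFAULT_CORR
    p = len(VARIABLE_ORDER)
    pos = {v: i for i, v in enumerate(VARIABLE_ORDER)}
    sigma = np.eye(p)
    for (a, b), rho in corr.items():
        if a not in pos or b not in pos:
            raise ConfigError(f"unknown covariate pair {(a, b)!r} in covariate_corr")
        if a == b or not (-1.0 <= rho <= 1.0):
            raise ConfigError(f"invalid correlation entry {(a, b)}: {rho}")
        sigma[pos[a], pos[b]] = sigma[pos[b], pos[a]] = rho
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin < -1e-8:
        raise ConfigError(
            f"covariate_corr is not embeddable in a positive semi-definite "
            f"structure (min eigenvalue {eigmin:.3g})"
        )
    return sigma


def _solve_intercept(score: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Bisection for alpha such that the area-weighted mean of sigmoid(alpha+score) hits target."""
    wsum = weights.sum()

    def mean_pf(alpha):
        return float((weights * _sigmoid(alpha + score)).sum() / wsum)

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_pf(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _logistic_protection(z_cols, effects, terr_area, eligible, target, noise_sd, rng):
    score = np.zeros(len(terr_area))
    for name, e in effects.items():
        score += e * z_cols[name]
    score = score + noise_sd * rng.standard_normal(len(score))
    w = terr_area * eligible
    alpha = _solve_intercept(score[eligible], w[eligible], target)
    pf = _sigmoid(alpha + score)
    pf[~eligible] = 0.0
    return pf


def _quota_protection(driver_values, terr_area, eligible, target):
    """Equal absolute protected area per standard analysis class of the driver."""
    v = driver_values[eligible]
    layout = class_layout(v, truncation=DEFAULT_TRUNCATION, n_interior=DEFAULT_INTERIOR_CLASSES)
    idx = layout.assign(v)
    area_class = np.bincount(idx, weights=terr_area[eligible], minlength=layout.n_classes)
    nonempty = area_class > 0
    total_target = target * terr_area[eligible].sum()
    quota = total_target / nonempty.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_class = np.where(nonempty, np.minimum(1.0, quota / area_class), 0.0)
    capped = int((nonempty & (area_class < quota)).sum())
    if capped:
        logger.warning(
            "quota regime: %d class(es) smaller than the quota %.1f km²; capped at class area",
            capped, quota,
        )
    pf = np.zeros(len(terr_area))
    pf[eligible] = rate_class[idx]
    return pf


def _protection(config: WorldConfig, regime, z_cols, driver_values, terr_area, eligible, rng):
    t = config.target_protected_fraction
    if regime == "fraction":
        # constant rate with mild relative jitter; ineligible slivers unprotected
        pf = t * (1.0 + config.noise_sd * 0.1 * rng.standard_normal(len(terr_area)))
        pf = np.clip(pf, 0.0, 1.0)
        pf[~eligible] = 0.0
        return pf
    if regime == "quota":
        return _quota_protection(driver_values, terr_area, eligible, t)
    if regime in ("preferential", "opportunistic"):
        effects = dict(config.effect_sizes) if config.effect_sizes else DEFAULT_EFFECTS[regime]
        return _logistic_protection(z_cols, effects, terr_area, eligible, t, config.noise_sd, rng)
    raise ConfigError(f"unknown regime {regime!r}")


def generate_world(config: WorldConfig) -> pd.DataFrame:
    """Generate the cell table for one configured world. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    res = config.resolution
    lats = np.arange(config.lat_range[0] + res / 2, config.lat_range[1], res)
    lons = np.arange(config.lon_range[0] + res / 2, config.lon_range[1], res)
    glon, glat = np.meshgrid(lons, lats)
    lat = glat.ravel()
    lon = glon.ravel()
    n = lat.size
    area = cell_area(lat, res)

    # land/ocean field: smooth periodic pattern plus noise, clipped to [0, 1]
    m = config.terrestrial_fraction_model
    tf = (
        m["mean"]
        + m["amplitude"] * np.sin(2 * np.pi * lon / m["lon_period"])
        * np.cos(2 * np.pi * lat / m["lat_period"])
        + m["noise_sd"] * rng.standard_normal(n)
    )
    tf = np.clip(tf, 0.0, 1.0)

    # correlated latent fields + latitudinal gradients, then marginal transforms
    sigma = _build_sigma(config.covariate_corr)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(len(VARIABLE_ORDER)))
    eps = rng.standard_normal((n, len(VARIABLE_ORDER))) @ chol.T
    coslat = np.cos(np.radians(lat))
    z_cols: dict[str, np.ndarray] = {}
    cov_cols: dict[str, np.ndarray] = {}
    for k, name in enumerate(VARIABLE_ORDER):
        z = _GRADIENT_AMPLITUDE[name] * (coslat - coslat.mean()) + eps[:, k]
        z_cols[name] = z
        cov_cols[name] = _TRANSFORMS[name](z)

    # regions: contiguous longitudinal strata
    band = (lon - config.lon_range[0]) / (config.lon_range[1] - config.lon_range[0])
    region_idx = np.minimum((band * config.n_regions).astype(int), config.n_regions - 1)
    labels = np.asarray(config.region_labels)[region_idx]

    terr_area = area * tf
    eligible = tf >= TERRESTRIAL_MIN_FRACTION

    if config.regime == "mixed":
        weights = dict(config.mixture_weights or {"fraction": 0.3, "opportunistic": 0.7})
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ConfigError("mixture_weights must be nonnegative with positive sum")
        total = sum(weights.values())
        pf = np.zeros(n)
        for regime, w in weights.items():
            if regime == "mixed":
                raise ConfigError("mixture_weights cannot nest 'mixed'")
            pf += (w / total) * _protection(
                config, regime, z_cols, cov_cols[config.quota_driver], terr_area, eligible, rng
            )
    else:
        pf = _protection(
            config, config.regime, z_cols, cov_cols[config.quota_driver],
            terr_area, eligible, rng,
        )

    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "cell_area_km2": area,
            "terrestrial_fraction": tf,
            "protected_fraction": pf,
            "region": labels,
        }
    )
    for name in VARIABLE_ORDER:
        df[name] = cov_cols[name]
    return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cells(cells: pd.DataFrame, path) -> None:
    """Write the cell table as UTF-8 CSV with full-precision floats."""
    cells.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    """Read and validate a cell table CSV; raises ParseError naming the defect."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file without header") from None
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    if df.empty:
        return df
    numeric = [c for c in df.columns if c not in ("cell_id", "region")]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {int(bad.idxmax())}")
        if parsed.isna().any():
            raise ParseError(f"{path}: missing value in column {col!r}, row {int(parsed.isna().idxmax())}")
        df[col] = parsed

    def _check(mask: pd.Series, message: str):
        if mask.any():
            raise ParseError(f"{path}: {message} (row {int(mask.idxmax())})")

    _check(~df["terrestrial_fraction"].between(0, 1), "terrestrial_fraction outside [0, 1]")
    _check(~df["protected_fraction"].between(0, 1), "protected_fraction outside [0, 1]")
    _check(df["cell_area_km2"] <= 0, "cell_area_km2 must be > 0")
    _check(~df["lat"].between(-90, 90), "lat outside [-90, 90]")
    return df
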