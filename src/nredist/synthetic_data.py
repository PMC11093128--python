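"""Seeded generation of synthetic worlds for the nitrogen-reallocation pipeline.

A world consists of a grid of saturating nitrogen–yield response curves
(pixel × crop × water regime × crop model), harvested areas, a current
fertilizer allocation skewed toward wealthy food-secure units, a country
covariate table and a region membership map.  The generator reproduces the
statistical structure the downstream analysis assumes — monotone saturating
responses heterogeneous across space and crops, a model ensemble scattered
around a shared mean response, rice systems with biological nitrogen
fixation, and current input concentrated where food insecurity is low — so
every pipeline stage is testable without external data.

Yield plateaus, saturation rates and current-rate levels are set to
magnitudes typical of global cereal systems: plateau yields of 5–10 t DM/ha,
half-saturation at roughly 75–90 kg N/ha, harvested areas totalling
~5.4e8 ha, and a fertilizer total of 54 Tg/a (a 59 Tg/a crop total less
5 Tg/a of biological fixation in rice).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit

from .allocation_optimizer import Allocation
from .crops import CROPS, N_DOMAIN_MAX, TG, WATER_REGIMES, get_crop
from .errors import ConfigurationError
from .response_model import ENSEMBLE, GridCellResponse, UnitResponse

DEFAULT_MODELS = ("EPIC-TAMU", "GEPIC", "LPJ-GUESS", "LPJmL", "PEPIC", "pDSSAT")

#: plateau yield (t DM/ha), mean saturation rate (1/kg/ha), share of area,
#: and current-rate pattern (kg fertilizer/ha) per crop
_CROP_GEN = {
    "maize": (10.0, 0.0085, 0.30, 119.0),
    "rice": (8.0, 0.0091, 0.29, 129.0),
    "winter_wheat": (7.0, 0.0078, 0.26, 100.0),
    "spring_wheat": (5.0, 0.0078, 0.15, 75.0),
}

_CONTINENTS = ("Africa", "Asia", "Europe", "North America", "South America",
               "Oceania")


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    ``input_skew`` controls how strongly current fertilizer input couples to
    a unit's latent wealth (0 = no coupling); food insecurity decreases with
    the same latent, so a positive skew concentrates input in food-secure
    units.  ``response_heterogeneity`` is the log-scale spread of yield
    plateaus across units and pixels.
    """

    seed: int
    n_units: int = 60
    pixels_per_unit: int = 4
    crops: tuple[str, ...] = tuple(CROPS)
    n_models: int = 6
    current_global_input_tg: float = 54.0  # synthetic fertilizer, Tg/a
    input_skew: float = 1.0
    response_heterogeneity: float = 0.15
    total_area_ha: float = 5.4e8
    bnf_total_tg: float = 5.0  # rice biological fixation, Tg/a
    model_spread: float = 0.08
    n_regions: int = 19
    allow_nonmonotone: bool = False

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        if self.pixels_per_unit < 1:
            raise ConfigurationError("pixels_per_unit must be >= 1")
        if not self.crops:
            raise ConfigurationError("crops must be non-empty")
        for c in self.crops:
            get_crop(c)
        if self.n_models < 1:
            raise ConfigurationError("n_models must be >= 1")
        if self.current_global_input_tg <= 0:
            raise ConfigurationError("current_global_input_tg must be > 0")
        if self.input_skew < 0:
            raise ConfigurationError("input_skew must be >= 0")
        if self.total_area_ha <= 0:
            raise ConfigurationError("total_area_ha must be > 0")
        if self.bnf_total_tg < 0:
            raise ConfigurationError("bnf_total_tg must be >= 0")

    @property
    def model_ids(self) -> tuple[str, ...]:
        if self.n_models <= len(DEFAULT_MODELS):
            return DEFAULT_MODELS[: self.n_models]
        return DEFAULT_MODELS + tuple(
            f"model_{i}" for i in range(len(DEFAULT_MODELS), self.n_models)
        )


@dataclass
class SyntheticWorld:
    """A generated world: gridded responses + country table + current rates."""

    grid: xr.Dataset
    countries: pd.DataFrame
    current_allocation: Allocation
    region_map: pd.DataFrame  # unit_id, region, continent
    config: WorldConfig

    @property
    def unit_ids(self) -> np.ndarray:
        return np.unique(self.grid["unit_id"].values)

    @property
    def crop_names(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.grid["crop"].values)

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(str(m) for m in self.grid["model"].values)

    def unit_bnf_rate(self, unit_id: int, crop: str) -> float:
        mask = self.grid["unit_id"].values == unit_id
        return float(self.grid["bnf_rate"].sel(crop=crop).values[mask][0])

    def crop_area_ha(self, crop: str) -> float:
        return float(self.grid["area_ha"].sel(crop=crop).sum())

    def crop_fert_total_kg(self, crop: str) -> float:
        area = self.grid["area_ha"].sel(crop=crop).sum("water_regime").values
        rate = self.grid["current_rate_kg_ha"].sel(crop=crop).values
        return float(area @ rate)

    def bnf_total_kg(self, crop: str | None = None) -> float:
        ds = self.grid
        area = ds["area_ha"].sum("water_regime")
        tot = (area * ds["bnf_rate"]).sum("crop") if crop is None else (
            area.sel(crop=crop) * ds["bnf_rate"].sel(crop=crop)
        )
        return float(tot.sum())

    def cells(
        self,
        unit_id: int | None = None,
        crop: str | None = None,
        model_id: str | None = None,
    ) -> Iterator[GridCellResponse]:
        """Iterate grid cells, optionally filtered (test/oracle path)."""
        ds = self.grid
        units = ds["unit_id"].values
        for ip, pix in enumerate(ds["pixel"].values):
            if unit_id is not None and units[ip] != unit_id:
                continue
            for c in self.crop_names:
                if crop is not None and c != crop:
                    continue
                for w in WATER_REGIMES:
                    area = float(ds["area_ha"].sel(crop=c, water_regime=w)[ip])
                    for m in self.model_ids:
                        if model_id is not None and m != model_id:
                            continue
                        yield GridCellResponse(
                            pixel_id=int(pix),
                            unit_id=int(units[ip]),
                            crop=c,
                            water_regime=w,
                            model_id=m,
                            poly_coeffs=ds["poly_coeff"]
                            .sel(crop=c, water_regime=w, model=m)
                            .values[ip],
                            area_ha=area,
                            bnf_rate=float(ds["bnf_rate"].sel(crop=c)[ip]),
                        )

    def unit_responses(self, ensemble: str = ENSEMBLE) -> list[UnitResponse]:
        """Aggregated calorie responses for every (unit, crop), vectorized.

        ``ensemble`` is a model id or ``"ensemble"`` (equal-weight mean of
        the model coefficient sets).
        """
        ds = self.grid
        units = ds["unit_id"].values
        out: list[UnitResponse] = []
        if ensemble == ENSEMBLE:
            coeff = ds["poly_coeff"].mean("model")
        else:
            if ensemble not in self.model_ids:
                raise ValueError(f"unknown model id {ensemble!r}")
            coeff = ds["poly_coeff"].sel(model=ensemble)
        for u in self.unit_ids:
            mask = units == u
            for c in self.crop_names:
                cp = get_crop(c)
                # rows: (pixel, regime) members
                cc = coeff.sel(crop=c).values[mask]  # (npix, 2, 4)
                aa = ds["area_ha"].sel(crop=c).values[mask]  # (npix, 2)
                bnf = float(ds["bnf_rate"].sel(crop=c).values[mask][0])
                out.append(
                    UnitResponse(
                        unit_id=int(u),
                        crop=cp,
                        model_id=ensemble,
                        coeffs=cc.reshape(-1, 4) * cp.calorie_coeff,
                        areas=aa.reshape(-1),
                        bnf_rate=bnf,
                    )
                )
        return out


# ---------------------------------------------------------------------------


def scale_to_total(
    raw: np.ndarray,
    areas: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    target: float,
) -> np.ndarray:
    """Scale positive raw rates so that sum(area*clip(s*raw, lb, ub)) == target.

    Bounded proportional scaling: a single multiplier is bisected, clipping
    to the per-entry bounds, and the residual left by clipping is spread
    over the unclipped entries so the total is met to machine precision.
    """
    lo_tot, hi_tot = float(areas @ lb), float(areas @ ub)
    if not (lo_tot - 1e-6 <= target <= hi_tot + 1e-6):
        raise ConfigurationError(
            f"target input {target:.6g} kg outside the feasible range "
            f"[{lo_tot:.6g}, {hi_tot:.6g}] implied by rate bounds and areas"
        )
    total = lambda s: float(areas @ np.clip(s * raw, lb, ub))
    s_hi = 1.0
    while total(s_hi) < target and s_hi < 1e12:
        s_hi *= 2.0
    s_lo = 0.0
    for _ in range(200):
        s = 0.5 * (s_lo + s_hi)
        if total(s) < target:
            s_lo = s
        else:
            s_hi = s
    s = 0.5 * (s_lo + s_hi)
    rates = np.clip(s * raw, lb, ub)
    free = (rates > lb + 1e-12) & (rates < ub - 1e-12)
    resid = target - float(areas @ rates)
    if free.any():
        rates[free] += resid / float(areas[free].sum())
    return np.clip(rates, lb, ub)


def _fit_cubics(curves: np.ndarray, n_grid: int = 41) -> np.ndarray:
    """Least-squares cubic coefficients (increasing order) for sampled curves.

    ``curves``: (n_curves, n_grid) samples on a uniform N grid [0, 200].
    """
    n = np.linspace(0.0, N_DOMAIN_MAX, n_grid)
    design = np.vander(n, 4, increasing=True)
    pinv = np.linalg.pinv(design)
    return curves @ pinv.T


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world (seeded, bitwise deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nu, ppu = config.n_units, config.pixels_per_unit
    crops = tuple(config.crops)
    models = config.model_ids
    n_pix = nu * ppu
    unit_of_pixel = np.repeat(np.arange(nu), ppu)

    # --- latent wealth drives GDP, food insecurity and current input
    wealth = rng.standard_normal(nu)
    gdp = np.exp(8.5 + 1.1 * wealth)
    fi = 100.0 * expit(-(1.0 + 1.2 * wealth + 0.6 * rng.standard_normal(nu)))
    population = rng.lognormal(16.0, 1.4, nu)
    agri_share = 100.0 * expit(
        -(2.0 + 0.7 * wealth + 0.5 * rng.standard_normal(nu))
    )
    countries = pd.DataFrame(
        {
            "country_id": np.arange(nu),
            "fi_prevalence": fi,
            "population": population,
            "gdp_per_capita": gdp,
            "agri_share_gdp": agri_share,
        }
    )

    # --- region membership (round-robin; continent label per region)
    n_regions = max(1, min(config.n_regions, nu))
    region_of_unit = np.arange(nu) % n_regions
    region_map = pd.DataFrame(
        {
            "unit_id": np.arange(nu),
            "region": [f"region_{r:02d}" for r in region_of_unit],
            "continent": [
                _CONTINENTS[r % len(_CONTINENTS)] for r in region_of_unit
            ],
        }
    )

    # --- harvested areas: lognormal unit and pixel weights, Beta regime split
    shares = np.array([_CROP_GEN[c][2] for c in crops])
    shares = shares / shares.sum()
    area = np.empty((n_pix, len(crops), 2))
    for ic, c in enumerate(crops):
        unit_w = rng.lognormal(0.0, 1.0, nu)
        pix_w = rng.lognormal(0.0, 0.5, (nu, ppu))
        pix_w = pix_w / pix_w.sum(axis=1, keepdims=True)
        unit_area = config.total_area_ha * shares[ic] * unit_w / unit_w.sum()
        pix_area = (unit_area[:, None] * pix_w).reshape(-1)
        irr = rng.beta(6.0, 12.0, nu)[unit_of_pixel]
        area[:, ic, 0] = pix_area * (1.0 - irr)
        area[:, ic, 1] = pix_area * irr

    # --- biological fixation in rice, scaled to the configured global total
    bnf = np.zeros((n_pix, len(crops)))
    if "rice" in crops and config.bnf_total_tg > 0:
        ic = crops.index("rice")
        unit_bnf = rng.uniform(20.0, 40.0, nu)
        rice_area_unit = np.array(
            [area[unit_of_pixel == u, ic, :].sum() for u in range(nu)]
        )
        factor = config.bnf_total_tg * TG / float(rice_area_unit @ unit_bnf)
        bnf[:, ic] = (unit_bnf * factor)[unit_of_pixel]

    # --- response curves: saturating template fitted by cubics
    # k below 0.01/kg keeps the fitted cubic monotone and concave on [0,200]
    k_hi = 0.025 if config.allow_nonmonotone else 0.0095
    n_grid = np.linspace(0.0, N_DOMAIN_MAX, 41)
    coeff = np.empty((n_pix, len(crops), 2, len(models), 4))
    het = config.response_heterogeneity
    model_bias = np.exp(
        config.model_spread * rng.standard_normal(len(models))
        - 0.5 * config.model_spread**2
    )
    regime_mult = {"rainfed": 0.9, "irrigated": 1.15}
    for ic, c in enumerate(crops):
        y_plateau, k_mean, _, _ = _CROP_GEN[c]
        unit_fac = np.exp(het * rng.standard_normal(nu))[unit_of_pixel]
        for iw, w in enumerate(WATER_REGIMES):
            pix_fac = np.exp(0.5 * het * rng.standard_normal(n_pix))
            ymax = y_plateau * regime_mult[w] * unit_fac * pix_fac
            k = np.clip(
                rng.lognormal(np.log(k_mean), 0.08, n_pix), 0.003, k_hi
            )
            y0_frac = rng.uniform(0.22, 0.28, n_pix)
            curves = ymax[:, None] * (
                y0_frac[:, None]
                + (1.0 - y0_frac[:, None])
                * (1.0 - np.exp(-np.outer(k, n_grid)))
            )
            base = _fit_cubics(curves)
            noise = np.exp(
                config.model_spread * rng.standard_normal((n_pix, len(models)))
                - 0.5 * config.model_spread**2
            )
            coeff[:, ic, iw, :, :] = (
                base[:, None, :] * (model_bias[None, :] * noise)[:, :, None]
            )

    # --- current fertilizer rates: wealth-coupled, bounded, conserved total
    lb = np.empty((nu, len(crops)))
    ub = np.empty((nu, len(crops)))
    unit_area_crop = np.empty((nu, len(crops)))
    unit_bnf_crop = np.empty((nu, len(crops)))
    for ic, c in enumerate(crops):
        cp = get_crop(c)
        for u in range(nu):
            mask = unit_of_pixel == u
            unit_area_crop[u, ic] = area[mask, ic, :].sum()
            unit_bnf_crop[u, ic] = bnf[mask, ic][0]
        lb[:, ic] = np.maximum(0.0, cp.rate_min_total - unit_bnf_crop[:, ic])
        ub[:, ic] = cp.rate_max_total - unit_bnf_crop[:, ic]
    base_rate = np.array([_CROP_GEN[c][3] for c in crops])
    raw = base_rate[None, :] * np.exp(
        config.input_skew * wealth[:, None]
        + 0.35 * rng.standard_normal((nu, len(crops)))
    )
    rates = scale_to_total(
        raw.reshape(-1),
        unit_area_crop.reshape(-1),
        lb.reshape(-1),
        ub.reshape(-1),
        config.current_global_input_tg * TG,
    ).reshape(nu, len(crops))

    current = Allocation(
        {
            (int(u), c): float(rates[u, ic])
            for u in range(nu)
            for ic, c in enumerate(crops)
        }
    )

    grid = xr.Dataset(
        {
            "poly_coeff": (
                ("pixel", "crop", "water_regime", "model", "coeff"),
                coeff,
            ),
            "area_ha": (("pixel", "crop", "water_regime"), area),
            "bnf_rate": (("pixel", "crop"), bnf),
            "current_rate_kg_ha": (
                ("pixel", "crop"),
                rates[unit_of_pixel, :],
            ),
            "unit_id": (("pixel",), unit_of_pixel),
        },
        coords={
            "pixel": np.arange(n_pix),
            "crop": list(crops),
            "water_regime": list(WATER_REGIMES),
            "model": list(models),
            "coeff": np.arange(4),
        },
    )
    return SyntheticWorld(
        grid=grid,
        countries=countries,
        current_allocation=current,
        region_map=region_map,
        config=config,
    )


def generate_foodsec_table(
    n_countries: int,
    seed: int,
    planted_slope: float = -0.35,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Country covariate table with a planted log(GDP)–log(FI) relation.

    Food-insecurity prevalence is right-skewed in (0, 100]; GDP per capita
    is log-normal with log(GDP) = const + planted_slope * (log FI − center)
    + Gaussian noise, so a regression of log(GDP) on log(FI) recovers
    ``planted_slope`` in expectation.
    """
    if n_countries < 3:
        raise ConfigurationError(
            "n_countries must be >= 3 (regression undefined below that)"
        )
    rng = np.random.default_rng(seed)
    center = np.log(22.0)
    log_fi = np.minimum(
        rng.normal(center, 0.7, n_countries), np.log(99.9)
    )
    gdp = np.exp(
        9.0
        + planted_slope * (log_fi - center)
        + noise_sd * rng.standard_normal(n_countries)
    )
    population = rng.lognormal(16.0, 1.4, n_countries)
    agri_share = 100.0 * expit(
        -(2.0 + 0.5 * rng.standard_normal(n_countries))
    )
    return pd.DataFrame(
        {
            "country_id": np.arange(n_countries),
            "fi_prevalence": np.exp(log_fi),
            "population": population,
            "gdp_per_capita": gdp,
            "agri_share_gdp": agri_share,
        }
    )
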