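"""Synthetic forcing generator for a cool, wet upland heathland site.

Emulates the study conditions of a seasonally waterlogged Atlantic heathland
on organo-mineral soil: ~1278 mm annual precipitation with a wet-winter
maritime seasonal profile, mean annual air temperature 7.1 degC with a
monthly standard deviation of 4.3 degC, and an experimental drought treatment
that excludes 20%-26% of rainfall during the growing season (March-September)
with retractable curtains. The generator produces paired 6-year (72-month)
control and drought climate blocks, seasonal plant carbon inputs, and
synthetic "observed" total soil respiration (Rs) series derived from a
simulated heterotrophic respiration (Rh) series by inverting the seasonal
Rh/Rs partition and adding multiplicative lognormal noise.

What it does NOT emulate: the actual 2009-2014 weather sequence, interannual
autocorrelation structure, or the deposited field dataset. All randomness
flows from one seeded generator passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import DEFAULT_RH_FRACTIONS, thornthwaite_pet

__all__ = [
    "SynthConfig",
    "generate_climate",
    "generate_plant_inputs",
    "generate_rs_observations",
    "write_workspace",
]

#: Monthly precipitation weights (Jan..Dec), summing to 1: a wet-winter
#: maritime upland profile whose summer months still carry ~7-8.5% of the
#: annual total each, so that at ~1278 mm yr^-1 summer rainfall roughly meets
#: summer PET and the untreated soil stays seasonally waterlogged (the site's
#: control plots never fall below ~91 mm of profile water).
P_SEASONAL_WEIGHTS = np.array(
    [0.10, 0.075, 0.075, 0.07, 0.07, 0.07, 0.075, 0.085, 0.085, 0.095, 0.10, 0.10]
)

#: Litterfall-weighted monthly plant-input weights (autumn peak), summing to 1.
INPUT_SEASONAL_WEIGHTS = np.array(
    [0.04, 0.04, 0.05, 0.06, 0.08, 0.09, 0.10, 0.10, 0.12, 0.13, 0.11, 0.08]
)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic site.

    ``drought_exclusion=None`` draws one exclusion fraction per year uniformly
    from [0.20, 0.26] (the curtain-efficiency range); a float fixes it.
    ``annual_input_kg_ha`` (4000 kg C ha^-1 yr^-1) is a placeholder magnitude
    for heathland litter + root inputs — the field value is not published at
    monthly resolution — and is freely configurable.
    """

    seed: int = 0
    years: int = 6
    annual_p_mean: float = 1278.0
    annual_p_sd: float = 110.0
    p_month_cv: float = 0.15
    ta_mean: float = 7.1
    ta_sd: float = 4.3
    ta_year_sd: float = 0.4
    latitude: float = 53.0
    drought_exclusion: float | None = None
    drought_window: tuple[int, int] = (3, 9)  # March-September inclusive
    annual_input_kg_ha: float = 4000.0
    drought_input_factor: float = 1.07
    rs_noise_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.drought_exclusion is not None and not (
            0.0 <= self.drought_exclusion < 1.0
        ):
            raise ValueError(
                f"drought_exclusion {self.drought_exclusion} outside [0, 1)"
            )


def _rng(cfg: SynthConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def generate_climate(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired control and drought climate blocks (``years`` x 12 months).

    Monthly precipitation follows the maritime seasonal profile scaled so each
    year's total is a draw around the annual mean, with multiplicative
    lognormal month-to-month noise. Temperature is a sinusoidal annual cycle
    (July peak) whose amplitude reproduces the monthly standard deviation,
    plus a small interannual offset. PET is computed by Thornthwaite at the
    configured latitude. The drought block equals the control except that
    precipitation in the drought window is reduced by the exclusion fraction.
    Deterministic given the seed.
    """
    rng = _rng(cfg)
    months = np.tile(np.arange(1, 13), cfg.years)
    years = np.repeat(np.arange(cfg.years), 12)

    # precipitation: seasonal shape * yearly total, lognormal monthly noise
    p = np.empty(cfg.years * 12)
    sigma = np.sqrt(np.log(1.0 + cfg.p_month_cv**2))
    for y in range(cfg.years):
        annual = max(rng.normal(cfg.annual_p_mean, cfg.annual_p_sd), 100.0)
        noise = rng.lognormal(-0.5 * sigma**2, sigma, 12)
        shape = P_SEASONAL_WEIGHTS * noise
        p[12 * y : 12 * (y + 1)] = annual * shape / shape.sum()

    # temperature: sinusoid with monthly SD ta_sd -> amplitude ta_sd * sqrt(2)
    amp = cfg.ta_sd * np.sqrt(2.0)
    year_offsets = rng.normal(0.0, cfg.ta_year_sd, cfg.years)
    temp = (
        cfg.ta_mean
        + amp * np.cos(2.0 * np.pi * (months - 7) / 12.0)
        + year_offsets[years]
    )

    pet = thornthwaite_pet(temp, latitude=cfg.latitude)

    control = pd.DataFrame(
        {
            "year": years,
            "month": months,
            "P_mm": p,
            "T_C": temp,
            "PET_mm": pet,
            "treatment": "control",
        }
    )

    if cfg.drought_exclusion is None:
        excl = rng.uniform(0.20, 0.26, cfg.years)[years]
    else:
        excl = np.full(cfg.years * 12, cfg.drought_exclusion)
    lo, hi = cfg.drought_window
    in_window = (months >= lo) & (months <= hi)
    drought = control.copy()
    drought["P_mm"] = np.where(in_window, p * (1.0 - excl), p)
    drought["treatment"] = "drought"
    return control, drought


def generate_plant_inputs(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Monthly plant C input series (kg C ha^-1) for control and drought.

    A litterfall-weighted seasonal shape scaled to the annual total; the
    drought series is the control multiplied uniformly by the treatment
    factor (default 1.07 — biomass slightly higher under the curtains, not
    significantly different). Annual totals are conserved by construction.
    """
    control = np.tile(INPUT_SEASONAL_WEIGHTS * cfg.annual_input_kg_ha, cfg.years)
    return control, control * cfg.drought_input_factor


def generate_rs_observations(
    rh_sim, months, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Synthetic observed total soil respiration from a simulated Rh series.

    Inverts the seasonal Rh/Rs fraction (``Rs = Rh / f(month)``) and applies
    multiplicative lognormal noise with coefficient of variation
    ``rs_noise_cv`` (mean-one, so the partition round-trip recovers Rh in the
    noise-free limit and is unbiased on average).
    """
    rh = np.asarray(rh_sim, dtype=float)
    if np.any(rh < 0):
        raise ValueError("rh_sim must be non-negative")
    mon = np.asarray(months, dtype=int)
    frac = np.array([DEFAULT_RH_FRACTIONS[int(m)] for m in mon])
    rs = rh / frac
    if cfg.rs_noise_cv > 0:
        rng = rng if rng is not None else _rng(cfg)
        sigma = np.sqrt(np.log(1.0 + cfg.rs_noise_cv**2))
        rs = rs * rng.lognormal(-0.5 * sigma**2, sigma, rs.size)
    return rs


def write_workspace(cfg: SynthConfig, outdir) -> dict[str, Path]:
    """Write a complete ready-to-run fixture workspace.

    Emits the control/drought climate blocks, both plant-input series and the
    site horizon table in the delimited formats the pipeline reads. Returns
    the mapping of logical name to path. Same seed, same bytes.
    """
    from .profile import clocaenog_horizons, write_horizon_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    control, drought = generate_climate(cfg)
    in_ctrl, in_drt = generate_plant_inputs(cfg)
    paths = {}

    paths["climate_control"] = out / "climate_control.csv"
    control.to_csv(paths["climate_control"], index=False)
    paths["climate_drought"] = out / "climate_drought.csv"
    drought.to_csv(paths["climate_drought"], index=False)

    for name, series in (("inputs_control", in_ctrl), ("inputs_drought", in_drt)):
        paths[name] = out / f"{name}.csv"
        pd.DataFrame(
            {
                "year": control["year"],
                "month": control["month"],
                "plant_c_kg_ha": series,
            }
        ).to_csv(paths[name], index=False)

    paths["profile"] = out / "profile.csv"
    write_horizon_table(clocaenog_horizons(), paths["profile"])

    paths["config"] = out / "synth_config.txt"
    with open(paths["config"], "w") as fh:
        for k, v in vars(cfg).items():
            fh.write(f"{k}: {v}\n")
    return paths
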