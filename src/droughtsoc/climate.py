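"""Climate forcing, Thornthwaite PET, monthly bucket water balance, and Rs partitioning.

The hydrological layer of the pipeline: monthly potential evapotranspiration
(PET) is derived from air temperature with the classic Thornthwaite (1948)
formulation; a top-down bucket water balance tracks plant-available water per
computational layer; profile water is classified into the Dry / Moderate /
Moist process zones used throughout the analysis; and observed total soil
respiration (Rs) is partitioned into heterotrophic (Rh) and autotrophic (Ra)
components with fixed seasonal fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateMonth",
    "WaterState",
    "thornthwaite_pet",
    "day_length_correction",
    "step_water",
    "run_water_balance",
    "classify_zone",
    "partition_rs",
    "DEFAULT_RH_FRACTIONS",
    "read_climate_table",
    "write_climate_table",
    "ZONE_DRY_MAX_MM",
    "ZONE_MODERATE_MAX_MM",
]

#: Soil-water zone boundaries (mm over the profile): Dry < 80, Moderate 80-110,
#: Moist > 110. These are analysis constants, independent of the profile's
#: field capacity.
ZONE_DRY_MAX_MM = 80.0
ZONE_MODERATE_MAX_MM = 110.0

#: Seasonal Rh/Rs fractions: summer (Jun-Aug) 0.46, spring and autumn
#: (Mar-May, Sep-Nov) 0.525, winter (Dec-Feb) 0.59.
DEFAULT_RH_FRACTIONS: Mapping[int, float] = {
    1: 0.59, 2: 0.59, 3: 0.525, 4: 0.525, 5: 0.525, 6: 0.46,
    7: 0.46, 8: 0.46, 9: 0.525, 10: 0.525, 11: 0.525, 12: 0.59,
}

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# mid-month day of year
_MID_MONTH_DOY = np.cumsum(_DAYS_IN_MONTH) - _DAYS_IN_MONTH / 2.0


@dataclass(frozen=True)
class ClimateMonth:
    """One month of forcing: precipitation P (mm), mean air temperature (degC),
    PET (mm), and the treatment the record belongs to."""

    year: int
    month: int
    p: float
    temp: float
    pet: float = float("nan")
    treatment: str = "control"

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} outside 1..12")
        if self.p < 0:
            raise ValueError("precipitation must be non-negative")


@dataclass
class WaterState:
    """Per-layer plant-available water (mm) plus the month's water-balance terms.

    ``wb`` holds storage change, surplus (drainage out of the profile),
    utilisation (net withdrawal from storage) and deficit (unmet PET), all mm.
    """

    water: np.ndarray
    wb: dict = field(default_factory=dict)

    @property
    def profile_total(self) -> float:
        return float(np.sum(self.water))

    def copy(self) -> "WaterState":
        return WaterState(self.water.copy(), dict(self.wb))


# ---------------------------------------------------------------------------
# Thornthwaite PET
# ---------------------------------------------------------------------------

def day_length_correction(latitude: float) -> np.ndarray:
    """Monthly Thornthwaite correction factors K = (L/12)(N/30), with L the
    mid-month day length (hours) at the given latitude and N the days in the
    month (non-leap calendar)."""
    if abs(latitude) > 66.5:
        raise ValueError("latitude beyond +-66.5 deg: day-length formula invalid")
    phi = np.radians(latitude)
    delta = 0.409 * np.sin(2.0 * np.pi * _MID_MONTH_DOY / 365.0 - 1.39)
    cos_omega = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    day_len = 24.0 / np.pi * np.arccos(cos_omega)
    return (day_len / 12.0) * (_DAYS_IN_MONTH / 30.0)


def thornthwaite_pet(
    monthly_temp: Sequence[float],
    latitude: float = 53.0,
    correction: Sequence[float] | None = None,
) -> np.ndarray:
    """Monthly PET (mm) by the classic Thornthwaite method.

    The series must start in January and span whole years; the annual heat
    index I = sum_m (T_m/5)^1.514 over months with T_m > 0 is computed per
    calendar year. Unadjusted PET is 16 (10 T / I)^a for 0 < T < 26.5 degC,
    the Willmott polynomial above 26.5 degC, and zero at or below 0 degC; the
    result is scaled by the day-length correction (computed from ``latitude``
    unless ``correction`` supplies the 12 monthly factors directly — PET is
    linear in that factor).

    A year in which every month is at or below freezing has heat index 0; its
    PET is returned as all-zero with a warning rather than an error.
    """
    temps = np.asarray(monthly_temp, dtype=float)
    if temps.size == 0 or temps.size % 12 != 0:
        raise ValueError("temperature series length must be a multiple of 12")
    corr = (
        day_length_correction(latitude)
        if correction is None
        else np.asarray(correction, dtype=float)
    )
    if corr.shape != (12,):
        raise ValueError("correction must supply 12 monthly factors")

    pet = np.zeros_like(temps)
    for y in range(temps.size // 12):
        t = temps[12 * y : 12 * (y + 1)]
        pos = t > 0.0
        heat_index = float(np.sum((t[pos] / 5.0) ** 1.514))
        if heat_index == 0.0:
            warnings.warn(
                f"year {y}: all months at or below 0 degC; PET set to zero",
                stacklevel=2,
            )
            continue
        a = (
            6.75e-7 * heat_index**3
            - 7.71e-5 * heat_index**2
            + 1.792e-2 * heat_index
            + 0.49239
        )
        mild = pos & (t < 26.5)
        hot = t >= 26.5
        block = np.zeros(12)
        block[mild] = 16.0 * (10.0 * t[mild] / heat_index) ** a
        block[hot] = -415.85 + 32.24 * t[hot] - 0.43 * t[hot] ** 2
        pet[12 * y : 12 * (y + 1)] = block * corr
    return pet


# ---------------------------------------------------------------------------
# Bucket water balance
# ---------------------------------------------------------------------------

def step_water(
    state: WaterState,
    cm: ClimateMonth,
    layers,
    headroom: float = 1.5,
) -> WaterState:
    """Advance the layered bucket balance by one month.

    Evapotranspirative demand is met from the month's rainfall first (the
    standard monthly bucket convention: when P >= PET the soil recharges and
    ET equals PET). The rainfall excess then infiltrates the top layer and
    cascades downward, each layer retaining water up to ``headroom`` times its
    field capacity (the excess over field capacity representing the
    transiently waterlogged state of poorly drained soils); outflow from the
    bottom layer is surplus. Any unmet demand is extracted from the profile
    proportionally to each layer's water above its lower bound; demand unmet
    even then is deficit.

    The monthly terms reconcile exactly: P = Δstorage + surplus + actual ET,
    with utilisation = max(0, −Δstorage) and deficit = PET − actual ET.
    """
    fc = np.array([la.water_capacity_fc for la in layers])
    wmin = np.array([la.water_min for la in layers])
    hold_max = headroom * fc

    w = state.water.astype(float).copy()
    start_total = float(w.sum())

    # rainfall meets evaporative demand first
    et_from_p = min(cm.p, cm.pet)
    inflow = cm.p - et_from_p
    demand = cm.pet - et_from_p

    # infiltration of the rainfall excess, with downward cascade
    for i in range(len(w)):
        space = hold_max[i] - w[i]
        taken = min(max(space, 0.0), inflow)
        w[i] += taken
        inflow -= taken
    surplus = inflow  # drains out of the bottom of the profile

    # remaining demand drawn from storage, proportional to available water
    avail = np.maximum(w - wmin, 0.0)
    avail_total = float(avail.sum())
    if avail_total <= 0.0 or demand <= 0.0:
        et_actual = et_from_p
    else:
        take = np.minimum(avail, demand * avail / avail_total)
        w -= take
        et_actual = et_from_p + float(take.sum())

    end_total = float(w.sum())
    d_storage = end_total - start_total
    wb = {
        "storage": d_storage,
        "surplus": surplus,
        "utilisation": max(0.0, -d_storage),
        "deficit": cm.pet - et_actual,
        "et_actual": et_actual,
        "closure": cm.p - d_storage - surplus - et_actual,
    }
    return WaterState(w, wb)


def run_water_balance(
    forcing: pd.DataFrame,
    layers,
    initial: str | np.ndarray = "fc",
    headroom: float = 1.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Run :func:`step_water` over a monthly forcing frame.

    ``forcing`` needs columns ``year, month, P_mm, T_C, PET_mm``. Returns a
    frame of monthly water-balance terms plus profile totals, and the per-layer
    water trajectory (months x layers, mm, end-of-month)."""
    fc = np.array([la.water_capacity_fc for la in layers])
    if isinstance(initial, str):
        if initial != "fc":
            raise ValueError("initial must be 'fc' or an array of mm")
        state = WaterState(fc.copy())
    else:
        state = WaterState(np.asarray(initial, dtype=float).copy())

    rows = []
    traj = np.empty((len(forcing), len(layers)))
    for i, rec in enumerate(forcing.itertuples(index=False)):
        cm = ClimateMonth(int(rec.year), int(rec.month), rec.P_mm, rec.T_C, rec.PET_mm)
        state = step_water(state, cm, layers, headroom=headroom)
        traj[i] = state.water
        rows.append(
            {
                "year": cm.year,
                "month": cm.month,
                "P_mm": cm.p,
                "PET_mm": cm.pet,
                "profile_water_mm": state.profile_total,
                **state.wb,
            }
        )
    return pd.DataFrame(rows), traj


def classify_zone(profile_water) -> np.ndarray | str:
    """Classify profile water (mm) into ``Dry`` (< 80), ``Moderate`` (80-110,
    inclusive) or ``Moist`` (> 110). Accepts scalars or arrays; every
    non-negative value maps to exactly one zone."""
    arr = np.asarray(profile_water, dtype=float)
    if np.any(arr < 0):
        raise ValueError("profile water must be non-negative")
    zones = np.where(
        arr < ZONE_DRY_MAX_MM,
        "Dry",
        np.where(arr <= ZONE_MODERATE_MAX_MM, "Moderate", "Moist"),
    )
    if np.isscalar(profile_water) or arr.ndim == 0:
        return str(zones)
    return zones


def partition_rs(
    rs: float, month: int, fractions: Mapping[int, float] | None = None
) -> tuple[float, float]:
    """Split total soil respiration into heterotrophic and autotrophic parts.

    ``rh = rs * f(month)`` with the seasonal fraction map (default: 46% in
    summer, 52.5% in spring/autumn, 59% in winter); ``ra`` is the remainder.
    Perturbed maps (e.g. +-5% or +-10% on one treatment) support the
    partitioning sensitivity analysis.
    """
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month {month} outside 1..12")
    if rs < 0:
        raise ValueError("rs must be non-negative")
    frac = (fractions or DEFAULT_RH_FRACTIONS)[int(month)]
    if not 0.0 < frac < 1.0:
        raise ValueError("Rh fraction must lie in (0, 1)")
    rh = rs * frac
    return rh, rs - rh


def perturbed_fractions(delta: float) -> dict[int, float]:
    """Return the seasonal fraction map scaled by (1 + delta), for the
    +-5% / +-10% sensitivity runs, clipped to (0, 1)."""
    return {
        m: float(np.clip(f * (1.0 + delta), 1e-9, 1 - 1e-9))
        for m, f in DEFAULT_RH_FRACTIONS.items()
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CLIMATE_COLUMNS = ["year", "month", "P_mm", "T_C", "PET_mm", "treatment"]


def read_climate_table(path, latitude: float = 53.0) -> pd.DataFrame:
    """Read monthly climate forcing from delimited text. A missing ``PET_mm``
    column triggers Thornthwaite computation from ``T_C`` at ``latitude``."""
    df = pd.read_csv(path, comment="#")
    required = {"year", "month", "P_mm", "T_C"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    if "PET_mm" not in df.columns:
        df = df.copy()
        df["PET_mm"] = thornthwaite_pet(df["T_C"].to_numpy(), latitude=latitude)
    if "treatment" not in df.columns:
        df["treatment"] = "control"
    return df[CLIMATE_COLUMNS]


def write_climate_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
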