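"""Soil profile representation: horizons, computational layers, and per-layer parameters.

A soil profile is described by a small table of pedogenic horizons (an organic
litter/fermentation layer over mineral horizons, as found in upland podzolic
organo-mineral soils). The turnover model does not operate on horizons directly:
the profile is discretized into thin computational layers of fixed thickness
(default 5 cm), each carrying its share of the soil organic carbon (SOC) stock,
a depth-weighted clay content, and water-holding parameters.

Conventions
-----------
* Depths are cm below the surface; layers are half-open ``[top, bottom)``.
* Horizon SOC stocks are t C ha^-1 (as commonly tabulated); layer stocks are
  kg C ha^-1 (the model's working unit).
* A bottom remainder thinner than half the layer thickness is merged into the
  layer above, so a 32 cm profile at 5 cm thickness yields six layers
  (0-5, 5-10, 10-15, 15-20, 20-25, 25-32 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

__all__ = [
    "Horizon",
    "Layer",
    "ConfigurationError",
    "discretize_profile",
    "layer_capacities",
    "co2_partition_fraction",
    "read_horizon_table",
    "write_layer_table",
    "clocaenog_horizons",
]

T_PER_HA_TO_KG_PER_HA = 1000.0


class ConfigurationError(ValueError):
    """Raised for invalid profile or run configuration."""


@dataclass(frozen=True)
class Horizon:
    """One pedogenic horizon of the profile table.

    Parameters
    ----------
    name : str
        Horizon label (e.g. ``LF``, ``Oh``, ``E``, ``BC``).
    lower_depth : float
        Depth of the horizon's lower boundary, cm below the surface.
    soc_stock : float
        SOC stock of the horizon, t C ha^-1.
    bulk_density : float
        Bulk density, g cm^-3.
    clay, silt, sand : float
        Particle-size fractions, percent of the mineral fraction. Organic
        horizons where texture cannot be measured carry zeros.
    """

    name: str
    lower_depth: float
    soc_stock: float
    bulk_density: float = 0.0
    clay: float = 0.0
    silt: float = 0.0
    sand: float = 0.0

    def __post_init__(self) -> None:
        if self.soc_stock < 0:
            raise ConfigurationError(f"horizon {self.name!r}: soc_stock < 0")
        if self.clay + self.silt + self.sand > 100.0 + 1e-9:
            raise ConfigurationError(
                f"horizon {self.name!r}: clay+silt+sand exceeds 100%"
            )


@dataclass
class Layer:
    """One computational layer of the discretized profile.

    ``soc_stock`` is kg C ha^-1. ``water_capacity_fc`` (field capacity) and
    ``water_min`` (lower bound of plant-available water) are mm of water held
    over the layer thickness; they are filled by :func:`layer_capacities`.
    """

    index: int
    top_depth: float
    bottom_depth: float
    soc_stock: float
    clay: float
    water_capacity_fc: float = float("nan")
    water_min: float = float("nan")

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth


def _validate_horizons(horizons: Sequence[Horizon]) -> None:
    if not horizons:
        raise ConfigurationError("empty horizon table")
    depths = [h.lower_depth for h in horizons]
    if any(b <= a for a, b in zip([0.0] + depths[:-1], depths)):
        raise ConfigurationError(
            f"horizon lower depths must be strictly increasing from 0: {depths}"
        )


def discretize_profile(
    horizons: Sequence[Horizon], thickness: float = 5.0
) -> list[Layer]:
    """Cut the horizon table into computational layers of fixed thickness.

    SOC is apportioned to layers by overlapping depth fraction, assuming the
    stock is uniformly distributed within each horizon; clay is depth-weighted
    across the horizons overlapping a layer. A bottom remainder thinner than
    ``thickness / 2`` merges into the layer above, otherwise it stands as a
    final (thin) layer.

    The operation conserves total SOC and is idempotent: re-discretizing a
    profile already on the layer grid returns the same grid and stocks.
    """
    _validate_horizons(horizons)
    if thickness <= 0:
        raise ConfigurationError("thickness must be positive")
    total_depth = horizons[-1].lower_depth
    if total_depth < thickness:
        raise ConfigurationError("profile shallower than one layer thickness")

    n_full = int(total_depth // thickness)
    bounds = [i * thickness for i in range(n_full + 1)]
    remainder = total_depth - bounds[-1]
    if remainder > 1e-12:
        if remainder < thickness / 2 and n_full >= 1:
            bounds[-1] = total_depth  # merge remainder into the layer above
        else:
            bounds.append(total_depth)

    tops = [h.lower_depth - hthick(horizons, h) for h in horizons]
    layers: list[Layer] = []
    for i, (top, bottom) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        soc = 0.0
        clay_wt = 0.0
        for h, h_top in zip(horizons, tops):
            ov = min(bottom, h.lower_depth) - max(top, h_top)
            if ov <= 0:
                continue
            h_thick = h.lower_depth - h_top
            soc += h.soc_stock * T_PER_HA_TO_KG_PER_HA * ov / h_thick
            clay_wt += h.clay * ov
        layers.append(
            Layer(
                index=i,
                top_depth=top,
                bottom_depth=bottom,
                soc_stock=soc,
                clay=clay_wt / (bottom - top),
            )
        )
    return layers


def hthick(horizons: Sequence[Horizon], h: Horizon) -> float:
    """Thickness of horizon ``h`` given the ordered table it belongs to."""
    i = horizons.index(h)
    upper = horizons[i - 1].lower_depth if i > 0 else 0.0
    return h.lower_depth - upper


def layer_capacities(
    layers: Sequence[Layer],
    mode: str = "pedotransfer",
    prescribed: Sequence[float] | None = None,
    wilt_fraction: float = 0.2,
    mm_per_cm_base: float = 1.0,
    mm_per_cm_clay: float = 0.05,
    mm_per_cm_soc: float = 0.0005,
) -> list[Layer]:
    """Fill per-layer field capacity (``water_capacity_fc``) and ``water_min``.

    ``mode='prescribed'`` copies the supplied mm values verbatim (used for site
    runs where the profile water capacities are known — e.g. the six values
    25.0, 7.5, 7.5, 7.5, 15.6, 12.2 mm totalling 75.3 mm). ``mode='pedotransfer'``
    applies a simple linear texture+SOC rule per cm of soil:

        capacity_mm = thickness_cm * (base + clay_coef*clay% + soc_coef*soc_density)

    with soc_density in kg C ha^-1 per cm. Organic-rich and clay-rich layers
    hold more water. ``water_min`` is ``wilt_fraction`` of field capacity.
    """
    if mode == "prescribed":
        if prescribed is None or len(prescribed) != len(layers):
            raise ConfigurationError(
                "prescribed capacities must match the layer count"
            )
        caps = list(prescribed)
    elif mode == "pedotransfer":
        caps = [
            layer.thickness
            * (
                mm_per_cm_base
                + mm_per_cm_clay * layer.clay
                + mm_per_cm_soc * layer.soc_stock / layer.thickness
            )
            for layer in layers
        ]
    else:
        raise ConfigurationError(f"unknown capacity mode {mode!r}")
    if any(c < 0 for c in caps):
        raise ConfigurationError("negative water capacity")
    return [
        replace(layer, water_capacity_fc=c, water_min=wilt_fraction * c)
        for layer, c in zip(layers, caps)
    ]


def co2_partition_fraction(
    clay: float, bio_fraction: float = 0.46
) -> tuple[float, float, float]:
    """Partition decomposed carbon into CO2, microbial biomass and humus.

    Decomposition products split between respired CO2 and stabilised carbon
    under a clay control: the CO2:stabilised ratio is

        x = 1.67 * (1.85 + 1.60 * exp(-0.0786 * clay))

    so the respired share ``x/(1+x)`` decreases monotonically with clay
    content (finer soils stabilise more of the decomposition flux). The
    stabilised share ``1/(1+x)`` is divided between BIO and HUM in a fixed
    configurable ratio (default 46:54).

    Returns ``(to_co2, to_bio, to_hum)`` summing to 1.
    """
    if not 0.0 <= clay <= 100.0:
        raise ValueError(f"clay content {clay} outside [0, 100]%")
    if not 0.0 < bio_fraction < 1.0:
        raise ValueError("bio_fraction must be in (0, 1)")
    x = 1.67 * (1.85 + 1.60 * math.exp(-0.0786 * clay))
    to_co2 = x / (1.0 + x)
    stabilised = 1.0 - to_co2
    return to_co2, bio_fraction * stabilised, (1.0 - bio_fraction) * stabilised


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_HORIZON_COLUMNS = {
    "horizon": "name",
    "depth_cm": "lower_depth",
    "soc_t_ha": "soc_stock",
    "bd_g_cm3": "bulk_density",
    "clay_pct": "clay",
    "silt_pct": "silt",
    "sand_pct": "sand",
}


def read_horizon_table(path) -> list[Horizon]:
    """Read a delimited horizon table (columns horizon, depth_cm, soc_t_ha,
    bd_g_cm3, clay_pct, silt_pct, sand_pct)."""
    df = pd.read_csv(path, comment="#")
    missing = set(_HORIZON_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"horizon table missing columns: {sorted(missing)}")
    horizons = [
        Horizon(**{attr: row[col] for col, attr in _HORIZON_COLUMNS.items()})
        for _, row in df.iterrows()
    ]
    _validate_horizons(horizons)
    return horizons


def write_horizon_table(horizons: Sequence[Horizon], path) -> None:
    df = pd.DataFrame(
        [
            {col: getattr(h, attr) for col, attr in _HORIZON_COLUMNS.items()}
            for h in horizons
        ]
    )
    df.to_csv(path, index=False)


def write_layer_table(layers: Sequence[Layer], path) -> None:
    """Emit the discretized layer table as delimited text."""
    pd.DataFrame(
        [
            {
                "layer": la.index,
                "top_cm": la.top_depth,
                "bottom_cm": la.bottom_depth,
                "soc_kg_ha": la.soc_stock,
                "clay_pct": la.clay,
                "fc_mm": la.water_capacity_fc,
                "water_min_mm": la.water_min,
            }
            for la in layers
        ]
    ).to_csv(path, index=False)


def clocaenog_horizons() -> list[Horizon]:
    """The published profile table for the Clocaenog heathland site: a C-rich
    organic top (LF over Oh) above a modified-mineral E horizon and a mineral
    gley BC horizon reaching 32 cm."""
    return [
        Horizon("LF", 5.0, 31.3, 0.11, 0.00, 0.00, 0.00),
        Horizon("Oh", 7.0, 25.7, 0.16, 0.75, 29.05, 20.10),
        Horizon("E", 17.0, 15.1, 0.37, 4.51, 55.22, 40.20),
        Horizon("BC", 32.0, 13.0, 0.85, 9.73, 50.07, 40.20),
    ]


#: The six per-layer field capacities (mm) of the site profile, totalling 75.3 mm.
CLOCAENOG_LAYER_FC_MM = [25.0, 7.5, 7.5, 7.5, 15.6, 12.2]
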