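"""Four-pool, depth-resolved monthly soil organic carbon turnover model.

The model follows the classic pool-type structure of first-order SOC models:
plant carbon inputs are split between decomposable (DPM) and resistant (RPM)
plant material; all four active pools — DPM, RPM, microbial biomass (BIO) and
humified organic matter (HUM) — decompose with pool-specific rate constants
modulated by temperature and soil moisture; the decomposed carbon partitions
between respired CO2 and stabilised carbon (BIO + HUM) under a clay control.
Each computational layer runs the same kinetics on its own stocks, clay
content and water state; layers are coupled only through the shared climate
and the water balance.

Respired CO2 is tracked by source pool, because the downstream efficiency
metrics distinguish respiration derived from labile (DPM + RPM) versus stable
(BIO + HUM) pools.

Update scheme: exact exponential decay per pool per month,
``loss = C (1 - exp(-k m_T m_W / 12))``, which conserves carbon exactly and
can never drive a stock negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profile import Layer, co2_partition_fraction

__all__ = [
    "POOLS",
    "ModelParams",
    "PoolState",
    "FluxRecord",
    "SimulationResult",
    "partition_inputs",
    "rate_modifier_temp",
    "rate_modifier_water",
    "step_month",
    "run_simulation",
    "spinup",
    "SpinupError",
]

POOLS = ("dpm", "rpm", "bio", "hum")
_DT_YR = 1.0 / 12.0


class SpinupError(RuntimeError):
    """Raised when iterative spin-up fails to converge."""


@dataclass
class ModelParams:
    """Tunable parameters of the turnover model.

    Attributes
    ----------
    k : dict
        First-order decomposition rate constants per pool, yr^-1. Defaults
        follow the RothC lineage: DPM 10, RPM 0.3, BIO 0.66, HUM 0.02.
    dpm_rpm_ratio : float
        DPM:RPM split ratio r of plant inputs; the DPM share is r/(1+r).
        Default 0.25 — resistant litter typical of woody heathland vegetation.
    t_ref : float
        Reference temperature (degC) at which the temperature modifier is 1.
    dry_floor, anoxic_floor : float
        Lower bounds of the moisture modifier at the dry (wilting) and
        waterlogged (saturation headroom) extremes.
    opt_lo_frac : float
        Start of the moisture optimum band as a fraction of field capacity;
        the modifier is 1 on [opt_lo_frac * fc, fc].
    headroom : float
        Saturation headroom as a multiple of field capacity (shared with the
        water balance); the anoxic decline spans (fc, headroom * fc].
    bio_fraction : float
        BIO share of the stabilised decomposition products (default 46:54
        BIO:HUM).
    depth_allocation : list
        Fraction of plant input delivered to each layer (surface-weighted
        litter by default); must sum to 1.
    """

    k: dict = field(
        default_factory=lambda: {"dpm": 10.0, "rpm": 0.3, "bio": 0.66, "hum": 0.02}
    )
    dpm_rpm_ratio: float = 0.25
    t_ref: float = 18.0
    dry_floor: float = 0.2
    anoxic_floor: float = 0.6
    opt_lo_frac: float = 0.6
    headroom: float = 1.5
    bio_fraction: float = 0.46
    depth_allocation: list = field(
        default_factory=lambda: [0.6, 0.2, 0.1, 0.05, 0.03, 0.02]
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.k.values()):
            raise ValueError("rate constants must be non-negative")
        if abs(sum(self.depth_allocation) - 1.0) > 1e-9:
            raise ValueError("depth_allocation must sum to 1")
        if not 0.0 < self.dry_floor <= 1.0 or not 0.0 < self.anoxic_floor <= 1.0:
            raise ValueError("modifier floors must lie in (0, 1]")

    def k_vector(self) -> np.ndarray:
        return np.array([self.k[p] for p in POOLS])


@dataclass
class PoolState:
    """Per-layer stocks of the four active pools, kg C ha^-1.

    ``stocks`` has shape (n_layers, 4) in :data:`POOLS` order. An optional
    inert stock (excluded from turnover) may be carried alongside.
    """

    stocks: np.ndarray
    inert: float = 0.0

    def __post_init__(self) -> None:
        self.stocks = np.asarray(self.stocks, dtype=float)
        if self.stocks.ndim != 2 or self.stocks.shape[1] != len(POOLS):
            raise ValueError("stocks must have shape (n_layers, 4)")
        if np.any(self.stocks < 0):
            raise ValueError("pool stocks must be non-negative")

    @property
    def n_layers(self) -> int:
        return self.stocks.shape[0]

    def pool(self, name: str) -> np.ndarray:
        return self.stocks[:, POOLS.index(name)]

    @property
    def total_soc(self) -> float:
        return float(self.stocks.sum()) + self.inert

    def copy(self) -> "PoolState":
        return PoolState(self.stocks.copy(), self.inert)


@dataclass
class FluxRecord:
    """One month's respiration and transfer bookkeeping.

    ``rh`` has shape (n_layers, 4): CO2-C respired per layer by source pool.
    ``to_bio`` / ``to_hum`` are the stabilisation transfers per layer and
    ``inputs`` the plant C delivered per layer (all kg C ha^-1).
    """

    month_index: int
    rh: np.ndarray
    to_bio: np.ndarray
    to_hum: np.ndarray
    inputs: np.ndarray

    @property
    def rh_total(self) -> float:
        return float(self.rh.sum())

    def rh_by_source(self, name: str) -> float:
        return float(self.rh[:, POOLS.index(name)].sum())


def partition_inputs(plant_c: float, params: ModelParams) -> np.ndarray:
    """Distribute one month's plant C input over layers and the DPM/RPM pools.

    Returns an (n_layers, 4) array of additions: the DPM share is
    r/(1+r) of the input (r the DPM:RPM ratio), the rest is RPM; both are
    spread over depth by ``params.depth_allocation``. BIO/HUM receive nothing
    directly.
    """
    if plant_c < 0:
        raise ValueError("plant input must be non-negative")
    r = params.dpm_rpm_ratio
    dpm_share = r / (1.0 + r)
    alloc = np.asarray(params.depth_allocation)
    out = np.zeros((alloc.size, len(POOLS)))
    out[:, 0] = plant_c * dpm_share * alloc
    out[:, 1] = plant_c * (1.0 - dpm_share) * alloc
    return out


def rate_modifier_temp(temp: float, params: ModelParams) -> float:
    """Temperature rate modifier in (0, 1].

    A logistic response ``f(T) = 47.91 / (1 + exp(106.06 / (T + 18.27)))``
    normalised by its value at the reference temperature ``t_ref`` and capped
    at 1, so the factor is 1 at (and above) the reference and strictly
    increasing below it. Defined for T > -18.27 degC (the formula's pole);
    colder months are pinned to the formula's limit of 0+.
    """
    t = np.asarray(temp, dtype=float)
    f = np.where(
        t > -18.27 + 1e-6,
        47.91 / (1.0 + np.exp(106.06 / np.maximum(t + 18.27, 1e-6))),
        0.0,
    )
    f_ref = 47.91 / (1.0 + np.exp(106.06 / (params.t_ref + 18.27)))
    out = np.minimum(f / f_ref, 1.0)
    return float(out) if out.ndim == 0 else out


def rate_modifier_water(
    layer_water, fc, params: ModelParams
) -> np.ndarray | float:
    """Moisture rate modifier in (0, 1], piecewise in layer water content.

    * at or below the wilting bound (``water_min`` = 0.2 fc by construction):
      the dry floor;
    * linear rise from the dry floor to 1 between the wilting bound and the
      start of the optimum band (``opt_lo_frac * fc``);
    * 1 across the optimum band up to field capacity;
    * linear decline above field capacity toward the anoxic floor at the
      saturation headroom (oxygen limitation suppressing decomposition in the
      waterlogged state).

    A zero-capacity layer is pinned at the dry floor.
    """
    w = np.asarray(layer_water, dtype=float)
    fc_arr = np.asarray(fc, dtype=float)
    dry, anox = params.dry_floor, params.anoxic_floor
    out = np.full(np.broadcast(w, fc_arr).shape, dry)
    fc_b = np.broadcast_to(fc_arr, out.shape)
    w_b = np.broadcast_to(w, out.shape)
    ok = fc_b > 0
    wmin = 0.2 * fc_b
    lo = params.opt_lo_frac * fc_b
    hi = params.headroom * fc_b
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = dry + (1.0 - dry) * (w_b - wmin) / np.maximum(lo - wmin, 1e-12)
        fall = 1.0 - (1.0 - anox) * (w_b - fc_b) / np.maximum(hi - fc_b, 1e-12)
    out = np.where(ok & (w_b > wmin) & (w_b < lo), rise, out)
    out = np.where(ok & (w_b >= lo) & (w_b <= fc_b), 1.0, out)
    out = np.where(ok & (w_b > fc_b), np.maximum(fall, anox), out)
    out = np.clip(out, min(dry, anox), 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def _partition_matrix(layers: Sequence[Layer], params: ModelParams) -> np.ndarray:
    """(n_layers, 3) array of (to_co2, to_bio, to_hum) fractions per layer."""
    return np.array(
        [co2_partition_fraction(la.clay, params.bio_fraction) for la in layers]
    )


def step_month(
    pools: PoolState,
    temp: float,
    layer_water: np.ndarray,
    layers: Sequence[Layer],
    params: ModelParams,
    plant_c: float = 0.0,
    month_index: int = 0,
    _partition: np.ndarray | None = None,
) -> tuple[PoolState, FluxRecord]:
    """Advance the pool state by one month.

    Every pool loses ``C (1 - exp(-k m_T m_W dt))`` with dt = 1/12 yr; the
    loss from each pool splits by the layer's clay-controlled partition into
    CO2 (recorded by source pool), BIO and HUM — BIO and HUM losses route
    through the same partition (self-recycling). Plant inputs are added after
    decomposition. Mass balance holds exactly:
    ΔSOC = inputs − total Rh.
    """
    if np.isnan(temp) or np.any(np.isnan(layer_water)):
        raise ValueError(f"NaN in forcing at month index {month_index}")
    fc = np.array([la.water_capacity_fc for la in layers])
    m_t = rate_modifier_temp(temp, params)
    m_w = np.asarray(rate_modifier_water(layer_water, fc, params))
    part = _partition if _partition is not None else _partition_matrix(layers, params)

    k = params.k_vector()  # (4,)
    decay = 1.0 - np.exp(-k[None, :] * m_t * m_w[:, None] * _DT_YR)
    loss = pools.stocks * decay  # (L, 4)
    loss_layer = loss.sum(axis=1)  # (L,)

    rh = loss * part[:, 0:1]
    to_bio = loss_layer * part[:, 1]
    to_hum = loss_layer * part[:, 2]

    new = pools.stocks - loss
    new[:, 2] += to_bio
    new[:, 3] += to_hum
    inputs = partition_inputs(plant_c, params)
    if inputs.shape[0] != new.shape[0]:
        raise ValueError("depth_allocation length does not match layer count")
    new += inputs

    flux = FluxRecord(
        month_index=month_index,
        rh=rh,
        to_bio=to_bio,
        to_hum=to_hum,
        inputs=inputs.sum(axis=1),
    )
    return PoolState(new, pools.inert), flux


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory of a run: pool stocks, source-resolved Rh, and soil water.

    ``pools`` has shape (n_months + 1, n_layers, 4) — index 0 is the initial
    state; ``rh`` (n_months, n_layers, 4); ``water`` (n_months, n_layers) mm
    end-of-month; ``wb`` the monthly water-balance frame; ``forcing`` the
    climate used.
    """

    pools: np.ndarray
    rh: np.ndarray
    water: np.ndarray
    wb: pd.DataFrame
    forcing: pd.DataFrame
    plant_inputs: np.ndarray

    @property
    def n_months(self) -> int:
        return self.rh.shape[0]

    def pool_totals(self, name: str) -> np.ndarray:
        """Profile-total trajectory of one pool (length n_months + 1)."""
        return self.pools[:, :, POOLS.index(name)].sum(axis=1)

    def soc_total(self) -> np.ndarray:
        return self.pools.sum(axis=(1, 2))

    def profile_water(self) -> np.ndarray:
        return self.water.sum(axis=1)

    def rh_monthly(self) -> np.ndarray:
        """Total Rh per month (kg CO2-C ha^-1)."""
        return self.rh.sum(axis=(1, 2))

    def rh_labile(self) -> np.ndarray:
        return self.rh[:, :, 0:2].sum(axis=(1, 2))

    def rh_stable(self) -> np.ndarray:
        return self.rh[:, :, 2:4].sum(axis=(1, 2))

    def tidy_fluxes(self) -> pd.DataFrame:
        """One row per (month, layer) with pool stocks and source-resolved Rh."""
        months, layers_n = self.rh.shape[0], self.rh.shape[1]
        idx = pd.MultiIndex.from_product(
            [range(months), range(1, layers_n + 1)], names=["month_index", "layer"]
        )
        data = {
            f"{p}_kg_ha": self.pools[1:, :, j].reshape(-1) for j, p in enumerate(POOLS)
        }
        data.update(
            {f"rh_{p}": self.rh[:, :, j].reshape(-1) for j, p in enumerate(POOLS)}
        )
        data["water_mm"] = self.water.reshape(-1)
        return pd.DataFrame(data, index=idx).reset_index()


def run_simulation(
    forcing: pd.DataFrame,
    plant_inputs: Sequence[float],
    layers: Sequence[Layer],
    params: ModelParams,
    init_pools: PoolState,
    initial_water: str | np.ndarray = "fc",
) -> SimulationResult:
    """Run the coupled water-balance + turnover model over a monthly forcing
    frame (columns ``year, month, P_mm, T_C, PET_mm``). ``plant_inputs`` is the
    matching monthly plant C series (kg C ha^-1)."""
    from .climate import run_water_balance

    plant = np.asarray(plant_inputs, dtype=float)
    if len(plant) != len(forcing):
        raise ValueError("plant input series must match forcing length")
    wb, water = run_water_balance(
        forcing, layers, initial=initial_water, headroom=params.headroom
    )
    part = _partition_matrix(layers, params)
    temps = forcing["T_C"].to_numpy()

    n = len(forcing)
    pools_traj = np.empty((n + 1, len(layers), len(POOLS)))
    rh_traj = np.empty((n, len(layers), len(POOLS)))
    state = init_pools.copy()
    pools_traj[0] = state.stocks
    for m in range(n):
        state, flux = step_month(
            state,
            temps[m],
            water[m],
            layers,
            params,
            plant_c=plant[m],
            month_index=m,
            _partition=part,
        )
        pools_traj[m + 1] = state.stocks
        rh_traj[m] = flux.rh
    return SimulationResult(pools_traj, rh_traj, water, wb, forcing, plant)


# ---------------------------------------------------------------------------
# Spin-up
# ---------------------------------------------------------------------------

def _periodic_water(block, layers, params, max_cycles=50, tol=1e-8):
    """Water trajectory of the repeating block once the bucket state is
    periodic (cycle-to-cycle end-state change below tol)."""
    from .climate import run_water_balance

    init: str | np.ndarray = "fc"
    prev_end = None
    for _ in range(max_cycles):
        _, water = run_water_balance(block, layers, initial=init, headroom=params.headroom)
        end = water[-1]
        if prev_end is not None and np.max(np.abs(end - prev_end)) < tol:
            return water
        prev_end = end
        init = end.copy()
    return water


def spinup(
    layers: Sequence[Layer],
    block: pd.DataFrame,
    plant_inputs: Sequence[float],
    params: ModelParams,
    target_soc: Sequence[float] | None = None,
    method: str = "direct",
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> PoolState:
    """Equilibrate the pools under a repeating climate block, then rescale to
    a target SOC profile.

    The monthly update is affine in the pool vector and layers are
    independent, so the block map for each layer is ``p -> M p + c`` with M a
    4x4 matrix. ``method='direct'`` composes the map numerically and solves
    the periodic fixed point ``(I − M) p = c`` exactly; ``method='iterate'``
    repeats the block until the per-pool relative change over one block falls
    below ``tol`` (raising :class:`SpinupError` with the residual on
    non-convergence). Both use the block's periodic water trajectory.

    If ``target_soc`` (per-layer kg C ha^-1) is given, each layer's pools are
    scaled proportionally so the layer total matches it, preserving pool
    proportions.
    """
    if len(block) < 12:
        raise ValueError("spin-up block must cover at least 12 months")
    plant = np.asarray(plant_inputs, dtype=float)
    water = _periodic_water(block, layers, params)
    temps = block["T_C"].to_numpy()
    part = _partition_matrix(layers, params)

    def run_block(state: PoolState, with_inputs: bool) -> PoolState:
        s = state
        for m in range(len(block)):
            s, _ = step_month(
                s,
                temps[m],
                water[m],
                layers,
                params,
                plant_c=plant[m] if with_inputs else 0.0,
                month_index=m,
                _partition=part,
            )
        return s

    n_l = len(layers)
    if method == "direct":
        zero = PoolState(np.zeros((n_l, len(POOLS))))
        c = run_block(zero, with_inputs=True).stocks  # (L, 4)
        m_cols = []
        for j in range(len(POOLS)):
            e = np.zeros((n_l, len(POOLS)))
            e[:, j] = 1.0
            m_cols.append(run_block(PoolState(e), with_inputs=False).stocks)
        stocks = np.empty((n_l, len(POOLS)))
        for la in range(n_l):
            m_mat = np.column_stack([m_cols[j][la] for j in range(len(POOLS))])
            stocks[la] = np.linalg.solve(np.eye(len(POOLS)) - m_mat, c[la])
        state = PoolState(np.maximum(stocks, 0.0))
    elif method == "iterate":
        state = PoolState(np.full((n_l, len(POOLS)), 1000.0))
        for _ in range(max_iter):
            nxt = run_block(state, with_inputs=True)
            denom = np.maximum(np.abs(state.stocks), 1e-12)
            resid = float(np.max(np.abs(nxt.stocks - state.stocks) / denom))
            state = nxt
            if resid < tol:
                break
        else:
            raise SpinupError(
                f"spin-up did not converge in {max_iter} blocks "
                f"(residual {resid:.3e} > tol {tol:.1e})"
            )
    else:
        raise ValueError(f"unknown spin-up method {method!r}")

    if target_soc is not None:
        target = np.asarray(target_soc, dtype=float)
        if target.shape != (n_l,):
            raise ValueError("target_soc must supply one value per layer")
        totals = state.stocks.sum(axis=1)
        scale = np.where(totals > 0, target / np.maximum(totals, 1e-300), 0.0)
        state = PoolState(state.stocks * scale[:, None])
    return state
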