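"""Efficiency metrics: CUE indices, carbon sequestration efficiency, stabilisation
efficiency, depth-resolved pool deltas, and water-binned comparisons.

The carbon-use efficiency indices relate source-resolved heterotrophic
respiration to the stocks it is drawn from:

* ``CUE_I`` — respiration derived from the labile pools (DPM + RPM) per unit
  of their C content (the respiration efficiency of fresh inputs);
* ``CUE_S`` — the corresponding ratio for the stable pools (BIO + HUM);
* ``CSE = CUE_I / CUE_S`` — the carbon sequestration efficiency: an increase
  means respiration associated with labile pools dominates over that from
  stable pools, a decrease the reverse;
* ``SE = ΔHUM / ΔBIO`` — the stabilisation efficiency between consecutive
  years: positive when BIO turnover is effectively converted into HUM,
  negative when BIO and HUM move in opposite directions (pool-state
  decoupling).

Undefined values (zero denominators) are flagged as NaN and counted, never
silently dropped.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .climate import classify_zone
from .model import SimulationResult
from .scenario import ScenarioPlan

__all__ = [
    "cue_indices",
    "cse",
    "stabilisation_efficiency",
    "depth_deltas",
    "binned_cse",
    "annual_metric_table",
]


def cue_indices(
    rh_labile: np.ndarray,
    rh_stable: np.ndarray,
    labile_stock: np.ndarray,
    stable_stock: np.ndarray,
    window: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed CUE indices from monthly flux and stock series.

    Over each non-overlapping window (default 12 months, the annual
    convention): ``cue_i = sum(rh_labile) / mean(labile stock)`` and
    ``cue_s = sum(rh_stable) / mean(stable stock)``. A window with zero mean
    stock yields NaN (flagged missing) rather than an exception.

    Stocks may have length ``n`` or ``n + 1`` (trajectory including the
    initial state); the mean is taken over the months of the window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rh_l = np.asarray(rh_labile, dtype=float)
    rh_s = np.asarray(rh_stable, dtype=float)
    st_l = np.asarray(labile_stock, dtype=float)[-rh_l.size:]
    st_s = np.asarray(stable_stock, dtype=float)[-rh_l.size:]
    n_win = rh_l.size // window

    def one(rh, st):
        out = np.empty(n_win)
        for w in range(n_win):
            sl = slice(w * window, (w + 1) * window)
            denom = float(np.mean(st[sl]))
            out[w] = np.sum(rh[sl]) / denom if denom > 0 else np.nan
        return out

    return one(rh_l, st_l), one(rh_s, st_s)


def cse(cue_i, cue_s):
    """Carbon sequestration efficiency ``CUE_I / CUE_S``; NaN where
    ``CUE_S`` is zero or undefined."""
    ci = np.asarray(cue_i, dtype=float)
    cs = np.asarray(cue_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.where(cs > 0, ci / np.where(cs > 0, cs, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def stabilisation_efficiency(
    hum_series, bio_series, tol: float = 1e-9
) -> np.ndarray:
    """SE_t = (HUM_t − HUM_{t−1}) / (BIO_t − BIO_{t−1}) on annual series.

    Positive values indicate effective conversion of BIO turnover into the
    stable HUM pool; negative values indicate BIO–HUM decoupling (one pool
    rising while the other falls). Steps with |ΔBIO| below ``tol`` are flagged
    NaN and excluded from aggregates. The returned series has length
    ``len(series) − 1``.
    """
    hum = np.asarray(hum_series, dtype=float)
    bio = np.asarray(bio_series, dtype=float)
    if hum.shape != bio.shape:
        raise ValueError("HUM and BIO series must have equal length")
    if hum.size < 2:
        raise ValueError("need at least two annual values")
    d_hum = np.diff(hum)
    d_bio = np.diff(bio)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(np.abs(d_bio) > tol, d_hum / np.where(d_bio == 0, 1, d_bio), np.nan)
    return se


def depth_deltas(
    drought_pools: np.ndarray, control_pools: np.ndarray
) -> np.ndarray:
    """Percentage pool change per layer, drought vs control, at a matched
    time point (typically end of the PDRS phase).

    Inputs are (n_layers, 4) stock arrays; the result is
    ``100 (drought − control) / control`` elementwise, with NaN flagged where
    the control stock is zero.
    """
    d = np.asarray(drought_pools, dtype=float)
    c = np.asarray(control_pools, dtype=float)
    if d.shape != c.shape:
        raise ValueError("layer grids do not match")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c != 0, 100.0 * (d - c) / np.where(c == 0, 1, c), np.nan)
    return out


def binned_cse(
    series: Mapping[str, pd.DataFrame],
    baseline: str,
    bin_width: float = 2.0,
    n_boot: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Median CSE per soil-water bin and its difference from a baseline scenario.

    ``series`` maps scenario label -> frame with columns ``water`` (mm) and
    ``cse``; rows with NaN CSE are dropped (they are flagged upstream).
    Water is grouped into half-open bins ``[lo, lo + bin_width)``; within each
    bin the median CSE is computed per scenario, and for bins populated in
    both a scenario and the baseline the difference of medians ``delta_cse``
    is reported with a 95% percentile bootstrap CI over the within-bin samples.

    Returns a tidy frame (scenario, bin_lo, n, median_cse, baseline_median,
    delta_cse, ci_lo, ci_hi). An empty bin overlap yields an empty result with
    a warning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if baseline not in series:
        raise ValueError(f"baseline scenario {baseline!r} not present")
    rng = np.random.default_rng(seed)

    def binned(df):
        d = df.dropna(subset=["cse", "water"])
        lo = np.floor(d["water"].to_numpy() / bin_width) * bin_width
        return {
            b: d["cse"].to_numpy()[lo == b] for b in np.unique(lo)
        }

    base_bins = binned(series[baseline])
    rows = []
    for name, df in series.items():
        if name == baseline:
            continue
        sc_bins = binned(df)
        shared = sorted(set(sc_bins) & set(base_bins))
        for b in shared:
            x, y = sc_bins[b], base_bins[b]
            delta = float(np.median(x) - np.median(y))
            boots = np.empty(n_boot)
            for k in range(n_boot):
                boots[k] = np.median(
                    rng.choice(x, x.size, replace=True)
                ) - np.median(rng.choice(y, y.size, replace=True))
            rows.append(
                {
                    "scenario": name,
                    "bin_lo": float(b),
                    "n": int(x.size),
                    "median_cse": float(np.median(x)),
                    "baseline_median": float(np.median(y)),
                    "delta_cse": delta,
                    "ci_lo": float(np.percentile(boots, 2.5)),
                    "ci_hi": float(np.percentile(boots, 97.5)),
                }
            )
    if not rows:
        warnings.warn("no soil-water bins shared with the baseline", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "scenario", "bin_lo", "n", "median_cse",
                "baseline_median", "delta_cse", "ci_lo", "ci_hi",
            ]
        )
    return pd.DataFrame(rows)


def annual_metric_table(
    result: SimulationResult,
    plan: ScenarioPlan | None = None,
    scenario: str = "",
    window: int = 12,
) -> pd.DataFrame:
    """Tidy annual metric table for one simulation run.

    One row per window (year by default): CUE_I, CUE_S, CSE, SE, mean profile
    water, soil-water zone, phase (from the plan, ``control`` if absent), and
    end-of-year HUM/BIO totals. This is the working table consumed by the
    scenario-comparison statistics.
    """
    labile = result.pools[:, :, 0:2].sum(axis=(1, 2))
    stable = result.pools[:, :, 2:4].sum(axis=(1, 2))
    cue_i, cue_s = cue_indices(
        result.rh_labile(), result.rh_stable(), labile, stable, window=window
    )
    n_win = cue_i.size
    water = result.profile_water()[: n_win * window].reshape(n_win, window).mean(axis=1)
    hum = result.pool_totals("hum")[window::window][:n_win]
    bio = result.pool_totals("bio")[window::window][:n_win]
    hum0 = result.pool_totals("hum")[0]
    bio0 = result.pool_totals("bio")[0]
    se = stabilisation_efficiency(
        np.concatenate([[hum0], hum]), np.concatenate([[bio0], bio])
    )
    if plan is not None:
        phase = plan.schedule["phase"].to_numpy()[:n_win]
        event = plan.schedule["event"].to_numpy()[:n_win]
    else:
        phase = np.full(n_win, "control")
        event = np.zeros(n_win, dtype=int)
    return pd.DataFrame(
        {
            "scenario": scenario,
            "year": np.arange(n_win),
            "phase": phase,
            "event": event,
            "water": water,
            "zone": classify_zone(water),
            "cue_i": cue_i,
            "cue_s": cue_s,
            "cse": cse(cue_i, cue_s),
            "se": se,
            "hum": hum,
            "bio": bio,
        }
    )
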