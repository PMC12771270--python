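"""Scenario construction: tiling climate blocks and labelling drought/recovery phases.

Long-term drought-frequency experiments are built from an observed (or
synthetic) 6-year climate block: the control run tiles the block for 32 cycles
(192 years), and each drought scenario replaces the control forcing with the
drought-treatment forcing during alternating drought segments. Drought and
post-drought recovery-and-stabilisation (PDRS) segments have equal length, so
a 192-year simulation accommodates 8, 4, 2 or 1 drought events for 12-, 24-,
48- and 96-year droughts respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioPlan",
    "build_control",
    "build_scenario",
    "phase_summaries",
    "STANDARD_DROUGHT_LENGTHS",
]

BLOCK_MONTHS = 72
STANDARD_DROUGHT_LENGTHS = (12, 24, 48, 96)


@dataclass
class ScenarioPlan:
    """Phase schedule of a drought scenario.

    ``schedule`` is a frame with one row per simulation year: columns
    ``year`` (0-based), ``phase`` (``drought`` | ``pdrs``) and ``event``
    (1-based drought-event index the year belongs to).
    """

    drought_length: int
    total_years: int
    schedule: pd.DataFrame
    n_events: int

    def phase_by_month(self) -> np.ndarray:
        return np.repeat(self.schedule["phase"].to_numpy(), 12)

    def event_by_month(self) -> np.ndarray:
        return np.repeat(self.schedule["event"].to_numpy(), 12)

    def to_csv(self, path) -> None:
        self.schedule.to_csv(path, index=False)


def _check_block(block: pd.DataFrame, name: str) -> None:
    if len(block) != BLOCK_MONTHS:
        raise ValueError(
            f"{name} block must be exactly {BLOCK_MONTHS} months "
            f"(6 years), got {len(block)}"
        )


def _tile(block: pd.DataFrame, cycles: int) -> pd.DataFrame:
    out = pd.concat([block] * cycles, ignore_index=True)
    out["year"] = np.repeat(np.arange(cycles * 6), 12)
    return out


def build_control(block: pd.DataFrame, cycles: int = 32) -> pd.DataFrame:
    """Tile a 6-year monthly climate block into the control forcing series.

    The output has ``cycles * 72`` months; every cycle is an exact copy of the
    block (the ``year`` column is rewritten to run 0..6*cycles-1).
    """
    _check_block(block, "control")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    return _tile(block, cycles)


def build_scenario(
    control_block: pd.DataFrame,
    drought_block: pd.DataFrame,
    drought_length: int,
    total_years: int = 192,
    start_phase: str = "drought",
) -> tuple[pd.DataFrame, ScenarioPlan]:
    """Build a drought-scenario forcing series and its phase plan.

    The schedule starts with a drought segment and alternates drought/PDRS
    segments of equal length (``drought_length`` years) until ``total_years``
    is covered; within drought segments the drought block is tiled, elsewhere
    the control block. ``total_years`` must equal
    ``n_events * 2 * drought_length`` for an integer number of events, and
    segment lengths must be multiples of the 6-year block.
    """
    _check_block(control_block, "control")
    _check_block(drought_block, "drought")
    if drought_length <= 0 or total_years % (2 * drought_length) != 0:
        valid = [
            length
            for length in range(1, total_years + 1)
            if total_years % (2 * length) == 0 and length % 6 == 0
        ]
        raise ValueError(
            f"drought_length {drought_length} does not divide total_years "
            f"{total_years} into equal drought/PDRS pairs; valid lengths: {valid}"
        )
    if drought_length % 6 != 0:
        raise ValueError("drought_length must be a multiple of the 6-year block")
    n_events = total_years // (2 * drought_length)

    phases = []
    events = []
    order = ("drought", "pdrs") if start_phase == "drought" else ("pdrs", "drought")
    for ev in range(1, n_events + 1):
        for ph in order:
            phases.extend([ph] * drought_length)
            events.extend([ev] * drought_length)
    schedule = pd.DataFrame(
        {"year": np.arange(total_years), "phase": phases, "event": events}
    )
    plan = ScenarioPlan(drought_length, total_years, schedule, n_events)

    blocks = []
    for start in range(0, total_years, 6):
        ph = phases[start]  # segments are block-aligned, one phase per block
        blocks.append(drought_block if ph == "drought" else control_block)
    forcing = pd.concat(blocks, ignore_index=True)
    forcing["year"] = np.repeat(np.arange(total_years), 12)
    return forcing, plan


def phase_summaries(
    drought_run: pd.DataFrame,
    control_run: pd.DataFrame,
    plan: ScenarioPlan,
) -> pd.DataFrame:
    """Per-event and pooled drought-impact summaries.

    Both runs are monthly frames with identical length ``total_years * 12``
    and one column per tracked variable (e.g. pool totals). For each drought
    event the summary reports, per variable:

    * ``max_impact`` — drought-minus-control delta at the final month of the
      drought segment (the maximum impact of the event);
    * ``annual_rate_drought`` / ``annual_rate_pdrs`` — end-minus-start delta
      change over the segment divided by the segment length in years;
    * ``end_pdrs_delta`` and ``end_pdrs_pct`` — delta at the final month of
      the PDRS segment, absolute and as % of the control value there;
    * ``yearly_delta_mean`` / ``yearly_delta_sd`` — diagnostic mean and SD of
      the year-on-year delta changes within the drought segment.

    A final row block ``event = 0`` pools the per-event values (mean).
    Swapping the two runs negates every delta (antisymmetry).
    """
    if len(drought_run) != len(control_run):
        raise ValueError("runs are misaligned: different lengths")
    if len(drought_run) != plan.total_years * 12:
        raise ValueError("runs do not match the plan length")
    if list(drought_run.columns) != list(control_run.columns):
        raise ValueError("runs are misaligned: different variables")

    delta = drought_run.to_numpy(dtype=float) - control_run.to_numpy(dtype=float)
    control = control_run.to_numpy(dtype=float)
    cols = list(drought_run.columns)
    ylen = plan.drought_length

    rows = []
    for ev in range(1, plan.n_events + 1):
        d0 = (ev - 1) * 2 * ylen * 12  # first month of drought segment
        d_end = d0 + ylen * 12 - 1  # last month of drought segment
        p_end = d0 + 2 * ylen * 12 - 1  # last month of PDRS segment
        for j, col in enumerate(cols):
            start_delta = delta[d0 - 1, j] if d0 > 0 else 0.0
            yearly = delta[d0 + 11 : d_end + 1 : 12, j]
            ydiff = np.diff(np.concatenate([[start_delta], yearly]))
            ctrl_end = control[p_end, j]
            rows.append(
                {
                    "event": ev,
                    "variable": col,
                    "max_impact": delta[d_end, j],
                    "annual_rate_drought": (delta[d_end, j] - start_delta) / ylen,
                    "annual_rate_pdrs": (delta[p_end, j] - delta[d_end, j]) / ylen,
                    "end_pdrs_delta": delta[p_end, j],
                    "end_pdrs_pct": (
                        100.0 * delta[p_end, j] / ctrl_end if ctrl_end != 0 else np.nan
                    ),
                    "yearly_delta_mean": float(np.mean(ydiff)),
                    "yearly_delta_sd": float(np.std(ydiff, ddof=1))
                    if ydiff.size > 1
                    else np.nan,
                }
            )
    per_event = pd.DataFrame(rows)
    pooled = (
        per_event.groupby("variable", sort=False)
        .mean(numeric_only=True)
        .reset_index()
        .assign(event=0)
    )
    return pd.concat([per_event, pooled[per_event.columns]], ignore_index=True)
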