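"""End-to-end orchestration: configuration, site setup, scenario runs, analysis.

This module ties the stages into one reproducible pipeline:

1. ``synth`` — generate a fixture workspace (climate blocks, plant inputs,
   profile table) from a seed;
2. ``run`` — discretize the profile, spin the pool model up to a periodic
   steady state under the control block, rescale to the site SOC stock, and
   simulate the control series plus the requested drought scenarios;
3. ``analyse`` — compute the annual metric tables, phase summaries,
   depth-resolved pool deltas, water-binned CSE comparisons, scenario
   statistics, stabilisation-efficiency bootstrap intervals and the
   uncertainty envelope, writing tidy delimited reports.

Every stage is a plain function usable from Python; the CLI wraps them thinly.
Outputs carry a commented header with the configuration hash and seed so a
run is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as mx
from . import model as md
from . import profile as pr
from . import scenario as sc
from . import stats as st
from .synth import SynthConfig, generate_climate, generate_plant_inputs

__all__ = ["RunConfig", "setup_site", "run_experiment", "analyse", "ExperimentResult", "pool_frame"]

log = logging.getLogger("droughtsoc")


@dataclass
class RunConfig:
    """Pipeline configuration. Defaults reproduce the standard study design:
    a 6-year block tiled to 192 years with drought lengths 12/24/48/96."""

    seed: int = 0
    outdir: str = "runs"
    total_years: int = 192
    drought_lengths: tuple = (12, 24, 48, 96)
    layer_thickness_cm: float = 5.0
    capacity_mode: str = "prescribed"
    prescribed_capacities_mm: tuple = tuple(pr.CLOCAENOG_LAYER_FC_MM)
    cue_window_months: int = 12
    cse_bin_mm: float = 2.0
    paired_bin_mm: float = 10.0
    baseline_scenario: str = "96-year"
    alpha: float = 0.05
    synth: SynthConfig = field(default_factory=SynthConfig)
    params: md.ModelParams = field(default_factory=md.ModelParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        params = md.ModelParams(**raw.pop("params", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise pr.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "drought_lengths" in raw:
            raw["drought_lengths"] = tuple(raw["drought_lengths"])
        if "prescribed_capacities_mm" in raw:
            raw["prescribed_capacities_mm"] = tuple(raw["prescribed_capacities_mm"])
        return cls(synth=synth, params=params, **raw)

    def digest(self) -> str:
        payload = json.dumps(
            {
                **{
                    k: v
                    for k, v in dataclasses.asdict(self).items()
                    if k not in ("synth", "params")
                },
                "synth": dataclasses.asdict(self.synth),
                "params": dataclasses.asdict(self.params),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# droughtsoc config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def setup_site(cfg: RunConfig) -> list[pr.Layer]:
    """Discretize the site horizon table and attach water capacities."""
    horizons = pr.clocaenog_horizons()
    layers = pr.discretize_profile(horizons, cfg.layer_thickness_cm)
    if cfg.capacity_mode == "prescribed":
        layers = pr.layer_capacities(
            layers, "prescribed", list(cfg.prescribed_capacities_mm)
        )
    else:
        layers = pr.layer_capacities(layers, "pedotransfer")
    return layers


@dataclass
class ExperimentResult:
    """All artefacts of one run: layers, blocks, spun-up state, and the control
    plus per-scenario simulation results and plans."""

    layers: list
    control_block: pd.DataFrame
    drought_block: pd.DataFrame
    inputs_control: np.ndarray
    inputs_drought: np.ndarray
    init_state: md.PoolState
    control: md.SimulationResult
    scenarios: dict  # label -> (SimulationResult, ScenarioPlan)


def scenario_label(length: int) -> str:
    return f"{length}-year"


def run_experiment(
    cfg: RunConfig,
    drought_lengths: tuple | None = None,
    input_multipliers: dict | None = None,
) -> ExperimentResult:
    """Run the control and drought-scenario simulations.

    ``input_multipliers`` (keys ``soc_t0, clay, p, temp, pet``) perturbs the
    inputs multiplicatively — used by the uncertainty envelope; the central
    run uses all-ones.
    """
    mult = {"soc_t0": 1.0, "clay": 1.0, "p": 1.0, "temp": 1.0, "pet": 1.0}
    if input_multipliers:
        mult.update(input_multipliers)
    lengths = drought_lengths if drought_lengths is not None else cfg.drought_lengths

    layers = setup_site(cfg)
    if mult["clay"] != 1.0:
        layers = [
            dataclasses.replace(la, clay=min(la.clay * mult["clay"], 100.0))
            for la in layers
        ]
    control_block, drought_block = generate_climate(cfg.synth)
    in_ctrl, in_drt = generate_plant_inputs(cfg.synth)
    for block in (control_block, drought_block):
        block["P_mm"] *= mult["p"]
        block["T_C"] *= mult["temp"]
        block["PET_mm"] *= mult["pet"]

    target = np.array([la.soc_stock for la in layers]) * mult["soc_t0"]
    init = md.spinup(layers, control_block, in_ctrl, cfg.params, target_soc=target)
    log.info("spun-up SOC %.0f kg C/ha over %d layers", init.total_soc, len(layers))

    cycles = cfg.total_years // 6
    control_forcing = sc.build_control(control_block, cycles)
    control_inputs = np.tile(in_ctrl, cycles)
    control_run = md.run_simulation(
        control_forcing, control_inputs, layers, cfg.params, init
    )

    scenarios = {}
    for length in lengths:
        forcing, plan = sc.build_scenario(
            control_block, drought_block, length, cfg.total_years
        )
        inputs = np.where(
            plan.phase_by_month() == "drought",
            np.tile(in_drt, cycles),
            np.tile(in_ctrl, cycles),
        )
        run = md.run_simulation(forcing, inputs, layers, cfg.params, init)
        scenarios[scenario_label(length)] = (run, plan)
        log.info("scenario %s: %d events", scenario_label(length), plan.n_events)

    return ExperimentResult(
        layers,
        control_block,
        drought_block,
        in_ctrl,
        in_drt,
        init,
        control_run,
        scenarios,
    )


def pool_frame(run: md.SimulationResult) -> pd.DataFrame:
    """Monthly profile totals per pool plus total SOC (end-of-month)."""
    return pd.DataFrame(
        {p: run.pool_totals(p)[1:] for p in md.POOLS}
        | {"soc": run.soc_total()[1:]}
    )


def analyse(
    cfg: RunConfig,
    exp: ExperimentResult,
    outdir: str | Path | None = None,
    uncertainty: bool = False,
) -> dict:
    """Compute all analysis products for one experiment.

    Returns a dict of frames/objects: ``metrics`` (stacked annual metric
    tables), ``phase_summaries``, ``depth_deltas``, ``binned_cse``,
    ``zone_tests``, ``paired_tests``, ``ancova``, ``se_bootstrap`` and,
    when requested, ``uncertainty`` (a three-run envelope on the longest
    drought scenario). Writes delimited reports when ``outdir`` is given.
    """
    tables = [
        mx.annual_metric_table(
            exp.control, None, scenario="control", window=cfg.cue_window_months
        )
    ]
    for label, (run, plan) in exp.scenarios.items():
        tables.append(
            mx.annual_metric_table(run, plan, scenario=label, window=cfg.cue_window_months)
        )
    metric_table = pd.concat(tables, ignore_index=True)
    n_missing = int(metric_table[["cse", "se"]].isna().sum().sum())
    if n_missing:
        log.warning("%d flagged-missing metric cells (zero denominators)", n_missing)

    control_frame = pool_frame(exp.control)
    summaries = []
    deltas = []
    for label, (run, plan) in exp.scenarios.items():
        s = sc.phase_summaries(pool_frame(run), control_frame, plan)
        s.insert(0, "scenario", label)
        summaries.append(s)
        dd = mx.depth_deltas(run.pools[-1], exp.control.pools[-1])
        deltas.append(
            pd.DataFrame(dd, columns=[f"{p}_pct" for p in md.POOLS]).assign(
                scenario=label, layer=np.arange(1, dd.shape[0] + 1)
            )
        )
    phase_summary = pd.concat(summaries, ignore_index=True)
    depth_delta = pd.concat(deltas, ignore_index=True)

    scen_only = metric_table[metric_table["scenario"] != "control"]
    series = {
        label: g[["water", "cse"]] for label, g in scen_only.groupby("scenario")
    }
    results: dict = {
        "metrics": metric_table,
        "phase_summaries": phase_summary,
        "depth_deltas": depth_delta,
    }
    if cfg.baseline_scenario in series and len(series) > 1:
        results["binned_cse"] = mx.binned_cse(
            series, cfg.baseline_scenario, cfg.cse_bin_mm, seed=cfg.seed
        )
        results["paired_tests"] = st.paired_bin_tests(
            scen_only, cfg.baseline_scenario, bin_width=cfg.paired_bin_mm,
            alpha=cfg.alpha,
        )
    results["zone_tests"] = st.zone_scenario_tests(scen_only, alpha=cfg.alpha)
    try:
        results["ancova"] = st.ancova_phase(scen_only)
    except ValueError as exc:
        log.warning("ANCOVA skipped: %s", exc)

    se_rows = []
    for label, g in metric_table.groupby("scenario"):
        se_vals = g["se"].to_numpy()
        if np.sum(~np.isnan(se_vals)) >= 6:
            estimate, lo, hi = st.block_bootstrap_ci(
                se_vals, np.mean, 6, n_boot=1000, seed=cfg.seed
            )
            se_rows.append(
                {"scenario": label, "se_mean": estimate, "ci_lo": lo, "ci_hi": hi}
            )
    results["se_bootstrap"] = pd.DataFrame(se_rows)

    if uncertainty:
        longest = max(cfg.drought_lengths)

        def runner(mult):
            e = run_experiment(cfg, drought_lengths=(longest,), input_multipliers=mult)
            run, _ = e.scenarios[scenario_label(longest)]
            return run.soc_total()[-1]

        results["uncertainty"] = st.uncertainty_envelope(runner)

    if outdir is not None:
        out = Path(outdir)
        for name in (
            "metrics", "phase_summaries", "depth_deltas", "binned_cse",
            "zone_tests", "paired_tests", "se_bootstrap",
        ):
            if name in results:
                _write(results[name], out / f"{name}.csv", cfg)
        manifest = {
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "scenarios": list(exp.scenarios),
            "n_events": {
                label: plan.n_events for label, (_, plan) in exp.scenarios.items()
            },
        }
        if "ancova" in results:
            a = results["ancova"]
            manifest["ancova"] = {
                "slope_drought": a.slope_drought,
                "slope_pdrs": a.slope_pdrs,
                "interaction_p": a.interaction_p,
            }
        if "uncertainty" in results:
            u = results["uncertainty"]
            manifest["uncertainty_pct"] = u.u_percent
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
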