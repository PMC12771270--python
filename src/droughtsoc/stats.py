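"""Uncertainty envelope, goodness-of-fit statistics, and scenario-comparison tests.

The uncertainty envelope brackets a simulation with two additional runs using
a predefined arrangement of multiplicative input perturbations (air
temperature +-2%, PET +-2%, precipitation +-5%, clay +-10%, initial SOC
+-20%): the "max" arrangement combines the perturbations that raise the
simulated SOC stock, the "min" arrangement those that lower it, and the
uncertainty is

    U% = 100 * (SOC_max - SOC_min) / (2 * SOC)

evaluated at the end of the forward simulation.

Scenario comparisons use non-parametric tests: a Kruskal-Wallis test across
scenarios within each soil-water zone, followed (when significant) by
pairwise Wilcoxon rank-sum tests with Benjamini-Hochberg FDR adjustment and a
compact letter display; paired Wilcoxon signed-rank tests on median CSE in
matched 10-mm water bins against a baseline scenario; an ANCOVA
(CSE ~ water x phase) testing whether the CSE-water slope differs between
drought and post-drought phases; and 6-year block-bootstrap confidence
intervals for annual series.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UncertaintyConfig",
    "UncertaintyResult",
    "EvalStats",
    "uncertainty_envelope",
    "fit_stats",
    "zone_scenario_tests",
    "paired_bin_tests",
    "ancova_phase",
    "block_bootstrap_ci",
]


# ---------------------------------------------------------------------------
# Uncertainty envelope
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertaintyConfig:
    """Multiplicative uncertainty factors for the main model inputs."""

    temp: float = 0.02
    pet: float = 0.02
    p: float = 0.05
    clay: float = 0.10
    soc_t0: float = 0.20

    def __post_init__(self) -> None:
        if min(self.temp, self.pet, self.p, self.clay, self.soc_t0) <= -1.0:
            raise ValueError("uncertainty factors must keep multipliers positive")

    def arrangement(self, which: str) -> dict[str, float]:
        """Input multipliers for the ``central``, ``max`` or ``min`` run.

        The max-SOC arrangement raises initial SOC, clay and precipitation and
        lowers temperature and PET; the min arrangement is the mirror image.
        """
        if which == "central":
            return {k: 1.0 for k in ("soc_t0", "clay", "p", "temp", "pet")}
        if which == "max":
            return {
                "soc_t0": 1.0 + self.soc_t0,
                "clay": 1.0 + self.clay,
                "p": 1.0 + self.p,
                "temp": 1.0 - self.temp,
                "pet": 1.0 - self.pet,
            }
        if which == "min":
            return {
                "soc_t0": 1.0 - self.soc_t0,
                "clay": 1.0 - self.clay,
                "p": 1.0 - self.p,
                "temp": 1.0 + self.temp,
                "pet": 1.0 + self.pet,
            }
        raise ValueError(f"unknown arrangement {which!r}")


@dataclass
class UncertaintyResult:
    soc_central: float
    soc_max: float
    soc_min: float
    u_percent: float
    ordered: bool = True  # soc_min <= soc_central <= soc_max held


def uncertainty_envelope(
    runner: Callable[[Mapping[str, float]], float],
    cfg: UncertaintyConfig = UncertaintyConfig(),
) -> UncertaintyResult:
    """Run the three-simulation uncertainty envelope.

    ``runner`` maps an input-multiplier dict (keys ``soc_t0, clay, p, temp,
    pet``) to the end-of-simulation SOC stock and must be deterministic. The
    envelope runs exactly three simulations (central, max, min) and applies
    U% = 100 (SOC_max − SOC_min) / (2 SOC). If the arrangements do not bracket
    the central run the violation is reported via ``ordered=False``, not
    hidden.
    """
    values = {}
    for which in ("central", "max", "min"):
        try:
            values[which] = float(runner(cfg.arrangement(which)))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"model runner failed for {which!r} arrangement") from exc
    soc, soc_max, soc_min = values["central"], values["max"], values["min"]
    u = 100.0 * (soc_max - soc_min) / (2.0 * soc)
    ordered = soc_min <= soc <= soc_max
    if not ordered:
        warnings.warn(
            "uncertainty arrangements do not bracket the central run "
            f"(min={soc_min:.6g}, central={soc:.6g}, max={soc_max:.6g})",
            stacklevel=2,
        )
    return UncertaintyResult(soc, soc_max, soc_min, u, ordered)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class EvalStats:
    n: int
    rmse: float
    mbe: float
    r2: float  # NaN when undefined (zero variance)


def fit_stats(observed: Sequence[float], predicted: Sequence[float]) -> EvalStats:
    """RMSE, mean bias error and R^2 between observed and predicted series.

    ``mbe = mean(O − P)``: negative values indicate overestimation by the
    model, positive underestimation. ``r2`` is the squared Pearson
    correlation, flagged NaN when either series has zero variance.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 1:
        raise ValueError("series must have equal, non-zero length")
    rmse = float(np.sqrt(np.mean((o - p) ** 2)))
    mbe = float(np.mean(o - p))
    if o.size >= 2 and np.std(o) > 0 and np.std(p) > 0:
        r2 = float(np.corrcoef(o, p)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return EvalStats(o.size, rmse, mbe, r2)


# ---------------------------------------------------------------------------
# Scenario comparison tests
# ---------------------------------------------------------------------------

def _compact_letters(
    groups: Sequence[str], different: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different. Insert-and-absorb construction over the ordered group list."""
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all((g, m) not in different and (m, g) not in different for m in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for s, ch in zip(letter_sets, letters):
        for g in groups:
            if g in s:
                out[g] += ch
    return out


def zone_scenario_tests(
    table: pd.DataFrame,
    value: str = "cse",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis + pairwise Wilcoxon rank-sum comparisons per soil-water zone.

    ``table`` needs columns ``zone``, ``scenario`` and the value column; NaN
    values are dropped with a count. Within each zone an overall
    Kruskal-Wallis test is run across scenarios; pairwise rank-sum tests are
    run only when the overall test is significant at ``alpha``, and their
    p-values are Benjamini-Hochberg adjusted. Both raw and adjusted p-values
    are reported (contrasts may be indicative even when nothing survives
    adjustment), along with a compact letter display per zone.

    Returns a tidy frame: one ``kruskal`` row per zone plus one ``wilcoxon``
    row per tested contrast (zone, test, contrast, statistic, p_raw, p_adj,
    letters).
    """
    rows = []
    d = table.dropna(subset=[value])
    for zone, zd in d.groupby("zone", sort=False):
        samples = {
            sc: g[value].to_numpy() for sc, g in zd.groupby("scenario", sort=False)
        }
        names = list(samples)
        if len(names) < 2 or any(v.size < 2 for v in samples.values()):
            continue
        arrays = list(samples.values())
        if np.ptp(np.concatenate(arrays)) == 0:
            kw_stat, kw_p = 0.0, 1.0  # degenerate all-tied data
        else:
            kw_stat, kw_p = sps.kruskal(*arrays)
        letters = {n: "a" for n in names}
        pair_rows = []
        if kw_p < alpha:
            pairs = list(itertools.combinations(names, 2))
            praw = []
            stats_ = []
            for a, b in pairs:
                res = sps.mannwhitneyu(
                    samples[a], samples[b], alternative="two-sided"
                )
                stats_.append(float(res.statistic))
                praw.append(float(res.pvalue))
            padj = multipletests(praw, method="fdr_bh")[1]
            different = {
                pair for pair, pa in zip(pairs, padj) if pa < alpha
            }
            letters = _compact_letters(names, different)
            for (a, b), st, pr, pa in zip(pairs, stats_, praw, padj):
                pair_rows.append(
                    {
                        "zone": zone,
                        "test": "wilcoxon",
                        "contrast": f"{a} vs {b}",
                        "statistic": st,
                        "p_raw": pr,
                        "p_adj": float(pa),
                        "letters": "",
                    }
                )
        rows.append(
            {
                "zone": zone,
                "test": "kruskal",
                "contrast": " | ".join(f"{n}:{letters[n]}" for n in names),
                "statistic": float(kw_stat),
                "p_raw": float(kw_p),
                "p_adj": float(kw_p),
                "letters": "".join(sorted(set("".join(letters.values())))),
            }
        )
        rows.extend(pair_rows)
    return pd.DataFrame(
        rows, columns=["zone", "test", "contrast", "statistic", "p_raw", "p_adj", "letters"]
    )


def paired_bin_tests(
    table: pd.DataFrame,
    baseline: str,
    value: str = "cse",
    bin_width: float = 10.0,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests on per-bin medians against a baseline.

    ``table`` needs columns ``scenario``, ``water``, ``zone`` and the value
    column. Within each zone, the value is aggregated to its median within
    matched ``bin_width``-mm soil-water bins per scenario; only bins present
    in both the scenario and the baseline enter the signed-rank test. Tests
    with fewer than two shared bins, or with all differences zero, are flagged
    untestable (``p_raw`` NaN) rather than dropped. P-values are BH-adjusted
    within each zone.
    """
    d = table.dropna(subset=[value, "water"]).copy()
    d["bin"] = np.floor(d["water"] / bin_width) * bin_width
    rows = []
    for zone, zd in d.groupby("zone", sort=False):
        med = zd.groupby(["scenario", "bin"])[value].median()
        if baseline not in med.index.get_level_values(0):
            continue
        base = med.loc[baseline]
        zone_rows = []
        for sc in med.index.get_level_values(0).unique():
            if sc == baseline:
                continue
            mine = med.loc[sc]
            shared = mine.index.intersection(base.index)
            if len(shared) < 2:
                zone_rows.append((sc, len(shared), np.nan, "too few shared bins"))
                continue
            x = mine.loc[shared].to_numpy()
            y = base.loc[shared].to_numpy()
            if np.allclose(x, y):
                zone_rows.append((sc, len(shared), np.nan, "all differences zero"))
                continue
            res = sps.wilcoxon(x, y, alternative=alternative, zero_method="wilcox")
            zone_rows.append((sc, len(shared), float(res.pvalue), ""))
        testable = [r for r in zone_rows if not np.isnan(r[2])]
        padj = (
            multipletests([r[2] for r in testable], method="fdr_bh")[1]
            if testable
            else []
        )
        adj_map = {r[0]: float(p) for r, p in zip(testable, padj)}
        for sc, n_bins, praw, flag in zone_rows:
            rows.append(
                {
                    "zone": zone,
                    "contrast": f"{sc} vs {baseline}",
                    "n_bins": n_bins,
                    "p_raw": praw,
                    "p_adj": adj_map.get(sc, np.nan),
                    "significant": adj_map.get(sc, np.nan) < alpha
                    if sc in adj_map
                    else False,
                    "flag": flag,
                }
            )
    return pd.DataFrame(
        rows, columns=["zone", "contrast", "n_bins", "p_raw", "p_adj", "significant", "flag"]
    )


@dataclass
class AncovaResult:
    slope_drought: float
    slope_pdrs: float
    interaction_p: float
    model: object = field(repr=False, default=None)


def ancova_phase(
    table: pd.DataFrame,
    value: str = "cse",
    water: str = "water",
    phase: str = "phase",
) -> AncovaResult:
    """ANCOVA of metric ~ soil water x phase (drought vs post-drought).

    Fits an ordinary least squares model with interaction across all supplied
    rows and reports the phase-specific water slopes and the interaction
    p-value: a significant interaction means the metric's sensitivity to soil
    water differs between phases (e.g. positive during drought, negative
    after rewetting).
    """
    d = table.dropna(subset=[value, water]).copy()
    phases = sorted(d[phase].unique())
    if len(phases) != 2:
        raise ValueError(f"need exactly two phases, got {phases}")
    if any(d.loc[d[phase] == ph, water].std() == 0 for ph in phases):
        raise ValueError("no soil-water variance within a phase")
    d = d.rename(columns={value: "_y", water: "_w", phase: "_ph"})
    fit = ols("_y ~ _w * C(_ph)", data=d).fit()
    ref, other = phases
    slope_ref = fit.params["_w"]
    inter_name = f"_w:C(_ph)[T.{other}]"
    slope_other = slope_ref + fit.params[inter_name]
    slopes = {ref: float(slope_ref), other: float(slope_other)}
    return AncovaResult(
        slope_drought=slopes.get("drought", float(slope_ref)),
        slope_pdrs=slopes.get("pdrs", float(slope_other)),
        interaction_p=float(fit.pvalues[inter_name]),
        model=fit,
    )


def block_bootstrap_ci(
    series: Sequence[float],
    stat: Callable[[np.ndarray], float] = np.mean,
    block_years: int = 6,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile CI for a statistic of an annual series by block bootstrap.

    Contiguous ``block_years``-long blocks (moving blocks, overlapping) are
    resampled with replacement and concatenated to the series length; the
    2.5/97.5 percentiles of the resampled statistic give the 95% interval.
    Seeded and reproducible. Returns ``(estimate, lo95, hi95)``.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < block_years:
        raise ValueError("series shorter than one block")
    if n_boot < 100:
        warnings.warn("n_boot < 100: interval will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = x.size
    starts_max = n - block_years + 1
    n_blocks = int(np.ceil(n / block_years))
    est = float(stat(x))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        sample = np.concatenate([x[s : s + block_years] for s in starts])[:n]
        boots[i] = stat(sample)
    return est, float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))
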