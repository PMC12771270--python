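import numpy as np
import pandas as pd
import pytest

from droughtsoc.stats import (
    UncertaintyConfig,
    ancova_phase,
    block_bootstrap_ci,
    fit_stats,
    paired_bin_tests,
    uncertainty_envelope,
    zone_scenario_tests,
)


class TestUncertaintyEnvelope:
    def test_arrangements_match_predefined_factors(self):
        cfg = UncertaintyConfig()
        assert cfg.arrangement("max") == {
            "soc_t0": 1.2, "clay": 1.1, "p": 1.05, "temp": 0.98, "pet": 0.98
        }
        assert cfg.arrangement("min") == {
            "soc_t0": 0.8, "clay": 0.9, "p": 0.95, "temp": 1.02, "pet": 1.02
        }

    def test_worked_triple(self):
        # a runner landing on (central, max, min) = (100, 110, 90) gives U% = 10
        def runner(mult):
            if mult["soc_t0"] == 1.0:
                return 100.0
            return 110.0 if mult["soc_t0"] > 1.0 else 90.0

        res = uncertainty_envelope(runner)
        assert res.u_percent == pytest.approx(10.0)
        assert res.ordered

    def test_degenerate_runner_zero_uncertainty(self):
        res = uncertainty_envelope(lambda mult: 42.0)
        assert res.u_percent == pytest.approx(0.0)

    def test_soc_passthrough_gives_twenty_percent(self):
        # a runner that just returns the (perturbed) initial SOC: U% = 20
        res = uncertainty_envelope(lambda mult: 1234.5 * mult["soc_t0"])
        assert res.u_percent == pytest.approx(20.0)

    def test_exactly_three_runs(self):
        calls = []
        uncertainty_envelope(lambda mult: calls.append(1) or 1.0)
        assert len(calls) == 3

    def test_runner_failure_annotated(self):
        def runner(mult):
            if mult["soc_t0"] > 1.0:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match="'max' arrangement"):
            uncertainty_envelope(runner)

    def test_unordered_envelope_reported_not_hidden(self):
        def runner(mult):
            return {1.0: 100.0, 1.2: 90.0, 0.8: 110.0}[mult["soc_t0"]]

        with pytest.warns(UserWarning, match="do not bracket"):
            res = uncertainty_envelope(runner)
        assert not res.ordered
        assert res.u_percent == pytest.approx(-10.0)


class TestFitStats:
    def test_perfect_fit(self):
        s = fit_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.rmse == 0.0 and s.mbe == 0.0 and s.r2 == pytest.approx(1.0)

    def test_overestimation_sign_convention(self):
        # model above the data -> negative MBE
        s = fit_stats([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert s.mbe == pytest.approx(-1.0)

    def test_rmse_mbe_arithmetic(self):
        s = fit_stats([0.0, 0.0], [3.0, -3.0])
        assert s.rmse == pytest.approx(3.0)
        assert s.mbe == pytest.approx(0.0)

    def test_rmse_dominates_mbe(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            o, p = rng.normal(size=30), rng.normal(size=30)
            s = fit_stats(o, p)
            assert s.rmse >= abs(s.mbe) - 1e-12

    def test_zero_variance_r2_flagged(self):
        s = fit_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(s.r2)


def _zone_table(samples_by_scenario, zone="Dry"):
    rows = []
    for sc, vals in samples_by_scenario.items():
        rows.extend({"zone": zone, "scenario": sc, "cse": v} for v in vals)
    return pd.DataFrame(rows)


class TestZoneScenarioTests:
    def test_identical_distributions_single_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.1, 40)
        table = _zone_table({s: base for s in ("12", "24", "48", "96")})
        out = zone_scenario_tests(table)
        kw = out[out["test"] == "kruskal"].iloc[0]
        assert kw["p_raw"] > 0.9
        assert kw["letters"] == "a"

    def test_separated_scenarios_distinct_letters(self):
        rng = np.random.default_rng(1)
        table = _zone_table(
            {"a": rng.normal(0, 1, 50), "b": rng.normal(10, 1, 50)}
        )
        out = zone_scenario_tests(table)
        pair = out[out["test"] == "wilcoxon"].iloc[0]
        assert pair["p_adj"] < 1e-3
        kw = out[out["test"] == "kruskal"].iloc[0]
        assert "a" in kw["contrast"] and "b" in kw["contrast"]
        assert len(set(kw["letters"])) == 2

    def test_all_tied_data_no_crash(self):
        table = _zone_table({s: [1.0, 1.0, 1.0] for s in ("a", "b", "c")})
        out = zone_scenario_tests(table)
        assert out[out["test"] == "kruskal"]["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_raw_and_adjusted_both_reported(self):
        rng = np.random.default_rng(3)
        table = _zone_table(
            {"a": rng.normal(0, 1, 30), "b": rng.normal(1.2, 1, 30),
             "c": rng.normal(0.1, 1, 30)}
        )
        out = zone_scenario_tests(table)
        pairs = out[out["test"] == "wilcoxon"]
        assert {"p_raw", "p_adj"} <= set(pairs.columns)
        assert (pairs["p_adj"] >= pairs["p_raw"] - 1e-12).all()


class TestPairedBinTests:
    def _table(self, offsets, zone="Moderate", water0=80.0, n_bins=8):
        rows = []
        for sc, off in offsets.items():
            for b in range(n_bins):
                rows.append(
                    {"zone": zone, "scenario": sc,
                     "water": water0 + 10.0 * b + 1.0,
                     "cse": 1.0 + off * (1 + 0.01 * b)}
                )
        return pd.DataFrame(rows)

    def test_identical_scenario_flagged_untestable(self):
        table = self._table({"a": 0.0, "base": 0.0})
        out = paired_bin_tests(table, "base")
        assert np.isnan(out["p_raw"].iloc[0])
        assert out["flag"].iloc[0] == "all differences zero"

    def test_constant_offset_exact_signed_rank_p(self):
        # +0.2 in all 8 shared bins: one-sided exact p = 1 / 2^8
        table = self._table({"a": 0.2, "base": 0.0})
        out = paired_bin_tests(table, "base", alternative="greater")
        assert out["p_raw"].iloc[0] == pytest.approx(1.0 / 2**8)

    def test_disjoint_bins_untestable(self):
        a = pd.DataFrame(
            {"zone": "Dry", "scenario": "a", "water": [10.0, 20.0], "cse": 1.0}
        )
        b = pd.DataFrame(
            {"zone": "Dry", "scenario": "base", "water": [50.0, 60.0], "cse": 1.0}
        )
        out = paired_bin_tests(pd.concat([a, b]), "base")
        assert out["flag"].iloc[0] == "too few shared bins"


class TestAncova:
    def _synthetic(self, slope_d, slope_p, n=200, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        water = rng.uniform(60, 120, n)
        phase = np.where(np.arange(n) % 2 == 0, "drought", "pdrs")
        slope = np.where(phase == "drought", slope_d, slope_p)
        cse_vals = 1.0 + slope * water + rng.normal(0, noise, n)
        return pd.DataFrame({"water": water, "phase": phase, "cse": cse_vals})

    def test_parameter_recovery_and_interaction(self):
        table = self._synthetic(+0.01, -0.01)
        res = ancova_phase(table)
        se = res.model.bse["_w"]
        assert abs(res.slope_drought - 0.01) < 3 * se
        assert abs(res.slope_pdrs + 0.01) < 3 * se
        assert res.interaction_p < 0.01

    def test_zero_noise_exact_recovery(self):
        table = self._synthetic(0.02, -0.03, noise=0.0)
        res = ancova_phase(table)
        assert res.slope_drought == pytest.approx(0.02, abs=1e-10)
        assert res.slope_pdrs == pytest.approx(-0.03, abs=1e-10)

    def test_null_interaction_p_roughly_uniform(self):
        # identical slopes in both phases: interaction p ~ U(0,1)
        ps = []
        for seed in range(200):
            table = self._synthetic(0.01, 0.01, n=60, noise=0.05, seed=seed)
            ps.append(ancova_phase(table).interaction_p)
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.0 <= rate <= 0.11  # 3-sigma binomial band around 0.05

    def test_single_phase_rejected(self):
        table = self._synthetic(0.01, 0.01)
        with pytest.raises(ValueError, match="two phases"):
            ancova_phase(table[table["phase"] == "drought"])


class TestBlockBootstrap:
    def test_constant_series_zero_width(self):
        est, lo, hi = block_bootstrap_ci(np.full(60, 3.3), seed=0)
        assert est == lo == hi == pytest.approx(3.3)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        a = block_bootstrap_ci(x, seed=123)
        b = block_bootstrap_ci(x, seed=123)
        assert a == b

    def test_coverage_on_iid_noise(self):
        # CI for the mean of N(0,1), length 60: ~95% of intervals cover 0
        rng = np.random.default_rng(8)
        cover = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=60)
            _, lo, hi = block_bootstrap_ci(
                x, n_boot=200, seed=int(rng.integers(2**31))
            )
            cover += lo <= 0.0 <= hi
        # the moving-block interval is systematically short here: 60 years at
        # 6-year blocks give only ~10 independent blocks, so the percentile CI
        # behaves like a z-interval with ~9 df (true coverage ~88%, vs ~96%
        # for the iid bootstrap at the same n); allow that plus binomial noise
        assert 0.84 <= cover / reps <= 0.99

    def test_short_series_rejected_and_low_nboot_warns(self):
        with pytest.raises(ValueError):
            block_bootstrap_ci(np.ones(3))
        with pytest.warns(UserWarning, match="n_boot"):
            block_bootstrap_ci(np.ones(12), n_boot=50, seed=0)
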