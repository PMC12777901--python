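"""Replication sizing, scenario comparison and sensitivity analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from afsim import (NotConvergedError, ReplicationResult, ScenarioSpec,
                   SensitivityGrid, ZeroMeanError, compare_scenarios,
                   min_replications, min_replications_trace, run_experiment,
                   scale_parameter, sensitivity_oneway, toy_config)
from afsim.engine import OUTPUTS


def rule_oracle(x, precision=0.01, confidence=0.95, min_reps=3):
    """Brute-force re-statement of the CI precision rule, written from the
    definition with stdlib statistics, independent of the implementation."""
    import statistics
    for n in range(min_reps, len(x) + 1):
        prev_mean = statistics.fmean(x[:n - 1])
        mean = statistics.fmean(x[:n])
        sd = statistics.stdev(x[:n])
        upper = mean + stats.t.ppf((1 + confidence) / 2, n - 1) * sd / math.sqrt(n)
        if prev_mean != 0 and abs(upper - prev_mean) / abs(prev_mean) < precision:
            return n
    return None


class TestMinReplications:
    def test_constant_stream_returns_min_reps(self):
        assert min_replications([7.0] * 10) == 3
        assert min_replications([7.0] * 10, min_reps=5) == 5

    def test_agrees_with_bruteforce_oracle_on_random_streams(self):
        rng = np.random.default_rng(314)
        checked = 0
        for _ in range(1000):
            x = rng.lognormal(mean=3.0, sigma=rng.uniform(0.005, 0.1),
                              size=60).tolist()
            expected = rule_oracle(x)
            if expected is None:
                with pytest.raises(NotConvergedError):
                    min_replications(x)
            else:
                assert min_replications(x) == expected
                checked += 1
        assert checked > 100  # the comparison actually exercised the rule

    def test_zero_mean_signalled(self):
        with pytest.raises(ZeroMeanError):
            min_replications([0.0, 0.0, 0.0, 0.0])
        assert min_replications([0.0] * 5, fallback_absolute=True) == 3

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError):
            min_replications([1.0, 2.0])

    def test_trace_matches_rule(self):
        rng = np.random.default_rng(9)
        x = rng.normal(100, 1, size=30)
        trace = min_replications_trace(x)
        n = min_replications(x)
        first_ok = trace[trace["rel_diff"] < 0.01]["n"].iloc[0]
        assert first_ok == n


def fake_results(values_by_output, snapshots=(1,)):
    """Build ReplicationResult stubs carrying one value per output/snapshot."""
    n = len(next(iter(values_by_output.values())))
    out = []
    for i in range(n):
        snaps = {}
        for s in snapshots:
            snaps[s] = {o: values_by_output.get(o, [0.0] * n)[i]
                        for o in OUTPUTS}
        out.append(ReplicationResult(snapshots=snaps, final_year=1,
                                     seed_key=(i,)))
    return out


class TestCompareScenarios:
    def test_identical_sets_give_zero_difference(self):
        base = fake_results({"strokes": [10.0, 12.0, 9.0, 11.0]})
        cmp = compare_scenarios(base, base, paired=True)
        assert (cmp.table["mean_diff"] == 0).all()
        assert (cmp.table["ci_half_width"] == 0).all()

    def test_constant_offset_recovered_exactly(self):
        base = fake_results({"strokes": [10.0, 12.0, 9.0, 11.0]})
        alt = fake_results({"strokes": [13.0, 15.0, 12.0, 14.0]})
        cmp = compare_scenarios(base, alt, paired=True)
        row = cmp.row("strokes", 1)
        assert row["mean_diff"] == 3.0 and row["ci_half_width"] == 0.0

    def test_unpaired_welch_matches_scipy_interval(self):
        rng = np.random.default_rng(77)
        xa = rng.normal(50, 4, size=10)
        xb = rng.normal(46, 9, size=10)
        cmp = compare_scenarios(fake_results({"strokes": xb}),
                                fake_results({"strokes": xa}),
                                paired=False)
        row = cmp.row("strokes", 1)
        ci = stats.ttest_ind(xa, xb, equal_var=False).confidence_interval(0.95)
        assert row["mean_diff"] == pytest.approx(xa.mean() - xb.mean())
        assert row["mean_diff"] - row["ci_half_width"] \
            == pytest.approx(ci.low)
        assert row["mean_diff"] + row["ci_half_width"] \
            == pytest.approx(ci.high)

    def test_mismatched_counts_rejected_when_paired(self):
        base = fake_results({"strokes": [1.0, 2.0]})
        alt = fake_results({"strokes": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="paired"):
            compare_scenarios(base, alt, paired=True)

    def test_single_replication_ci_flagged_undefined(self):
        base = fake_results({"strokes": [4.0]})
        cmp = compare_scenarios(base, base, paired=True)
        assert not cmp.table["ci_defined"].any()


class TestRunExperiment:
    def test_reruns_reproduce_summaries(self):
        cfg = toy_config(base_seed=5)
        a = run_experiment(cfg, n_replications=2)
        b = run_experiment(cfg, n_replications=2)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_single_replication_summary_equals_replication(self):
        cfg = toy_config(base_seed=5)
        res = run_experiment(cfg, scenario_specs={}, n_replications=1)
        row = res.summary[(res.summary["output"] == "strokes")
                          & (res.summary["snapshot"] == "10")].iloc[0]
        assert row["mean"] == res.replication_values("baseline", "strokes", 10)[0]
        assert not row["ci_defined"]

    def test_effective_treatment_reduces_strokes_under_crn(self):
        # the direction oracle: moving untreated patients onto a treatment
        # with relative risk < 1 cannot raise expected ischaemic strokes
        cfg = toy_config(base_seed=21)
        res = run_experiment(
            cfg, scenario_specs={"all_warfarin": ScenarioSpec.
                                 from_retained_fraction(
                                     "all_warfarin", cfg.baseline_allocation,
                                     0.1)},
            n_replications=8)
        cmp = compare_scenarios(res.results["baseline"],
                                res.results["all_warfarin"], paired=True)
        assert cmp.row("ischaemic_strokes", 10)["mean_diff"] < 0
        assert cmp.row("strokes", "end")["mean_diff"] < 0

    def test_paired_self_comparison_exactly_zero(self):
        cfg = toy_config(base_seed=8)
        res = run_experiment(
            cfg, scenario_specs={"same": ScenarioSpec("baseline")},
            n_replications=3)
        cmp = compare_scenarios(res.results["baseline"], res.results["same"],
                                paired=True)
        assert (cmp.table["mean_diff"] == 0).all()


class TestSensitivity:
    def test_default_grid_has_nine_points_including_zero(self):
        grid = SensitivityGrid("costs.annual_treatment_cost.noac")
        assert len(grid.increments) == 9
        assert 0.0 in grid.increments
        assert grid.increments == tuple(sorted(grid.increments))

    def test_grid_without_zero_rejected(self):
        with pytest.raises(ValueError):
            SensitivityGrid("x", (-0.1, 0.1))

    def test_unknown_parameter_path_rejected(self):
        cfg = toy_config()
        with pytest.raises(KeyError):
            scale_parameter(cfg, "costs.no_such_thing", 1.1)

    def test_zero_increment_reproduces_baseline_exactly(self):
        cfg = toy_config(base_seed=3)
        grid = SensitivityGrid("costs.annual_treatment_cost.noac",
                               (-0.1, 0.0, 0.1))
        sens = sensitivity_oneway(cfg, "costs.annual_treatment_cost.noac",
                                  grid, scenario_specs={}, n_replications=2)
        direct = run_experiment(cfg, scenario_specs={}, n_replications=2)
        at_zero = sens.summaries[sens.summaries["increment"] == 0.0] \
            .drop(columns="increment").reset_index(drop=True)
        pd.testing.assert_frame_equal(at_zero, direct.summary)

    def test_noac_cost_sweep_monotone_in_treatment_cost(self):
        cfg = toy_config(base_seed=13)
        grid = SensitivityGrid("costs.annual_treatment_cost.noac",
                               (-0.2, -0.1, 0.0, 0.1, 0.2))
        sens = sensitivity_oneway(cfg, "costs.annual_treatment_cost.noac",
                                  grid, scenario_specs={}, n_replications=2)
        series = sens.series("cost_treatment", 10)
        assert list(series.index) == sorted(series.index)
        assert series.is_monotonic_increasing
        assert series.diff().dropna().gt(0).all()

    def test_parameter_with_no_structural_effect_changes_nothing(self):
        cfg = toy_config(base_seed=4)
        # nobody is on NOAC in this configuration, so its price is inert
        cfg.baseline_allocation.counts[:, 2] = 0
        cfg.baseline_allocation.counts[:, 0] += 1
        grid = SensitivityGrid("costs.annual_treatment_cost.noac",
                               (-0.2, 0.0, 0.2))
        sens = sensitivity_oneway(cfg, "costs.annual_treatment_cost.noac",
                                  grid, scenario_specs={}, n_replications=2)
        pivot = sens.summaries.pivot_table(index=["output", "snapshot"],
                                           columns="increment", values="mean")
        assert pivot.nunique(axis=1).le(1).all()
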