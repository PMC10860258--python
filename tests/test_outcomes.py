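"""RECIST classification, benefit rate, feasibility and cycle statistics."""

import numpy as np
import pytest

from mtbkit.io import LesionSeries, Milestones
from mtbkit.outcomes import (
    BestResponse,
    classify_best_response,
    clinical_benefit_rate,
    cycle_start_summary,
    feasibility_summary,
    percent_change,
    round_half_up,
    waterfall_table,
)


def series(baseline, sums, ned=False, subject="S"):
    return LesionSeries(subject, baseline, list(sums), ned_flag=ned)


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,timepoint,expected",
        [(100, 70, -30.0), (50, 50, 0.0), (80, 100, 25.0)],
    )
    def test_arithmetic(self, baseline, timepoint, expected):
        assert percent_change(baseline, timepoint) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0, 10)


class TestClassify:
    def test_complete_response_at_zero(self):
        assert classify_best_response(series(100, [0])).response == "CR"

    def test_pr_at_minus_30_boundary_inclusive(self):
        r = classify_best_response(series(100, [70]))
        assert r.response == "PR"
        assert r.best_percent_change == pytest.approx(-30.0)

    def test_minus_30_boundary_strict_knob(self):
        r = classify_best_response(series(100, [70]), pr_boundary_inclusive=False)
        assert r.response == "SD"

    def test_pd_requires_both_conditions(self):
        # +22% and +11 mm: PD
        assert classify_best_response(series(50, [61])).response == "PD"
        # +25% but only +4 mm: not PD (5 mm absolute rule)
        assert classify_best_response(series(16, [20])).response == "SD"
        # +10 mm but only +10%: not PD (20% rule)
        assert classify_best_response(series(100, [110])).response == "SD"

    def test_pd_referenced_to_nadir_not_baseline(self):
        # drop to 50 then rebound to 65: +30%/+15mm over nadir, but still
        # below baseline; PR takes precedence at -50% best change
        assert classify_best_response(series(100, [50, 65])).response == "PR"
        # drop to 80 (-20%, not PR) then rebound to 100: +25%, +20 mm
        # over the nadir triggers PD even at baseline level
        assert classify_best_response(series(100, [80, 100])).response == "PD"

    def test_plus_20_boundary_needs_5mm(self):
        # exactly +20% and exactly +5 mm from nadir: PD (inclusive)
        assert classify_best_response(series(25, [30])).response == "PD"

    def test_ned_class(self):
        r = classify_best_response(series(None, [], ned=True))
        assert r.response == "NED"
        assert r.best_percent_change is None

    def test_sd_band(self):
        assert classify_best_response(series(100, [85])).response == "SD"

    def test_no_timepoints_rejected(self):
        with pytest.raises(ValueError):
            classify_best_response(series(100, []))

    def test_truth_table_grid(self):
        # exhaustive boundary grid asserted against hand-derived labels
        cases = [
            (100, [0], "CR"),
            (100, [100, 0], "CR"),
            (100, [70], "PR"),
            (100, [69.9], "PR"),
            (100, [70.1], "SD"),
            (100, [120], "PD"),        # +20%, +20 mm
            (100, [119.9], "SD"),
            (20, [24], "SD"),          # +20% but +4 mm only
            (20, [25], "PD"),          # +25%, +5 mm
            (100, [95, 114.1], "PD"),  # nadir 95: +20.1%, +19.1 mm
            (100, [95, 113], "SD"),    # nadir 95: +18.9%
        ]
        for baseline, sums, expected in cases:
            got = classify_best_response(series(baseline, sums)).response
            assert got == expected, (baseline, sums, got, expected)


class TestBenefitRate:
    def test_pooled_stratum_counts_give_trial_benefit(self):
        # pooled per-stratum best-response counts: 18 NED, 11 CR, 11 PR,
        # 41 SD, 43 PD over 124 evaluable subjects -> 65%
        classes = (["NED"] * 18 + ["CR"] * 11 + ["PR"] * 11 + ["SD"] * 41
                   + ["PD"] * 43)
        proportion, percent = clinical_benefit_rate(classes)
        assert percent == 65.0
        assert proportion == pytest.approx(81 / 124)

    def test_all_pd_is_zero(self):
        assert clinical_benefit_rate(["PD"] * 5) == (0.0, 0.0)

    def test_matches_brute_force_counting(self, rng):
        classes = ["CR", "PR", "SD", "PD", "NED"]
        for _ in range(50):
            labels = [classes[i] for i in rng.integers(0, 5, size=30)]
            proportion, _ = clinical_benefit_rate(labels)
            benefit = sum(1 for l in labels if l != "PD")
            assert proportion == pytest.approx(benefit / 30)

    def test_permutation_invariant_and_bounded(self, rng):
        labels = ["CR", "PD", "SD", "PD", "NED", "PR"]
        base = clinical_benefit_rate(labels)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        assert clinical_benefit_rate(shuffled) == base
        assert 0.0 <= base[0] <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clinical_benefit_rate([])


class TestFeasibility:
    def test_single_subject(self):
        table = feasibility_summary([Milestones("S", 10, 17, 23, 38, 200)])
        assert table.loc["treatment_start", "mean"] == 38
        assert table.loc["treatment_start", "median"] == 38

    def test_stratum_mean_echo(self):
        # the three per-stratum treatment-start means average to 38
        ms = [Milestones(f"S{i}", treatment_start=v)
              for i, v in enumerate([31, 48, 35])]
        table = feasibility_summary(ms)
        assert table.loc["treatment_start", "mean"] == pytest.approx(38.0)

    def test_missing_milestones_excluded_per_statistic(self):
        ms = [Milestones("A", sequencing=10), Milestones("B")]
        table = feasibility_summary(ms)
        assert table.loc["sequencing", "n"] == 1
        assert table.loc["report", "n"] == 0
        assert np.isnan(table.loc["report", "mean"])

    def test_matches_brute_force(self, rng):
        ms = []
        for i in range(50):
            seq = float(rng.integers(2, 30))
            ms.append(Milestones(f"S{i}", seq, seq + 7, seq + 13, seq + 28))
        table = feasibility_summary(ms)
        seqs = [m.sequencing for m in ms]
        assert table.loc["sequencing", "mean"] == pytest.approx(np.mean(seqs))
        assert table.loc["sequencing", "median"] == pytest.approx(np.median(seqs))
        assert table.loc["sequencing", "min"] == min(seqs)
        assert table.loc["sequencing", "max"] == max(seqs)

    def test_means_monotone_along_milestone_order(self, small_cohort):
        bundle, _ = small_cohort
        table = feasibility_summary(bundle.milestones.values())
        means = table["mean"].to_numpy()
        assert np.all(np.diff(means) >= 0)


class TestCycleStart:
    def test_trial_counts(self):
        out = cycle_start_summary(
            {"c1": 121, "c2": 12, "c3": 3, "c5": 1, "never": 7}, n=144
        )
        assert out["ever_started"] == 95.14
        assert out["c1"] == 84.03
        assert out["c2"] == 8.33
        assert out["never"] == 4.86

    def test_all_cycle1(self):
        out = cycle_start_summary({"c1": 10}, n=10)
        assert out["ever_started"] == 100.0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            counts = {c: int(rng.integers(0, 10))
                      for c in ("c1", "c2", "c3", "c5", "never")}
            n = sum(counts.values()) + int(rng.integers(0, 5)) + 1
            out = cycle_start_summary(counts, n)
            for c, k in counts.items():
                assert out[c] == pytest.approx(round_half_up(100 * k / n, 2))

    def test_counts_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            cycle_start_summary({"c1": 5, "never": 6}, n=10)


class TestWaterfall:
    def _responses(self, changes):
        return [BestResponse(f"S{i}", "SD" if c == 0 else ("PD" if c > 0 else "PR"),
                             float(c)) for i, c in enumerate(changes)]

    def test_trial_counts(self):
        changes = [-10.0] * 46 + [0.0] * 6 + [15.0] * 21
        out = waterfall_table(self._responses(changes))
        assert out["n"] == 73
        assert (out["n_decrease"], out["n_no_change"], out["n_increase"]) == (
            46, 6, 21)
        assert out["percent_decrease"] == 63.01

    def test_all_zero_changes(self):
        out = waterfall_table(self._responses([0.0] * 4))
        assert out["percent_decrease"] == 0.0
        assert out["n_no_change"] == 4

    def test_sorted_descending_and_sign_counts(self, rng):
        changes = list(rng.uniform(-80, 80, size=40).round(1))
        out = waterfall_table(self._responses(changes))
        assert out["best_percent_change"] == sorted(changes, reverse=True)
        assert out["n_decrease"] == sum(1 for c in changes if c < 0)
        assert out["n_increase"] == sum(1 for c in changes if c > 0)

    def test_missing_change_rejected(self):
        with pytest.raises(ValueError):
            waterfall_table([BestResponse("S", "NED", None)])


class TestRounding:
    def test_half_up_at_printed_precision(self):
        assert round_half_up(64.5) == 65.0
        assert round_half_up(95.135, 2) == 95.14
        assert round_half_up(0.5) == 1.0
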