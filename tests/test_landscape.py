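"""Arm-level event calling, recurrence, TMB, oncoprint."""

import pytest

from mtbkit.io import (
    Arm,
    ArmMap,
    CohortBundle,
    CopyNumberSegment,
    FusionEvent,
    SomaticEventSet,
    SomaticVariant,
)
from mtbkit.landscape import (
    ArmEvent,
    build_oncoprint,
    call_arm_events,
    cohort_arm_recurrence,
    compute_tmb,
)

ARMS = ArmMap([
    Arm("17p", "17", 1, 24_000_000),
    Arm("17q", "17", 24_000_001, 81_000_000),
    Arm("11q", "11", 50_000_001, 135_000_000),
])


def seg(chrom, start, end, log2, n_genes, subject="S1"):
    return CopyNumberSegment(subject, chrom, start, end, log2, n_genes)


class TestCallArmEvents:
    def test_gene_filter_blocks_49_gene_segment(self):
        # 90% of 17q but only 49 genes: below the >=50 gene filter
        q = ARMS.arms["17q"]
        length = int(0.9 * q.length)
        events = call_arm_events(
            [seg("17", q.start, q.start + length - 1, 0.6, 49)], ARMS
        )
        assert events == []

    def test_inclusive_thresholds_emit_gain(self):
        # 60 genes, log2 exactly 0.5, exactly 60% coverage: all inclusive
        q = ARMS.arms["17q"]
        length = int(0.6 * q.length)
        (event,) = call_arm_events(
            [seg("17", q.start, q.start + length - 1, 0.5, 60)], ARMS
        )
        assert event.direction == "gain"
        assert event.arm_id == "17q"
        assert event.covered_fraction == pytest.approx(0.6, abs=1e-6)

    def test_disjoint_loss_fractions_add(self):
        q = ARMS.arms["11q"]
        l1 = int(0.30 * q.length)
        l2 = int(0.25 * q.length)
        segs = [
            seg("11", q.start, q.start + l1 - 1, -0.6, 80),
            seg("11", q.end - l2 + 1, q.end, -0.6, 80),
        ]
        (event,) = call_arm_events(segs, ARMS)
        assert event.direction == "loss"
        assert event.covered_fraction == pytest.approx(0.55, abs=1e-6)

    def test_overlapping_segments_unioned_not_double_counted(self):
        q = ARMS.arms["17q"]
        length = int(0.6 * q.length)
        segs = [
            seg("17", q.start, q.start + length - 1, 0.7, 80),
            seg("17", q.start, q.start + length - 1, 0.8, 80),
        ]
        (event,) = call_arm_events(segs, ARMS)
        assert event.covered_fraction <= 1.0
        assert event.covered_fraction == pytest.approx(0.6, abs=1e-6)

    def test_subthreshold_fraction_emits_nothing(self):
        q = ARMS.arms["17q"]
        length = int(0.49 * q.length)
        assert call_arm_events(
            [seg("17", q.start, q.start + length - 1, 0.9, 200)], ARMS
        ) == []

    def test_unknown_chromosome_warns_and_skips(self):
        with pytest.warns(UserWarning, match="no arm"):
            events = call_arm_events([seg("99", 1, 10**8, 0.9, 100)], ARMS)
        assert events == []

    def test_monotone_in_all_three_thresholds(self, rng):
        segs = []
        for i in range(50):
            arm = list(ARMS)[int(rng.integers(len(ARMS)))]
            length = int(rng.uniform(0.2, 1.0) * arm.length)
            start = arm.start + int(rng.integers(0, arm.length - length + 1))
            segs.append(
                seg(arm.chrom, start, start + length - 1,
                    float(rng.uniform(-1, 1)), int(rng.integers(10, 200)),
                    subject=f"S{i % 5}")
            )
        base = len(call_arm_events(segs, ARMS))
        assert len(call_arm_events(segs, ARMS, min_genes=100)) <= base
        assert len(call_arm_events(segs, ARMS, log2_thresh=0.8)) <= base
        assert len(call_arm_events(segs, ARMS, arm_fraction=0.8)) <= base


class TestRecurrence:
    def _events(self, n, arm="17q", direction="gain"):
        return [ArmEvent(f"S{i}", arm, direction, 0.8) for i in range(n)]

    def test_14_subjects_excluded(self):
        assert cohort_arm_recurrence(self._events(14)).empty

    def test_15_subjects_included_with_count(self):
        table = cohort_arm_recurrence(self._events(15))
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.arm_id, row.direction, row.n_subjects) == ("17q", "gain", 15)

    def test_longitudinal_biopsies_count_once(self):
        events = self._events(14) + [ArmEvent("S0", "17q", "gain", 0.9)]
        assert cohort_arm_recurrence(events).empty


class TestTMB:
    def _snv(self, i, subject="S1"):
        return SomaticVariant(subject, "1", i + 1, "C", "T", "SNV")

    def test_arithmetic(self):
        result = compute_tmb([self._snv(i) for i in range(42)], callable_mb=30)
        assert result.tmb == pytest.approx(1.4)

    def test_empty(self):
        assert compute_tmb([], callable_mb=30, subject_id="S").tmb == 0.0

    def test_indels_excluded(self):
        variants = [self._snv(i) for i in range(10)] + [
            SomaticVariant("S1", "1", 100 + i, "CA", "C", "deletion")
            for i in range(5)
        ]
        result = compute_tmb(variants, callable_mb=10)
        assert result.n_point_mutations == 10
        assert result.tmb == pytest.approx(1.0)

    def test_invariant_under_reordering_and_linear_in_duplication(self):
        variants = [self._snv(i) for i in range(7)]
        fwd = compute_tmb(variants, 10).tmb
        rev = compute_tmb(list(reversed(variants)), 10).tmb
        assert fwd == rev
        assert compute_tmb(variants * 2, 10).tmb == pytest.approx(2 * fwd)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            compute_tmb([], callable_mb=0)


class TestOncoprint:
    def _bundle(self):
        bundle = CohortBundle(
            tumor_types={"A": "neuroblastoma", "B": "CNS", "C": "rare"},
        )
        bundle.events["A"] = SomaticEventSet(
            "A",
            variants=[
                SomaticVariant("A", "2", 100, "C", "T", "SNV", gene="ALK"),
            ],
            fusions=[FusionEvent("A", "EML4", "ALK")],
        )
        bundle.events["B"] = SomaticEventSet(
            "B",
            variants=[SomaticVariant("B", "17", 5, "C", "T", "SNV", gene="TP53")],
        )
        bundle.events["C"] = SomaticEventSet("C")
        return bundle

    def test_empty_events_alphabetical_rows(self):
        bundle = CohortBundle(tumor_types={"A": "rare"})
        bundle.events["A"] = SomaticEventSet("A")
        op = build_oncoprint(bundle, ["ZZZ", "AAA"])
        assert list(op.cells.index) == ["AAA", "ZZZ"]
        assert all(cell == frozenset() for cell in op.cells.to_numpy().ravel())

    def test_snv_and_fusion_union_in_one_cell(self):
        op = build_oncoprint(self._bundle(), ["ALK", "TP53", "MYCN"])
        assert op.cells.at["ALK", "A"] == frozenset({"SNV", "fusion"})

    def test_frequency_ordering_matches_brute_force(self):
        bundle = self._bundle()
        panel = ["MYCN", "TP53", "ALK", "EML4", "NRAS"]
        op = build_oncoprint(bundle, panel)
        # brute force: count subjects altered per gene, sort desc then alpha
        counts = {g: 0 for g in panel}
        for s, ev in bundle.events.items():
            hit = {v.gene for v in ev.variants} | {
                g for f in ev.fusions for g in (f.gene_5p, f.gene_3p)
            }
            for g in hit & set(panel):
                counts[g] += 1
        expected = sorted(panel, key=lambda g: (-counts[g], g))
        assert list(op.cells.index) == expected

    def test_columns_grouped_by_tumor_type(self):
        op = build_oncoprint(self._bundle(), ["ALK"])
        assert list(op.cells.columns) == ["A", "B", "C"]  # NB, CNS, rare


class TestPlantedRecovery:
    """Closed loop: planted arm events are recovered exactly."""

    def test_exact_recovery_at_fractions_above_half(self, small_cohort):
        bundle, truth = small_cohort
        for subject in bundle.subjects:
            events = call_arm_events(
                bundle.events[subject].segments, bundle.arm_map
            )
            called = {(e.arm_id, e.direction) for e in events}
            assert called == truth.arm_events[subject]

    def test_nothing_called_below_half_fraction(self, rng):
        for _ in range(20):
            arm = list(ARMS)[int(rng.integers(len(ARMS)))]
            frac = float(rng.uniform(0.05, 0.49))
            length = int(frac * arm.length)
            start = arm.start + int(rng.integers(0, arm.length - length + 1))
            segs = [seg(arm.chrom, start, start + length - 1, 0.9, 100)]
            assert call_arm_events(segs, ARMS) == []
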