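"""Tiered drug-gene matching and combination assembly."""

import numpy as np
import pandas as pd
import pytest

from mtbkit.expression import NRZScoreTable
from mtbkit.io import (
    DrugRule,
    DrugRuleSet,
    FusionEvent,
    SomaticEventSet,
    SomaticVariant,
)
from mtbkit.matching import (
    MatchCandidate,
    NoPlanError,
    SupportingEvent,
    assemble_combination,
    generate_report,
    match_tier1,
    match_tier2,
    match_tier3,
    report_to_json,
    validate_report,
)


def snv(gene, subject="S1", protein_change=None):
    return SomaticVariant(subject, "1", 100, "C", "T", "SNV", gene=gene,
                          effect="missense", protein_change=protein_change)


def nrz_table(z_by_gene, tau=2.0):
    z = pd.Series(z_by_gene, dtype=float)
    flags = pd.Series("neutral", index=z.index, dtype=object)
    flags[z >= tau] = "over"
    flags[z <= -tau] = "under"
    return NRZScoreTable("S1", z, flags, tau)


def cand(drug, tier=1, score=1.0, mode="sensitivity"):
    return MatchCandidate(
        drug=drug, tier=tier, mode=mode,
        supporting_events=[SupportingEvent("G", "event", None)], score=score,
    )


class TestTier1:
    def test_direct_variant_match(self):
        rules = DrugRuleSet([DrugRule("crizotinib", "ALK", "direct")])
        events = SomaticEventSet("S1", variants=[snv("ALK", protein_change="R1275Q")])
        (c,) = match_tier1(events, rules)
        assert c.drug == "crizotinib" and c.tier == 1
        assert c.supporting_events[0].value == "ALK R1275Q"

    def test_gene_without_rule_yields_nothing(self):
        rules = DrugRuleSet([DrugRule("crizotinib", "ALK", "direct")])
        events = SomaticEventSet("S1", variants=[snv("OTHER")])
        assert match_tier1(events, rules) == []

    def test_fusion_matches_on_either_partner(self):
        rules = DrugRuleSet([DrugRule("drugF", "FLI1", "direct")])
        events = SomaticEventSet(
            "S1", fusions=[FusionEvent("S1", "EWSR1", "FLI1")]
        )
        (c,) = match_tier1(events, rules)
        assert c.supporting_events[0].gene == "FLI1"
        assert c.supporting_events[0].value == "EWSR1_FLI1"
        # and the 5' partner matches too when it has the rule
        rules5 = DrugRuleSet([DrugRule("drugE", "EWSR1", "direct")])
        (c5,) = match_tier1(events, rules5)
        assert c5.supporting_events[0].gene == "EWSR1"


class TestTier2:
    RULES = DrugRuleSet([DrugRule("trametinib", "MAP2K1", "direct")])

    def test_single_hop_inference(self):
        events = SomaticEventSet("S1", variants=[snv("NF1")])
        inference = {"NF1": [("MAP2K1", "loss activates MEK")]}
        (c,) = match_tier2(events, self.RULES, inference)
        assert c.drug == "trametinib" and c.tier == 2

    def test_empty_map_yields_nothing(self):
        events = SomaticEventSet("S1", variants=[snv("NF1")])
        assert match_tier2(events, self.RULES, {}) == []

    def test_two_hop_chains_not_followed(self):
        # G -> H -> MAP2K1: only single hops are honored, so a variant in G
        # finds nothing (H has no rule), while a variant in H matches
        events_g = SomaticEventSet("S1", variants=[snv("G")])
        events_h = SomaticEventSet("S1", variants=[snv("H")])
        inference = {"G": [("H", "")], "H": [("MAP2K1", "")]}
        assert match_tier2(events_g, self.RULES, inference) == []
        assert len(match_tier2(events_h, self.RULES, inference)) == 1


class TestTier3:
    def test_over_rule_matched_above_tau(self):
        rules = DrugRuleSet(
            [DrugRule("topotecan", "TOP2A", "expression", "over")]
        )
        (c,) = match_tier3(nrz_table({"TOP2A": 3.1}), rules)
        assert c.drug == "topotecan" and c.tier == 3
        assert c.score == pytest.approx(3.1)

    def test_below_tau_yields_nothing(self):
        rules = DrugRuleSet(
            [DrugRule("topotecan", "TOP2A", "expression", "over")]
        )
        assert match_tier3(nrz_table({"TOP2A": 1.5}), rules) == []

    def test_direction_must_agree(self):
        rules = DrugRuleSet([DrugRule("d", "G", "expression", "under")])
        assert match_tier3(nrz_table({"G": 4.0}), rules) == []
        (c,) = match_tier3(nrz_table({"G": -4.0}), rules)
        assert c.drug == "d"

    def test_resistance_match_becomes_veto(self):
        rules = DrugRuleSet([
            DrugRule("drugY", "geneB", "expression", "over", "resistance"),
            DrugRule("drugY", "geneC", "expression", "over", "sensitivity"),
        ])
        candidates = match_tier3(nrz_table({"geneB": 4.0, "geneC": 5.0}), rules)
        assert {c.mode for c in candidates} == {"sensitivity", "resistance"}
        plan_error = pytest.raises(NoPlanError)
        with plan_error:
            assemble_combination(
                [c for c in candidates if c.drug == "drugY"],
            )


class TestAssembleCombination:
    def test_two_nonconflicting_candidates(self):
        plan = assemble_combination([cand("a"), cand("b")])
        assert plan.drugs == ["a", "b"]

    def test_greedy_trace_with_conflict(self):
        # ranked 1..5; #2 and #3 conflict -> plan is {1,2,4,5}
        cands = [cand(f"d{i}", tier=1, score=10 - i) for i in range(1, 6)]
        plan = assemble_combination(
            cands, blacklist=[frozenset(("d2", "d3"))], max_drugs=4
        )
        assert plan.drugs == ["d1", "d2", "d4", "d5"]
        assert {"drug": "d3", "reason": "interaction conflict"} in plan.excluded

    def test_all_vetoed_is_no_plan(self):
        with pytest.raises(NoPlanError):
            assemble_combination(
                [cand("a")], vetoes=[cand("a", mode="resistance")]
            )

    def test_max_drugs_respected(self):
        cands = [cand(f"d{i}") for i in range(8)]
        assert len(assemble_combination(cands).drugs) == 4
        assert len(assemble_combination(cands, max_drugs=2).drugs) == 2

    def test_priority_regimen_seeds_plan(self):
        cands = [
            cand("x", tier=1, score=9),
            cand("p1", tier=3, score=1),
            cand("p2", tier=3, score=1),
        ]
        plan = assemble_combination(
            cands, priority_regimens=[["p1", "p2"]], max_drugs=3
        )
        assert plan.drugs[:2] == ["p1", "p2"]
        assert plan.priority_regimen_used
        assert plan.drugs[2] == "x"

    def test_unsupported_priority_regimen_ignored(self):
        plan = assemble_combination(
            [cand("a")], priority_regimens=[["a", "missing"]]
        )
        assert not plan.priority_regimen_used

    def test_tier_dominance_in_ranking(self, rng):
        for _ in range(100):
            tiers = rng.integers(1, 4, size=6)
            score = float(rng.uniform(0, 5))
            cands = [
                cand(f"d{i}", tier=int(t), score=score)
                for i, t in enumerate(tiers)
            ]
            plan = assemble_combination(cands, max_drugs=4)
            plan_tiers = [plan.rationale[d].tier for d in plan.drugs]
            assert plan_tiers == sorted(plan_tiers)

    def test_random_configurations_satisfy_invariants(self):
        rng = np.random.default_rng(2024)
        drugs = [f"d{i}" for i in range(10)]
        n_valid = 0
        for _ in range(1000):
            n_cand = int(rng.integers(1, 8))
            cands = [
                cand(
                    str(rng.choice(drugs)),
                    tier=int(rng.integers(1, 4)),
                    score=float(rng.uniform(0, 5)),
                    mode="resistance" if rng.uniform() < 0.15 else "sensitivity",
                )
                for _ in range(n_cand)
            ]
            n_black = int(rng.integers(0, 4))
            blacklist = {
                frozenset(rng.choice(drugs, size=2, replace=False))
                for _ in range(n_black)
            }
            try:
                plan = assemble_combination(cands, blacklist=blacklist)
            except NoPlanError:
                continue
            n_valid += 1
            assert 1 <= len(plan.drugs) <= 4
            assert len(set(plan.drugs)) == len(plan.drugs)
            vetoed = {c.drug for c in cands if c.mode == "resistance"}
            assert not (set(plan.drugs) & vetoed)
            for i, a in enumerate(plan.drugs):
                for b in plan.drugs[i + 1:]:
                    assert frozenset((a, b)) not in blacklist
        assert n_valid > 500  # most configurations admit a plan

    def test_blacklist_growth_never_increases_plan_size(self, rng):
        cands = [cand(f"d{i}", score=float(5 - i)) for i in range(6)]
        pairs = [frozenset((f"d{i}", f"d{j}")) for i in range(6) for j in range(i)]
        sizes = []
        for k in range(0, len(pairs) + 1, 3):
            try:
                sizes.append(len(assemble_combination(cands, blacklist=pairs[:k]).drugs))
            except NoPlanError:
                sizes.append(0)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestReport:
    def _plan(self):
        return assemble_combination([cand("a", score=2.0), cand("b")],
                                    subject_id="S1")

    def test_deterministic_json(self):
        r1 = generate_report(self._plan(), parameters={"tau": 2.0})
        r2 = generate_report(self._plan(), parameters={"tau": 2.0})
        assert report_to_json(r1) == report_to_json(r2)

    def test_empty_veto_list_empty_exclusions(self):
        report = generate_report(self._plan())
        assert report["excluded"] == []

    def test_schema_validation_on_synthetic_subjects(self, small_cohort):
        from mtbkit import pipeline

        bundle, _ = small_cohort
        n_checked = 0
        for subject in bundle.subjects[:10]:
            result = pipeline.run_subject(bundle, subject)
            if result.report is not None:
                validate_report(result.report)
                n_checked += 1
        assert n_checked >= 5

    def test_schema_rejects_missing_key(self):
        report = generate_report(self._plan())
        del report["plan"]
        with pytest.raises(ValueError, match="plan"):
            validate_report(report)
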