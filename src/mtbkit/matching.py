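"""Three-tier drug-gene matching and combination-plan assembly.

Tier 1 matches somatic events (variants, fusions) directly against
``direct`` rules; tier 2 follows a single curated gene-to-target hop into
``direct``/``inferred`` rules; tier 3 matches NRZ over/under expression
flags against ``expression`` rules. Resistance rules are hard vetoes for
the matched drug. Candidates are ranked (tier ascending, score
descending, drug name) and a greedy cycle adds the best non-conflicting
candidate per round, up to four drugs, optionally seeded with a
previously established priority regimen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mtbkit.expression import NRZScoreTable
from mtbkit.io import DrugRuleSet, SomaticEventSet, SomaticVariant

__all__ = [
    "MatchCandidate",
    "TreatmentPlan",
    "NoPlanError",
    "EVENT_CLASS_WEIGHTS",
    "match_tier1",
    "match_tier2",
    "match_tier3",
    "assemble_combination",
    "generate_report",
    "REPORT_SCHEMA",
    "validate_report",
]

#: Ranking weight of the event class supporting a variant-tier candidate.
#: Fusions outrank hotspot SNVs (those with a named protein change), which
#: outrank other small variants, which outrank copy-number support.
EVENT_CLASS_WEIGHTS: dict[str, float] = {
    "fusion": 4.0,
    "hotspot_snv": 3.0,
    "variant": 2.0,
    "cnv": 1.0,
}


class NoPlanError(RuntimeError):
    """No eligible candidate survives veto/conflict filtering."""


@dataclass(frozen=True)
class SupportingEvent:
    gene: str
    description: str
    value: float | str | None = None  # z-score or variant notation

    def as_dict(self) -> dict:
        return {"gene": self.gene, "description": self.description, "value": self.value}


@dataclass
class MatchCandidate:
    """A drug supported by at least one molecular event, with a rank score."""

    drug: str
    tier: int  # 1 direct, 2 inferred, 3 expression
    mode: str  # sensitivity | resistance
    supporting_events: list[SupportingEvent]
    score: float
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.supporting_events:
            raise ValueError("a candidate needs at least one supporting event")
        if self.tier not in (1, 2, 3):
            raise ValueError(f"tier must be 1, 2 or 3, got {self.tier}")

    @property
    def rank_key(self) -> tuple:
        return (self.tier, -self.score, self.drug)


@dataclass
class TreatmentPlan:
    """An ordered 1-4 drug combination with per-drug rationale."""

    subject_id: str
    drugs: list[str]
    rationale: dict[str, MatchCandidate]
    excluded: list[dict] = field(default_factory=list)
    priority_regimen_used: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.drugs) <= 4:
            raise ValueError("a plan holds between 1 and 4 drugs")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("plan drugs must be unique")


def _variant_weight(variant: SomaticVariant) -> float:
    if variant.protein_change:
        return EVENT_CLASS_WEIGHTS["hotspot_snv"]
    return EVENT_CLASS_WEIGHTS["variant"]


def _variant_notation(v: SomaticVariant) -> str:
    if v.protein_change:
        return f"{v.gene} {v.protein_change}"
    return f"{v.gene} {v.chrom}:{v.pos}{v.ref}>{v.alt}"


def match_tier1(
    events: SomaticEventSet, rules: DrugRuleSet
) -> list[MatchCandidate]:
    """Direct variant/drug matches: a somatic event in a gene with a
    ``direct`` rule. Both fusion partners are eligible for matching."""
    hits: dict[tuple[str, str], list[tuple[SupportingEvent, float, str]]] = {}
    for v in events.variants:
        for rule in rules.for_gene(v.gene, tier="direct"):
            hits.setdefault((rule.drug, rule.mode), []).append(
                (
                    SupportingEvent(v.gene, v.effect or v.variant_class,
                                    _variant_notation(v)),
                    _variant_weight(v),
                    rule.evidence,
                )
            )
    for f in events.fusions:
        for gene in (f.gene_5p, f.gene_3p):
            for rule in rules.for_gene(gene, tier="direct"):
                hits.setdefault((rule.drug, rule.mode), []).append(
                    (
                        SupportingEvent(gene, "fusion", f.label),
                        EVENT_CLASS_WEIGHTS["fusion"],
                        rule.evidence,
                    )
                )
    return _collapse_hits(hits, tier=1)


def match_tier2(
    events: SomaticEventSet,
    rules: DrugRuleSet,
    inference_map: Mapping[str, list[tuple[str, str]]],
) -> list[MatchCandidate]:
    """Inferred matches: a variant in gene G, a single curated hop G -> T,
    and a ``direct`` or ``inferred`` rule on target T. Exactly one hop;
    chains are never followed."""
    hits: dict[tuple[str, str], list[tuple[SupportingEvent, float, str]]] = {}
    for v in events.variants:
        for target, hop_evidence in inference_map.get(v.gene, []):
            for tier_name in ("direct", "inferred"):
                for rule in rules.for_gene(target, tier=tier_name):
                    desc = f"{v.effect or v.variant_class} via {v.gene}->{target}"
                    ev = "; ".join(e for e in (hop_evidence, rule.evidence) if e)
                    hits.setdefault((rule.drug, rule.mode), []).append(
                        (
                            SupportingEvent(v.gene, desc, _variant_notation(v)),
                            _variant_weight(v),
                            ev,
                        )
                    )
    return _collapse_hits(hits, tier=2)


def match_tier3(
    nrz: NRZScoreTable, rules: DrugRuleSet, tau: float | None = None
) -> list[MatchCandidate]:
    """Expression matches: an NRZ over/under flag agreeing with an
    ``expression`` rule's direction. Sensitivity rules yield candidates;
    resistance rules yield vetoes under the same matching. Candidates score
    by |z| of the best supporting gene."""
    if tau is not None and tau != nrz.tau:
        raise ValueError(
            f"NRZ table was flagged at tau={nrz.tau}, requested {tau}"
        )
    hits: dict[tuple[str, str], list[tuple[SupportingEvent, float, str]]] = {}
    for gene, flag in nrz.flags.items():
        if flag == "neutral":
            continue
        for rule in rules.for_gene(gene, tier="expression"):
            if rule.direction != flag:
                continue
            z = float(nrz.z[gene])
            hits.setdefault((rule.drug, rule.mode), []).append(
                (
                    SupportingEvent(gene, f"{flag}expressed", z),
                    abs(z),
                    rule.evidence,
                )
            )
    return _collapse_hits(hits, tier=3)


def _collapse_hits(
    hits: Mapping[tuple[str, str], list[tuple[SupportingEvent, float, str]]],
    tier: int,
) -> list[MatchCandidate]:
    candidates = []
    for (drug, mode), supports in sorted(hits.items()):
        events = [s[0] for s in supports]
        score = max(s[1] for s in supports)
        evidence = "; ".join(sorted({s[2] for s in supports if s[2]}))
        candidates.append(
            MatchCandidate(
                drug=drug,
                tier=tier,
                mode=mode,
                supporting_events=events,
                score=score,
                evidence=evidence,
            )
        )
    candidates.sort(key=lambda c: c.rank_key)
    return candidates


def assemble_combination(
    candidates: Sequence[MatchCandidate],
    vetoes: Sequence[MatchCandidate] = (),
    blacklist: Iterable[frozenset[str]] = (),
    max_drugs: int = 4,
    priority_regimens: Sequence[Sequence[str]] | None = None,
    subject_id: str = "",
) -> TreatmentPlan:
    """Greedy assembly of a 1-4 drug combination.

    Resistance candidates (whether passed among ``candidates`` or
    ``vetoes``) veto their drug outright. Remaining sensitivity candidates
    are ranked (tier, -score, drug); if a priority regimen is fully
    contained in the candidate drugs and internally conflict-free it seeds
    the plan. Each cycle then adds the best-ranked drug that neither
    duplicates a plan drug nor conflicts with one via the interaction
    blacklist, stopping at ``max_drugs`` or exhaustion.
    """
    blacklist = {frozenset(pair) for pair in blacklist}
    vetoed_drugs = {c.drug for c in vetoes if c.mode == "resistance"}
    vetoed_drugs |= {c.drug for c in candidates if c.mode == "resistance"}
    excluded: list[dict] = []
    pool: list[MatchCandidate] = []
    seen_vetoed: set[str] = set()
    for cand in sorted(candidates, key=lambda c: c.rank_key):
        if cand.mode == "resistance":
            continue
        if cand.drug in vetoed_drugs:
            if cand.drug not in seen_vetoed:
                excluded.append({"drug": cand.drug, "reason": "resistance veto"})
                seen_vetoed.add(cand.drug)
            continue
        pool.append(cand)
    if not pool:
        raise NoPlanError("no eligible candidates after resistance vetoes")

    by_drug: dict[str, MatchCandidate] = {}
    for cand in pool:  # already rank-ordered; keep the best candidate per drug
        by_drug.setdefault(cand.drug, cand)

    plan_drugs: list[str] = []
    rationale: dict[str, MatchCandidate] = {}
    priority_used = False

    def conflicts(drug: str) -> bool:
        return any(frozenset((drug, p)) in blacklist for p in plan_drugs)

    if priority_regimens:
        for regimen in priority_regimens:
            regimen = list(regimen)
            if len(regimen) > max_drugs:
                continue
            if not all(d in by_drug for d in regimen):
                continue
            internal_ok = all(
                frozenset((a, b)) not in blacklist
                for i, a in enumerate(regimen)
                for b in regimen[i + 1:]
            )
            if not internal_ok:
                continue
            for d in regimen:
                plan_drugs.append(d)
                rationale[d] = by_drug[d]
            priority_used = True
            break

    for cand in pool:
        if len(plan_drugs) >= max_drugs:
            break
        if cand.drug in plan_drugs:
            continue
        if conflicts(cand.drug):
            excluded.append(
                {"drug": cand.drug, "reason": "interaction conflict"}
            )
            continue
        plan_drugs.append(cand.drug)
        rationale[cand.drug] = cand

    if not plan_drugs:
        raise NoPlanError("all eligible candidates conflict with each other")
    return TreatmentPlan(
        subject_id=subject_id,
        drugs=plan_drugs,
        rationale=rationale,
        excluded=excluded,
        priority_regimen_used=priority_used,
    )


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------

#: Minimal structural schema of the report JSON (field name -> type or
#: nested schema); checked by :func:`validate_report`.
REPORT_SCHEMA: dict = {
    "subject_id": str,
    "plan": {
        "drugs": list,
        "priority_regimen_used": bool,
    },
    "rationale": list,
    "excluded": list,
    "provenance": {
        "tool": str,
        "version": str,
        "parameters": dict,
    },
}


def generate_report(
    plan: TreatmentPlan,
    parameters: Mapping | None = None,
    notes: Sequence[str] = (),
) -> dict:
    """Deterministic drug-prediction report for one subject.

    The same plan and parameters always serialize to byte-identical JSON
    (sorted keys, no timestamps).
    """
    from mtbkit import __version__

    rationale = []
    for drug in plan.drugs:
        cand = plan.rationale[drug]
        rationale.append(
            {
                "drug": drug,
                "tier": cand.tier,
                "mode": cand.mode,
                "score": cand.score,
                "evidence": cand.evidence,
                "supporting_events": [e.as_dict() for e in cand.supporting_events],
            }
        )
    report = {
        "subject_id": plan.subject_id,
        "plan": {
            "drugs": list(plan.drugs),
            "priority_regimen_used": plan.priority_regimen_used,
        },
        "rationale": rationale,
        "excluded": list(plan.excluded),
        "notes": list(notes),
        "provenance": {
            "tool": "mtbkit",
            "version": __version__,
            "parameters": dict(parameters or {}),
        },
    }
    return report


def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_markdown(report: Mapping) -> str:
    lines = [f"# Drug prediction report: {report['subject_id']}", ""]
    lines.append("## Recommended combination")
    for entry in report["rationale"]:
        lines.append(
            f"- **{entry['drug']}** (tier {entry['tier']}, {entry['mode']})"
        )
        for ev in entry["supporting_events"]:
            lines.append(f"  - {ev['gene']}: {ev['description']} ({ev['value']})")
    lines.append("")
    lines.append("## Excluded drugs")
    if report["excluded"]:
        for ex in report["excluded"]:
            lines.append(f"- {ex['drug']}: {ex['reason']}")
    else:
        lines.append("(none)")
    return "\n".join(lines) + "\n"


def validate_report(report: Mapping, schema: Mapping | None = None) -> None:
    """Raise ValueError if the report does not match REPORT_SCHEMA."""
    schema = REPORT_SCHEMA if schema is None else schema

    def check(obj, sch, path="report"):
        for key, expected in sch.items():
            if key not in obj:
                raise ValueError(f"{path}: missing key {key!r}")
            val = obj[key]
            if isinstance(expected, dict):
                if not isinstance(val, Mapping):
                    raise ValueError(f"{path}.{key}: expected mapping")
                check(val, expected, f"{path}.{key}")
            elif not isinstance(val, expected):
                raise ValueError(
                    f"{path}.{key}: expected {expected.__name__}, "
                    f"got {type(val).__name__}"
                )

    check(report, schema)
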