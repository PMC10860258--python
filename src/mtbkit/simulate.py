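"""Seeded synthetic-cohort generator for closed-loop pipeline testing.

The generator emits a complete cohort bundle exhibiting the statistical
structure each pipeline stage assumes - a 22-tissue normal expression
reference, tumors with genes spiked over/under by a stated number of
reference SDs, mutation catalogs drawn multinomially from known signature
mixtures, planted arm-level gains/losses, driver variants and fusions
wired to a generated drug-rule knowledge base, and lesion-diameter
trajectories constructed to classify into every RECIST class - together
with the ground truth needed to verify recovery. All randomness flows
through one seeded ``numpy`` generator.

Expression noise is lognormal-like (Gaussian on the log2 scale) per gene
per tissue; a spike is an additive shift of ``k`` reference SDs on the
log scale. Mutation counts per subject are drawn to span the trial's
qualitative TMB ordering (neuroblastoma-like high, CNS-like low) without
attempting to reproduce the real cohort's distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mtbkit.io import (
    Arm,
    ArmMap,
    CohortBundle,
    CopyNumberSegment,
    DrugRule,
    DrugRuleSet,
    ExpressionMatrix,
    FusionEvent,
    LesionSeries,
    Milestones,
    SomaticEventSet,
    SomaticVariant,
)
from mtbkit.signatures import CONTEXTS_96, MutationCatalog, SignatureMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "synthetic_signature_matrix",
    "generate_mutation_catalog",
    "generate_lesion_series",
    "generate_cohort",
]

_PYRIMIDINE_SUBS = {
    "C>A": ("C", "A"),
    "C>G": ("C", "G"),
    "C>T": ("C", "T"),
    "T>A": ("T", "A"),
    "T>C": ("T", "C"),
    "T>G": ("T", "G"),
}

#: Driver genes with direct (tier-1) drug rules in the generated KB.
_DRIVER_RULES = [
    ("crizotinib", "ALK"),
    ("lapatinib", "ERBB4"),
    ("palbociclib", "CDK4"),
    ("dasatinib", "KIT"),
    ("olaparib", "BRCA2"),
]

#: Tier-2 wiring: altered gene -> drug-target gene, plus the direct rule
#: on the target.
_INFERENCE_RULES = [
    ("NF1", "MAP2K1", "trametinib"),
    ("PTEN", "MTOR", "sirolimus"),
]

#: Expression (tier-3) sensitivity rules: overexpression of the gene
#: suggests the drug.
_EXPRESSION_RULES = [
    ("topotecan", "TOP2A", "over"),
    ("YM155", "BIRC5", "over"),
    ("ribociclib", "CDK6", "over"),
    ("vorinostat", "HDAC2", "over"),
    ("vismodegib", "SMO", "over"),
    ("sorafenib", "PDGFRA", "over"),
    ("decitabine", "DNMT1", "over"),
    ("irinotecan", "TOP1", "over"),
    ("bortezomib", "PSMB5", "over"),
    ("everolimus", "RPS6KB1", "over"),
]

#: Expression resistance rules: overexpression vetoes the drug.
_RESISTANCE_RULES = [
    ("methotrexate", "DHFR", "over"),
    ("temozolomide", "MGMT", "over"),
]

_FUSIONS = [("EWSR1", "FLI1"), ("SS18", "SSX2")]

#: Per-type RECIST class frequencies used when assigning intended classes.
_RESPONSE_FREQS = {
    "neuroblastoma": {"NED": 0.04, "CR": 0.15, "PR": 0.0, "SD": 0.48, "PD": 0.33},
    "CNS": {"NED": 0.30, "CR": 0.05, "PR": 0.11, "SD": 0.27, "PD": 0.27},
    "rare": {"NED": 0.10, "CR": 0.08, "PR": 0.12, "SD": 0.30, "PD": 0.40},
}

#: Mean mutation-catalog size per tumor type (qualitative TMB ordering).
_MUTATIONS_BY_TYPE = {"neuroblastoma": 120, "CNS": 30, "rare": 50}

#: Type-characteristic signature-mixture Dirichlet concentrations.
_SIGNATURE_ALPHA = {
    "neuroblastoma": np.array([2.0, 1.0, 1.0, 8.0, 1.0]),
    "CNS": np.array([6.0, 2.0, 1.0, 1.0, 1.0]),
    "rare": np.array([3.0, 3.0, 2.0, 1.0, 2.0]),
}

#: Arm events characteristically planted per type (arm, direction).
_ARM_EVENTS_BY_TYPE = {
    "neuroblastoma": [("17q", "gain"), ("11q", "loss"), ("1p", "loss")],
    "CNS": [("17p", "loss")],
    "rare": [("8q", "gain"), ("16q", "loss")],
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with trial-like defaults.

    Defaults emulate the study conditions at desk scale: 22 normal
    tissues, spikes of 4 reference SDs, five synthetic signatures,
    arm events planted at fractions of at least 0.5, and RECIST class
    frequencies close to the trial's per-stratum best-response mix.
    """

    seed: int = 0
    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"neuroblastoma": 6, "CNS": 8, "rare": 14}
    )
    n_genes: int = 400
    n_normal_tissues: int = 22
    n_spike_over: int = 8
    n_spike_under: int = 4
    spike_sd: float = 4.0  # effect size k, in reference SDs
    n_signatures: int = 5
    arm_event_prob: float = 0.8
    planted_fraction_range: tuple[float, float] = (0.6, 0.95)
    arm_log2: float = 0.7
    segment_genes: int = 100
    fusion_prob: float = 0.15
    resistance_spike_prob: float = 0.2
    lesion_timepoints: int = 3

    def validate(self) -> None:
        if self.n_spike_over + self.n_spike_under > self.n_genes:
            raise ValueError("more spikes requested than genes available")
        if self.spike_sd <= 0:
            raise ValueError("spike effect size must be positive")
        if not 0 <= self.arm_event_prob <= 1:
            raise ValueError("arm_event_prob must be a probability")
        if any(n < 0 for n in self.n_subjects.values()):
            raise ValueError("subject counts must be >= 0")
        lo, hi = self.planted_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("planted fractions must lie in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, keyed by subject."""

    spiked_over: dict[str, set[str]] = field(default_factory=dict)
    spiked_under: dict[str, set[str]] = field(default_factory=dict)
    exposures: dict[str, np.ndarray] = field(default_factory=dict)
    signature_names: list[str] = field(default_factory=list)
    arm_events: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    intended_response: dict[str, str] = field(default_factory=dict)
    expected_drugs: dict[str, set[str]] = field(default_factory=dict)
    driver_variants: dict[str, set[str]] = field(default_factory=dict)


def synthetic_signature_matrix(
    n_signatures: int = 5, rng: np.random.Generator | None = None
) -> SignatureMatrix:
    """Well-separated synthetic signatures over the 96 contexts.

    Each signature concentrates 80% of its mass on its own disjoint block
    of bins (Dirichlet within the block) with a flat 20% background, so
    distinct mixtures remain identifiable by NNLS.
    """
    rng = rng or np.random.default_rng(0)
    block = 96 // n_signatures
    profiles = np.zeros((96, n_signatures))
    for s in range(n_signatures):
        lo = s * block
        hi = 96 if s == n_signatures - 1 else lo + block
        within = rng.dirichlet(np.ones(hi - lo))
        profiles[lo:hi, s] = 0.8 * within
        profiles[:, s] += 0.2 / 96
    profiles /= profiles.sum(axis=0, keepdims=True)
    return SignatureMatrix(profiles, [f"SigS{i+1}" for i in range(n_signatures)])


def generate_mutation_catalog(
    signatures: SignatureMatrix,
    pi: np.ndarray,
    n: int,
    rng: np.random.Generator | int,
    subject_id: str = "sim",
) -> MutationCatalog:
    """Draw a catalog of ``n`` mutations multinomially from mixture W @ pi."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("pi must lie on the probability simplex")
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = signatures.profiles @ pi
    counts = rng.multinomial(n, probs)
    return MutationCatalog(subject_id=subject_id, counts=counts)


def generate_lesion_series(
    intended_class: str,
    rng: np.random.Generator | int,
    subject_id: str = "sim",
    n_timepoints: int = 3,
) -> LesionSeries:
    """A lesion-sum trajectory guaranteed to classify as intended.

    Trajectories are built against the documented classification rules:
    CR ends at zero; PR's best change is drawn in [-80%, -35%]; SD stays
    strictly inside (-30%, +20%) of baseline without tripping the
    nadir-referenced PD rule; PD shows at least +20% and +5 mm over the
    nadir; NED has no measurable disease.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if intended_class == "NED":
        return LesionSeries(subject_id, baseline_sum=None, timepoint_sums=[],
                            ned_flag=True)
    baseline = float(rng.uniform(40.0, 120.0))
    if intended_class == "CR":
        mid = [float(baseline * rng.uniform(0.2, 0.6))
               for _ in range(max(0, n_timepoints - 1))]
        sums = sorted(mid, reverse=True) + [0.0]
    elif intended_class == "PR":
        best = baseline * (1.0 + rng.uniform(-0.80, -0.35))
        mid = [float(rng.uniform(best, baseline * 0.95))
               for _ in range(max(0, n_timepoints - 1))]
        sums = sorted(mid, reverse=True) + [float(best)]
    elif intended_class == "SD":
        # monotone non-increasing path inside the SD band never rises,
        # so the nadir-PD rule cannot trip
        changes = sorted(
            rng.uniform(-0.25, 0.15, size=n_timepoints), reverse=True
        )
        sums = [float(baseline * (1.0 + c)) for c in changes]
    elif intended_class == "PD":
        worst = baseline * (1.0 + rng.uniform(0.25, 0.60))
        if worst - baseline < 5.0:
            worst = baseline + 5.0 + rng.uniform(0.0, 5.0)
        lead = [float(baseline * rng.uniform(0.95, 1.1))
                for _ in range(max(0, n_timepoints - 1))]
        # keep pre-progression points from tripping or lowering the nadir
        lead = [min(x, baseline * 1.15) for x in lead]
        lead = [max(x, baseline) for x in lead]
        sums = lead + [float(worst)]
    else:
        raise ValueError(f"unknown intended class {intended_class!r}")
    return LesionSeries(subject_id, baseline_sum=baseline,
                        timepoint_sums=sums, ned_flag=False)


def _default_arm_map() -> ArmMap:
    """A compact synthetic genome: 6 chromosomes with p and q arms."""
    arms = []
    for i, chrom in enumerate(["1", "8", "11", "16", "17", "19"]):
        p_len = 40_000_000 + i * 5_000_000
        q_len = 60_000_000 + i * 5_000_000
        arms.append(Arm(f"{chrom}p", chrom, 1, p_len))
        arms.append(Arm(f"{chrom}q", chrom, p_len + 1, p_len + q_len))
    return ArmMap(arms)


def _build_rules() -> tuple[DrugRuleSet, dict[str, list[tuple[str, str]]]]:
    rules = []
    for drug, gene in _DRIVER_RULES:
        rules.append(DrugRule(drug, gene, "direct", "any", "sensitivity",
                              f"synthetic evidence: {drug}-{gene}"))
    inference_map: dict[str, list[tuple[str, str]]] = {}
    for altered, target, drug in _INFERENCE_RULES:
        inference_map.setdefault(altered, []).append(
            (target, f"synthetic hop {altered}->{target}")
        )
        rules.append(DrugRule(drug, target, "direct", "any", "sensitivity",
                              f"synthetic evidence: {drug}-{target}"))
    for drug, gene, direction in _EXPRESSION_RULES:
        rules.append(DrugRule(drug, gene, "expression", direction, "sensitivity",
                              f"synthetic evidence: {drug}-{gene}"))
    for drug, gene, direction in _RESISTANCE_RULES:
        rules.append(DrugRule(drug, gene, "expression", direction, "resistance",
                              f"synthetic evidence: {drug}-{gene} resistance"))
    for g5, g3 in _FUSIONS:
        rules.append(DrugRule(f"inhibitor_{g3}", g3, "direct", "any",
                              "sensitivity", f"synthetic evidence: {g3} fusion"))
    return DrugRuleSet(rules), inference_map


def _gene_universe(n_genes: int) -> list[str]:
    named = sorted(
        {g for _, g in _DRIVER_RULES}
        | {t for _, t, _ in _INFERENCE_RULES}
        | {a for a, _, _ in _INFERENCE_RULES}
        | {g for _, g, _ in _EXPRESSION_RULES}
        | {g for _, g, _ in _RESISTANCE_RULES}
        | {g for pair in _FUSIONS for g in pair}
    )
    fillers = [f"G{i:04d}" for i in range(n_genes - len(named))]
    return named + fillers


def generate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[CohortBundle, GroundTruth]:
    """Generate a full synthetic cohort and its ground truth.

    Deterministic for a fixed config (including seed): the same config
    always produces an identical bundle.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config.n_genes)
    n_genes = len(genes)
    arm_map = _default_arm_map()
    rules, inference_map = _build_rules()
    signatures = synthetic_signature_matrix(
        config.n_signatures, np.random.default_rng(config.seed + 1)
    )
    truth = GroundTruth(signature_names=list(signatures.names))

    # normal reference: per-gene location and scale on the log2 scale
    gene_mu = rng.uniform(2.0, 10.0, size=n_genes)
    gene_sd = rng.uniform(0.2, 0.6, size=n_genes)
    normal = gene_mu[:, None] + gene_sd[:, None] * rng.standard_normal(
        (n_genes, config.n_normal_tissues)
    )
    normal_ref = ExpressionMatrix(
        pd.DataFrame(
            normal, index=genes,
            columns=[f"tissue{t+1:02d}" for t in range(config.n_normal_tissues)],
        ),
        scale="normalized_log",
    )

    subjects: list[tuple[str, str]] = []
    for tumor_type in ("neuroblastoma", "CNS", "rare"):
        for i in range(config.n_subjects.get(tumor_type, 0)):
            subjects.append((f"{tumor_type[:3].upper()}{i+1:03d}", tumor_type))

    bundle = CohortBundle(
        normal_reference=normal_ref,
        arm_map=arm_map,
        rules=rules,
        inference_map=inference_map,
        blacklist={frozenset(p) for p in [("topotecan", "irinotecan")]},
    )
    expression_cols: dict[str, np.ndarray] = {}
    rule_over_genes = [g for _, g, d in _EXPRESSION_RULES if d == "over"]
    resistance_genes = [g for _, g, _ in _RESISTANCE_RULES]
    gene_index = {g: i for i, g in enumerate(genes)}
    driver_pool = [g for _, g in _DRIVER_RULES] + [a for a, _, _ in _INFERENCE_RULES]
    chroms = sorted({a.chrom for a in arm_map})

    for subject, tumor_type in subjects:
        bundle.tumor_types[subject] = tumor_type
        events = SomaticEventSet(subject_id=subject)
        truth.expected_drugs[subject] = set()

        # --- expression: baseline noise + spikes -------------------------
        x = gene_mu + gene_sd * rng.standard_normal(n_genes)
        # guarantee a handful of rule genes among the over-spikes so a
        # tier-3 plan always exists
        n_rule_spikes = min(3, config.n_spike_over, len(rule_over_genes))
        over = list(
            rng.choice(rule_over_genes, size=n_rule_spikes, replace=False)
        )
        others = [g for g in genes if g not in set(over) | set(resistance_genes)]
        over += list(
            rng.choice(others, size=config.n_spike_over - n_rule_spikes,
                       replace=False)
        )
        remaining = [g for g in others if g not in set(over)]
        under = list(
            rng.choice(remaining, size=config.n_spike_under, replace=False)
        )
        for g in over:
            x[gene_index[g]] += config.spike_sd * gene_sd[gene_index[g]]
        for g in under:
            x[gene_index[g]] -= config.spike_sd * gene_sd[gene_index[g]]
        if rng.uniform() < config.resistance_spike_prob:
            g = resistance_genes[int(rng.integers(len(resistance_genes)))]
            x[gene_index[g]] += config.spike_sd * gene_sd[gene_index[g]]
        expression_cols[subject] = x
        truth.spiked_over[subject] = set(over)
        truth.spiked_under[subject] = set(under)
        for drug, gene, direction in _EXPRESSION_RULES:
            if direction == "over" and gene in truth.spiked_over[subject]:
                truth.expected_drugs[subject].add(drug)

        # --- mutation catalog from a type-characteristic mixture ---------
        pi = rng.dirichlet(_SIGNATURE_ALPHA[tumor_type][: config.n_signatures])
        n_mut = max(10, int(rng.poisson(_MUTATIONS_BY_TYPE[tumor_type])))
        catalog = generate_mutation_catalog(signatures, pi, n_mut, rng, subject)
        truth.exposures[subject] = pi
        events.variants.extend(
            _variants_from_catalog(catalog, genes, chroms, rng, subject)
        )

        # --- driver variants wired to tier-1/2 rules ----------------------
        truth.driver_variants[subject] = set()
        if rng.uniform() < 0.6:
            gene = driver_pool[int(rng.integers(len(driver_pool)))]
            events.variants.append(
                SomaticVariant(
                    subject_id=subject,
                    chrom=chroms[int(rng.integers(len(chroms)))],
                    pos=int(rng.integers(1, 10_000_000)),
                    ref="C", alt="A", variant_class="SNV",
                    gene=gene, effect="missense",
                    protein_change=f"R{int(rng.integers(50, 1500))}Q",
                    trinucleotide_context="ACA",
                )
            )
            truth.driver_variants[subject].add(gene)
            for rule in rules.for_gene(gene, tier="direct"):
                truth.expected_drugs[subject].add(rule.drug)
            for target, _ in inference_map.get(gene, []):
                for rule in rules.for_gene(target, tier="direct"):
                    truth.expected_drugs[subject].add(rule.drug)

        # --- fusions ------------------------------------------------------
        if tumor_type == "rare" and rng.uniform() < config.fusion_prob:
            g5, g3 = _FUSIONS[int(rng.integers(len(_FUSIONS)))]
            events.fusions.append(FusionEvent(subject, g5, g3))
            for rule in rules.for_gene(g3, tier="direct"):
                truth.expected_drugs[subject].add(rule.drug)

        # --- arm-level CNV events -----------------------------------------
        truth.arm_events[subject] = set()
        if rng.uniform() < config.arm_event_prob:
            type_events = _ARM_EVENTS_BY_TYPE[tumor_type]
            k = int(rng.integers(1, len(type_events) + 1))
            picked = rng.choice(len(type_events), size=k, replace=False)
            for idx in picked:
                arm_id, direction = type_events[idx]
                arm = arm_map.arms[arm_id]
                frac = rng.uniform(*config.planted_fraction_range)
                length = int(frac * arm.length)
                start = arm.start + int(rng.integers(0, arm.length - length + 1))
                log2 = config.arm_log2 if direction == "gain" else -config.arm_log2
                events.segments.append(
                    CopyNumberSegment(
                        subject, arm.chrom, start, start + length - 1,
                        log2_ratio=float(log2),
                        n_genes=config.segment_genes,
                    )
                )
                truth.arm_events[subject].add((arm_id, direction))
        # neutral background segment on every chromosome
        for chrom in chroms:
            chrom_arms = arm_map.arms_on(chrom)
            end = max(a.end for a in chrom_arms)
            events.segments.append(
                CopyNumberSegment(
                    subject, chrom, 1, end,
                    log2_ratio=float(rng.uniform(-0.1, 0.1)),
                    n_genes=config.segment_genes * 4,
                )
            )

        # --- outcomes ------------------------------------------------------
        freqs = _RESPONSE_FREQS[tumor_type]
        classes = list(freqs)
        intended = classes[
            int(rng.choice(len(classes), p=np.array(list(freqs.values()))
                           / sum(freqs.values())))
        ]
        truth.intended_response[subject] = intended
        bundle.lesions[subject] = generate_lesion_series(
            intended, rng, subject, config.lesion_timepoints
        )
        seq = max(2.0, rng.normal(10.0, 3.0))
        report = seq + max(1.0, rng.normal(7.0, 2.0))
        board = report + max(1.0, rng.normal(6.0, 3.0))
        start = board + max(1.0, rng.normal(15.0, 10.0))
        end = start + max(7.0, rng.normal(156.0, 80.0))
        bundle.milestones[subject] = Milestones(
            subject, round(seq), round(report), round(board), round(start),
            round(end),
        )
        bundle.events[subject] = events

    if subjects:
        bundle.expression = ExpressionMatrix(
            pd.DataFrame(
                {s: expression_cols[s] for s, _ in subjects}, index=genes
            ),
            scale="normalized_log",
        )
    bundle.validate()
    return bundle, truth


def _variants_from_catalog(
    catalog: MutationCatalog,
    genes: Sequence[str],
    chroms: Sequence[str],
    rng: np.random.Generator,
    subject: str,
) -> list[SomaticVariant]:
    """Expand a 96-bin catalog into concrete pyrimidine-strand SNV records."""
    variants = []
    for bin_idx, count in enumerate(catalog.counts):
        if count == 0:
            continue
        label = CONTEXTS_96[bin_idx]
        five, sub, three = label[0], label[2:5], label[6]
        ref, alt = _PYRIMIDINE_SUBS[sub]
        context = f"{five}{ref}{three}"
        for _ in range(count):
            variants.append(
                SomaticVariant(
                    subject_id=subject,
                    chrom=chroms[int(rng.integers(len(chroms)))],
                    pos=int(rng.integers(1, 50_000_000)),
                    ref=ref,
                    alt=alt,
                    variant_class="SNV",
                    gene=str(genes[int(rng.integers(len(genes)))]),
                    effect="missense",
                    trinucleotide_context=context,
                )
            )
    return variants
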