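"""Per-subject and cohort orchestration over the pipeline stages.

A run is driven by a single manifest (YAML) naming every input file and
the parameter block; outputs embed the parameters and the manifest hash
so a rerun with identical inputs reproduces identical files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from mtbkit import expression as expr
from mtbkit import landscape, matching, outcomes, signatures
from mtbkit.io import (
    CohortBundle,
    read_arm_map,
    read_expression,
    read_inference_map,
    read_knowledge_base,
    read_lesions,
    read_milestones,
    read_segments,
    read_variants,
    read_fusions,
    write_arm_map,
    write_expression,
    write_fusions,
    write_knowledge_base,
    write_lesions,
    write_milestones,
    write_segments,
    write_variants,
    SomaticEventSet,
)

logger = logging.getLogger("mtbkit")

__all__ = [
    "RunParameters",
    "run_subject",
    "run_cohort",
    "write_bundle",
    "load_bundle",
]


@dataclass
class RunParameters:
    """The tunable parameters of an end-to-end run."""

    tau: float = 2.0
    sd_floor: float = 0.1
    min_genes: int = 50
    log2_thresh: float = 0.5
    arm_fraction: float = 0.5
    min_recurrent_subjects: int = 15
    callable_mb: float = 30.0
    max_drugs: int = 4
    exposure_cutoff: float = 0.0
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "tau": self.tau,
            "sd_floor": self.sd_floor,
            "min_genes": self.min_genes,
            "log2_thresh": self.log2_thresh,
            "arm_fraction": self.arm_fraction,
            "min_recurrent_subjects": self.min_recurrent_subjects,
            "callable_mb": self.callable_mb,
            "max_drugs": self.max_drugs,
            "exposure_cutoff": self.exposure_cutoff,
            "seed": self.seed,
        }


@dataclass
class SubjectResult:
    subject_id: str
    status: str  # "ok" | "no_plan"
    report: dict | None
    nrz: expr.NRZScoreTable | None
    tmb: landscape.TMBResult | None
    arm_events: list[landscape.ArmEvent] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def run_subject(
    bundle: CohortBundle,
    subject_id: str,
    params: RunParameters | None = None,
    sig_matrix: signatures.SignatureMatrix | None = None,
) -> SubjectResult:
    """Execute the per-subject flow: scoring, landscape, matching, report.

    Stages whose inputs are missing are skipped with an explicit note and
    the tiers depending on them disabled; a subject whose candidates are
    exhausted by vetoes gets status ``no_plan`` rather than an error.
    """
    params = params or RunParameters()
    if subject_id not in bundle.tumor_types:
        raise KeyError(f"unknown subject {subject_id}")
    notes: list[str] = []
    events = bundle.events.get(subject_id, SomaticEventSet(subject_id))

    nrz = None
    if (
        bundle.expression is not None
        and subject_id in bundle.expression.sample_ids
        and bundle.normal_reference is not None
    ):
        ref = expr.build_normal_reference(
            bundle.normal_reference, sd_floor=params.sd_floor
        )
        nrz = expr.nrz_score(
            bundle.expression.sample(subject_id), ref, tau=params.tau,
            subject_id=subject_id,
        )
    else:
        notes.append("expression stage skipped: no tumor expression or reference")

    tmb = landscape.compute_tmb(
        events.variants, callable_mb=params.callable_mb, subject_id=subject_id
    )
    notes.append(f"TMB denominator assumed callable_mb={params.callable_mb}")
    arm_events = []
    if bundle.arm_map is not None:
        arm_events = landscape.call_arm_events(
            events.segments, bundle.arm_map,
            min_genes=params.min_genes,
            log2_thresh=params.log2_thresh,
            arm_fraction=params.arm_fraction,
        )
    else:
        notes.append("arm-event stage skipped: no arm map")

    candidates: list[matching.MatchCandidate] = []
    if bundle.rules is not None:
        candidates += matching.match_tier1(events, bundle.rules)
        candidates += matching.match_tier2(
            events, bundle.rules, bundle.inference_map
        )
        if nrz is not None:
            candidates += matching.match_tier3(nrz, bundle.rules)
        else:
            notes.append("tier-3 matching disabled: no NRZ scores")
    else:
        notes.append("matching skipped: no knowledge base")

    logger.info(
        "subject %s: %d variants, %d arm events, %d candidates",
        subject_id, len(events.variants), len(arm_events), len(candidates),
    )
    report = None
    status = "ok"
    try:
        plan = matching.assemble_combination(
            candidates,
            blacklist=bundle.blacklist,
            max_drugs=params.max_drugs,
            subject_id=subject_id,
        )
        report = matching.generate_report(
            plan, parameters=params.as_dict(), notes=notes
        )
    except matching.NoPlanError as exc:
        status = "no_plan"
        notes.append(str(exc))
    return SubjectResult(
        subject_id=subject_id,
        status=status,
        report=report,
        nrz=nrz,
        tmb=tmb,
        arm_events=arm_events,
        notes=notes,
    )


def run_cohort(
    bundle: CohortBundle,
    params: RunParameters | None = None,
    gene_panel: list[str] | None = None,
) -> dict:
    """Cohort-level summaries: oncoprint, signature table, benefit, feasibility."""
    params = params or RunParameters()
    if not bundle.subjects:
        raise ValueError("cohort is empty")
    all_arm_events = []
    catalogs = {}
    for subject in bundle.subjects:
        events = bundle.events.get(subject, SomaticEventSet(subject))
        if bundle.arm_map is not None:
            all_arm_events += landscape.call_arm_events(
                events.segments, bundle.arm_map,
                min_genes=params.min_genes,
                log2_thresh=params.log2_thresh,
                arm_fraction=params.arm_fraction,
            )
        catalog = signatures.catalog_from_variants(events.variants, subject)
        if catalog.total > 0:
            catalogs[subject] = catalog
    recurrent = landscape.cohort_arm_recurrence(
        all_arm_events, min_subjects=params.min_recurrent_subjects
    )
    summary_catalogs = {s: c.as_series() for s, c in catalogs.items()}

    responses = []
    for subject in bundle.subjects:
        if subject in bundle.lesions:
            responses.append(
                outcomes.classify_best_response(bundle.lesions[subject])
            )
    summary: dict = {"n_subjects": len(bundle.subjects)}
    if responses:
        proportion, percent = outcomes.clinical_benefit_rate(responses)
        measurable = [r for r in responses if r.best_percent_change is not None]
        summary["benefit"] = {"proportion": proportion, "percent": percent}
        if measurable:
            wf = outcomes.waterfall_table(measurable)
            summary["waterfall"] = {
                k: wf[k] for k in ("n", "n_decrease", "n_no_change",
                                   "n_increase", "percent_decrease")
            }
        by_type: dict[str, list] = {}
        for r in responses:
            by_type.setdefault(bundle.tumor_types[r.subject_id], []).append(r)
        summary["benefit_by_type"] = {
            t: outcomes.clinical_benefit_rate(rs)[1] for t, rs in sorted(by_type.items())
        }
    if bundle.milestones:
        summary["feasibility"] = outcomes.feasibility_summary(
            bundle.milestones.values()
        )
    if gene_panel and bundle.events:
        summary["oncoprint"] = landscape.build_oncoprint(
            bundle, gene_panel, recurrent
        )
    summary["recurrent_arms"] = recurrent
    if summary_catalogs:
        summary["catalogs"] = pd.DataFrame(summary_catalogs)
    summary["tmb"] = {
        s: landscape.compute_tmb(
            bundle.events[s].variants, params.callable_mb, s
        ).tmb
        for s in bundle.subjects
        if s in bundle.events
    }
    return summary


# ---------------------------------------------------------------------------
# bundle persistence (directory of flat files + manifest)
# ---------------------------------------------------------------------------


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> Path:
    """Write a bundle as a directory of TSV/JSON files plus manifest.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": {}, "shared": {}}
    all_variants, all_segments, all_fusions = [], [], []
    for subject in bundle.subjects:
        events = bundle.events.get(subject)
        if events:
            all_variants += events.variants
            all_segments += events.segments
            all_fusions += events.fusions
        manifest["subjects"][subject] = {
            "tumor_type": bundle.tumor_types[subject]
        }
    write_variants(all_variants, outdir / "variants.tsv")
    write_segments(all_segments, outdir / "segments.tsv")
    write_fusions(all_fusions, outdir / "fusions.tsv")
    manifest["shared"]["variants"] = "variants.tsv"
    manifest["shared"]["segments"] = "segments.tsv"
    manifest["shared"]["fusions"] = "fusions.tsv"
    if bundle.expression is not None:
        write_expression(bundle.expression, outdir / "expression.tsv")
        manifest["shared"]["expression"] = "expression.tsv"
        manifest["shared"]["expression_scale"] = bundle.expression.scale
    if bundle.normal_reference is not None:
        write_expression(bundle.normal_reference, outdir / "normal_reference.tsv")
        manifest["shared"]["normal_reference"] = "normal_reference.tsv"
        manifest["shared"]["normal_reference_scale"] = bundle.normal_reference.scale
    if bundle.arm_map is not None:
        write_arm_map(bundle.arm_map, outdir / "arms.tsv")
        manifest["shared"]["arms"] = "arms.tsv"
    if bundle.rules is not None:
        write_knowledge_base(bundle.rules, outdir / "rules.tsv")
        manifest["shared"]["rules"] = "rules.tsv"
    if bundle.inference_map:
        rows = [
            {"gene": g, "target_gene": t, "evidence": e}
            for g, links in sorted(bundle.inference_map.items())
            for t, e in links
        ]
        pd.DataFrame(rows, columns=["gene", "target_gene", "evidence"]).to_csv(
            outdir / "inference_map.tsv", sep="\t", index=False
        )
        manifest["shared"]["inference_map"] = "inference_map.tsv"
    if bundle.blacklist:
        rows = [
            {"drug_a": a, "drug_b": b}
            for a, b in sorted(tuple(sorted(p)) for p in bundle.blacklist)
        ]
        pd.DataFrame(rows, columns=["drug_a", "drug_b"]).to_csv(
            outdir / "blacklist.tsv", sep="\t", index=False
        )
        manifest["shared"]["blacklist"] = "blacklist.tsv"
    if bundle.lesions:
        write_lesions(bundle.lesions, outdir / "lesions.tsv")
        manifest["shared"]["lesions"] = "lesions.tsv"
    if bundle.milestones:
        write_milestones(bundle.milestones, outdir / "milestones.tsv")
        manifest["shared"]["milestones"] = "milestones.tsv"
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def load_bundle(manifest_path: str | Path) -> CohortBundle:
    """Load a bundle from a manifest written by :func:`write_bundle`."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    shared = manifest.get("shared", {})
    bundle = CohortBundle()
    for subject, info in manifest.get("subjects", {}).items():
        bundle.tumor_types[subject] = info["tumor_type"]
        bundle.events[subject] = SomaticEventSet(subject)

    def _path(key: str) -> Path | None:
        return base / shared[key] if key in shared else None

    if _path("variants"):
        for v in read_variants(_path("variants"), dialect="tsv"):
            bundle.events.setdefault(
                v.subject_id, SomaticEventSet(v.subject_id)
            ).variants.append(v)
    if _path("segments"):
        for s in read_segments(_path("segments")):
            bundle.events.setdefault(
                s.subject_id, SomaticEventSet(s.subject_id)
            ).segments.append(s)
    if _path("fusions"):
        for f in read_fusions(_path("fusions")):
            bundle.events.setdefault(
                f.subject_id, SomaticEventSet(f.subject_id)
            ).fusions.append(f)
    if _path("expression"):
        bundle.expression = read_expression(
            _path("expression"), scale=shared.get("expression_scale", "raw_counts")
        )
    if _path("normal_reference"):
        bundle.normal_reference = read_expression(
            _path("normal_reference"),
            scale=shared.get("normal_reference_scale", "normalized_log"),
        )
    if _path("arms"):
        bundle.arm_map = read_arm_map(_path("arms"))
    if _path("rules"):
        bundle.rules = read_knowledge_base(_path("rules"))
    if _path("inference_map"):
        bundle.inference_map = read_inference_map(_path("inference_map"))
    if _path("blacklist"):
        df = pd.read_csv(_path("blacklist"), sep="\t", dtype=str)
        bundle.blacklist = {
            frozenset((r.drug_a, r.drug_b)) for r in df.itertuples(index=False)
        }
    if _path("lesions"):
        bundle.lesions = read_lesions(_path("lesions"))
    if _path("milestones"):
        bundle.milestones = read_milestones(_path("milestones"))
    bundle.validate()
    return bundle


def manifest_hash(manifest_path: str | Path) -> str:
    """Stable content hash of a manifest, embedded in run outputs."""
    data = Path(manifest_path).read_bytes()
    return hashlib.sha256(data).hexdigest()[:16]
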