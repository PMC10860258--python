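"""Data model and readers/writers for every external format the pipeline touches.

All coordinates held in memory are 1-based inclusive; input dialects
(e.g. 0-based half-open SEG exports) are converted at the boundary.
Gene identity is by plain symbol, case-sensitive, with no alias resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SomaticVariant",
    "CopyNumberSegment",
    "FusionEvent",
    "ExpressionMatrix",
    "Arm",
    "ArmMap",
    "DrugRule",
    "DrugRuleSet",
    "SomaticEventSet",
    "LesionSeries",
    "Milestones",
    "CohortBundle",
    "MalformedRecordError",
    "read_variants",
    "write_variants",
    "read_segments",
    "write_segments",
    "read_fusions",
    "write_fusions",
    "read_expression",
    "write_expression",
    "read_knowledge_base",
    "write_knowledge_base",
    "read_arm_map",
    "arm_map_from_cytoband",
    "write_arm_map",
    "read_inference_map",
    "read_lesions",
    "write_lesions",
    "read_milestones",
    "write_milestones",
]

VARIANT_CLASSES = ("SNV", "insertion", "deletion")
RULE_TIERS = ("direct", "inferred", "expression")
RULE_DIRECTIONS = ("over", "under", "any")
RULE_MODES = ("sensitivity", "resistance")
TUMOR_TYPES = ("neuroblastoma", "CNS", "rare")

_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MILESTONE_ORDER = (
    "sequencing",
    "report",
    "tumor_board",
    "treatment_start",
    "end_of_therapy",
)


class MalformedRecordError(ValueError):
    """A record in an input file violates the format or a model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic SNV or small indel with its annotation.

    ``trinucleotide_context`` is the pyrimidine-strand 3-mer around an SNV
    (the reference base, or its complement for purine references, at the
    center). It may be supplied by the caller or derived from a genome FASTA.
    """

    subject_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    gene: str = ""
    effect: str = ""
    protein_change: str | None = None
    trinucleotide_context: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MalformedRecordError(f"pos must be >= 1, got {self.pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise MalformedRecordError(
                f"variant_class must be one of {VARIANT_CLASSES}, got "
                f"{self.variant_class!r}"
            )
        if self.variant_class == "SNV" and not (
            len(self.ref) == 1 and len(self.alt) == 1
        ):
            raise MalformedRecordError(
                f"SNV requires single-base alleles, got {self.ref}>{self.alt}"
            )
        ctx = self.trinucleotide_context
        if ctx is not None:
            if len(ctx) != 3 or any(b not in _COMPLEMENT for b in ctx):
                raise MalformedRecordError(
                    f"trinucleotide context must be a 3-mer over ACGT, got {ctx!r}"
                )
            if ctx[1] not in _PYRIMIDINES:
                raise MalformedRecordError(
                    f"trinucleotide context center must be a pyrimidine, got {ctx!r}"
                )
            if self.variant_class == "SNV":
                expected = self.ref if self.ref in _PYRIMIDINES else _COMPLEMENT[self.ref]
                if ctx[1] != expected:
                    raise MalformedRecordError(
                        f"context center {ctx[1]!r} does not match reference "
                        f"allele {self.ref!r} on the pyrimidine strand"
                    )


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number segment with its log2 tumor/normal ratio and gene count."""

    subject_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MalformedRecordError(
                f"segment start {self.start} > end {self.end}"
            )
        if self.n_genes < 0:
            raise MalformedRecordError(f"n_genes must be >= 0, got {self.n_genes}")
        if not np.isfinite(self.log2_ratio):
            raise MalformedRecordError("log2_ratio must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FusionEvent:
    """A gene fusion call with its 5' and 3' partners."""

    subject_id: str
    gene_5p: str
    gene_3p: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.gene_5p or not self.gene_3p:
            raise MalformedRecordError("fusion partners must be non-empty symbols")
        if not self.label:
            object.__setattr__(self, "label", f"{self.gene_5p}_{self.gene_3p}")


class ExpressionMatrix:
    """A genes x samples expression table with an explicit scale flag.

    ``scale`` is either ``raw_counts`` (non-negative counts, the substrate of
    :func:`mtbkit.expression.normalize_counts`) or ``normalized_log``
    (already on the log2 scale on which NRZ scoring operates).
    """

    SCALES = ("raw_counts", "normalized_log")

    def __init__(self, values: pd.DataFrame, scale: str = "raw_counts") -> None:
        if scale not in self.SCALES:
            raise ValueError(f"scale must be one of {self.SCALES}, got {scale!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise MalformedRecordError(f"duplicate gene ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise MalformedRecordError(f"duplicate sample ids: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise MalformedRecordError("expression values must all be finite")
        if scale == "raw_counts" and arr.size and arr.min() < 0:
            raise MalformedRecordError("raw counts must be non-negative")
        self.values = values.astype(float)
        self.scale = scale

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's expression vector indexed by gene."""
        return self.values[sample_id]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, scale={self.scale})"


@dataclass(frozen=True)
class Arm:
    arm_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MalformedRecordError(
                f"arm {self.arm_id}: length must be positive"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ArmMap:
    """Chromosome-arm geometry (1-based inclusive intervals per arm)."""

    def __init__(self, arms: Iterable[Arm]) -> None:
        self.arms: dict[str, Arm] = {}
        by_chrom: dict[str, list[Arm]] = {}
        for arm in arms:
            if arm.arm_id in self.arms:
                raise MalformedRecordError(f"duplicate arm id {arm.arm_id}")
            self.arms[arm.arm_id] = arm
            by_chrom.setdefault(arm.chrom, []).append(arm)
        for chrom, chrom_arms in by_chrom.items():
            chrom_arms.sort(key=lambda a: a.start)
            for a, b in zip(chrom_arms, chrom_arms[1:]):
                if b.start <= a.end:
                    raise MalformedRecordError(
                        f"arms {a.arm_id} and {b.arm_id} overlap on {chrom}"
                    )
        self._by_chrom = by_chrom

    def arms_on(self, chrom: str) -> list[Arm]:
        return list(self._by_chrom.get(chrom, []))

    def __contains__(self, arm_id: str) -> bool:
        return arm_id in self.arms

    def __iter__(self):
        return iter(self.arms.values())

    def __len__(self) -> int:
        return len(self.arms)


@dataclass(frozen=True)
class DrugRule:
    """One drug-gene rule from the knowledge base.

    Tier ``direct``/``inferred`` rules match somatic events and carry
    direction ``any``; tier ``expression`` rules match NRZ flags and must
    state ``over`` or ``under``. ``mode`` distinguishes sensitivity rules
    (the drug is a candidate) from resistance rules (the drug is vetoed).
    """

    drug: str
    gene: str
    tier: str
    direction: str = "any"
    mode: str = "sensitivity"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.tier not in RULE_TIERS:
            raise MalformedRecordError(f"unknown tier {self.tier!r}")
        if self.direction not in RULE_DIRECTIONS:
            raise MalformedRecordError(f"unknown direction {self.direction!r}")
        if self.mode not in RULE_MODES:
            raise MalformedRecordError(f"unknown mode {self.mode!r}")
        if self.tier == "expression" and self.direction not in ("over", "under"):
            raise MalformedRecordError(
                f"expression rule ({self.drug}, {self.gene}) must state a "
                f"direction of over or under, got {self.direction!r}"
            )
        if self.tier in ("direct", "inferred") and self.direction != "any":
            raise MalformedRecordError(
                f"{self.tier} rule ({self.drug}, {self.gene}) must have "
                f"direction=any, got {self.direction!r}"
            )


class DrugRuleSet:
    """The drug-gene knowledge base, indexed by gene for matching."""

    def __init__(self, rules: Iterable[DrugRule]) -> None:
        self.rules = list(rules)
        self._by_gene: dict[str, list[DrugRule]] = {}
        for rule in self.rules:
            self._by_gene.setdefault(rule.gene, []).append(rule)

    def for_gene(self, gene: str, tier: str | None = None) -> list[DrugRule]:
        rules = self._by_gene.get(gene, [])
        if tier is not None:
            rules = [r for r in rules if r.tier == tier]
        return rules

    @property
    def genes(self) -> set[str]:
        return set(self._by_gene)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass
class SomaticEventSet:
    """All somatic events called for one subject's biopsy."""

    subject_id: str
    variants: list[SomaticVariant] = field(default_factory=list)
    segments: list[CopyNumberSegment] = field(default_factory=list)
    fusions: list[FusionEvent] = field(default_factory=list)


@dataclass
class LesionSeries:
    """Target-lesion diameter sums (mm) for one subject over time.

    ``baseline_sum`` is the pre-cycle-1 sum of longest diameters;
    ``timepoint_sums`` follow in scan order. ``ned_flag`` marks subjects
    rendered free of measurable disease by surgery before cycle 1.
    """

    subject_id: str
    baseline_sum: float | None
    timepoint_sums: list[float] = field(default_factory=list)
    ned_flag: bool = False

    def __post_init__(self) -> None:
        if not self.ned_flag and self.baseline_sum is None:
            raise MalformedRecordError(
                f"{self.subject_id}: baseline required unless NED"
            )
        for s in ([self.baseline_sum] if self.baseline_sum is not None else []) + list(
            self.timepoint_sums
        ):
            if s < 0:
                raise MalformedRecordError("lesion sums must be >= 0")


@dataclass
class Milestones:
    """Days from biopsy to each workflow milestone for one subject.

    Milestones, in order: sequencing complete, analysis/report, tumor-board
    decision, treatment start, end of therapy. Missing values are allowed;
    present values must be non-negative and non-decreasing in that order.
    """

    subject_id: str
    sequencing: float | None = None
    report: float | None = None
    tumor_board: float | None = None
    treatment_start: float | None = None
    end_of_therapy: float | None = None

    def __post_init__(self) -> None:
        prev = None
        for name in MILESTONE_ORDER:
            val = getattr(self, name)
            if val is None:
                continue
            if val < 0:
                raise MalformedRecordError(
                    f"{self.subject_id}: milestone {name} is negative"
                )
            if prev is not None and val < prev:
                raise MalformedRecordError(
                    f"{self.subject_id}: milestone {name} precedes an earlier one"
                )
            prev = val

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in MILESTONE_ORDER}


@dataclass
class CohortBundle:
    """Everything the pipeline needs for one cohort run.

    Per-subject somatic events, tumor expression, lesion and milestone
    tables, and tumor-type labels, plus the shared normal-reference
    expression matrix, arm map, drug-rule knowledge base, tier-2 inference
    map and drug-pair interaction blacklist.
    """

    events: dict[str, SomaticEventSet] = field(default_factory=dict)
    expression: ExpressionMatrix | None = None
    lesions: dict[str, LesionSeries] = field(default_factory=dict)
    milestones: dict[str, Milestones] = field(default_factory=dict)
    tumor_types: dict[str, str] = field(default_factory=dict)
    normal_reference: ExpressionMatrix | None = None
    arm_map: ArmMap | None = None
    rules: DrugRuleSet | None = None
    inference_map: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    blacklist: set[frozenset[str]] = field(default_factory=set)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.tumor_types)

    def validate(self) -> None:
        """Check cross-table referential integrity."""
        registry = set(self.tumor_types)
        for name, table in (
            ("events", self.events),
            ("lesions", self.lesions),
            ("milestones", self.milestones),
        ):
            unknown = set(table) - registry
            if unknown:
                raise MalformedRecordError(
                    f"{name} references unregistered subjects: {sorted(unknown)}"
                )
        if self.expression is not None:
            unknown = set(self.expression.sample_ids) - registry
            if unknown:
                raise MalformedRecordError(
                    f"expression references unregistered subjects: {sorted(unknown)}"
                )
        for subj, label in self.tumor_types.items():
            if label not in TUMOR_TYPES:
                raise MalformedRecordError(
                    f"subject {subj}: unknown tumor type {label!r}"
                )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = {
    "subject": "subject",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "effect": "effect",
    "protein_change": "protein_change",
    "context": "context",
}

# INFO keys used when reading annotation from VCF
_VCF_INFO_KEYS = {
    "gene": "GENE",
    "effect": "EFFECT",
    "protein_change": "PCHANGE",
    "context": "CONTEXT",
}


def _classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    return "deletion"


def read_variants(
    path: str | Path,
    dialect: str = "auto",
    subject_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
    info_keys: Mapping[str, str] | None = None,
) -> list[SomaticVariant]:
    """Read somatic variants from a VCF 4.x file or a MAF-like TSV.

    One record is emitted per ALT allele. ``variant_class`` is derived from
    allele lengths. For VCF, annotation is taken from INFO keys (defaults
    GENE/EFFECT/PCHANGE/CONTEXT, override via ``info_keys``) and the subject
    from the single sample column unless ``subject_id`` is given. For TSV,
    ``column_map`` maps the model fields to file columns.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "vcf":
        return _read_variants_vcf(path, subject_id, info_keys)
    if dialect == "tsv":
        return _read_variants_tsv(path, subject_id, column_map)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_variants_vcf(
    path: Path,
    subject_id: str | None,
    info_keys: Mapping[str, str] | None,
) -> list[SomaticVariant]:
    from cyvcf2 import VCF

    keys = dict(_VCF_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    vcf = VCF(str(path))
    if subject_id is None:
        subject_id = vcf.samples[0] if vcf.samples else path.stem
    out: list[SomaticVariant] = []
    for rec in vcf:
        for alt in rec.ALT:
            out.append(
                SomaticVariant(
                    subject_id=subject_id,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    variant_class=_classify_alleles(rec.REF, alt),
                    gene=rec.INFO.get(keys["gene"]) or "",
                    effect=rec.INFO.get(keys["effect"]) or "",
                    protein_change=rec.INFO.get(keys["protein_change"]),
                    trinucleotide_context=rec.INFO.get(keys["context"]),
                )
            )
    vcf.close()
    return out


def _read_variants_tsv(
    path: Path,
    subject_id: str | None,
    column_map: Mapping[str, str] | None,
) -> list[SomaticVariant]:
    cols = dict(_VARIANT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [cols[k] for k in ("chrom", "pos", "ref", "alt")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"{path}: missing columns {missing}")
    out: list[SomaticVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            ref, alt = row[cols["ref"]], row[cols["alt"]]
            out.append(
                SomaticVariant(
                    subject_id=subject_id or row.get(cols["subject"], path.stem),
                    chrom=row[cols["chrom"]],
                    pos=int(row[cols["pos"]]),
                    ref=ref,
                    alt=alt,
                    variant_class=_classify_alleles(ref, alt),
                    gene=row.get(cols["gene"], ""),
                    effect=row.get(cols["effect"], ""),
                    protein_change=row.get(cols["protein_change"]) or None,
                    trinucleotide_context=row.get(cols["context"]) or None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise MalformedRecordError(f"{path} line {i}: {exc}") from exc
    return out


def write_variants(variants: Sequence[SomaticVariant], path: str | Path) -> None:
    """Write variants as the MAF-like TSV dialect that round-trips read_variants."""
    rows = [
        {
            "subject": v.subject_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "effect": v.effect,
            "protein_change": v.protein_change or "",
            "context": v.trinucleotide_context or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=list(_VARIANT_COLUMNS.values())).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

_SEGMENT_COLUMNS = ["subject", "chrom", "start", "end", "log2_ratio", "n_genes"]


def read_segments(
    path: str | Path,
    dialect: str = "one_based",
    subject_id: str | None = None,
) -> list[CopyNumberSegment]:
    """Read copy-number segments from a SEG-style TSV.

    ``dialect`` is ``one_based`` (1-based inclusive, the internal convention)
    or ``zero_half_open`` (BED-style; start is incremented on read).
    """
    if dialect not in ("one_based", "zero_half_open"):
        raise ValueError(f"unknown segment dialect {dialect!r}")
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SEGMENT_COLUMNS if c not in df.columns and c != "subject"]
    if missing:
        raise MalformedRecordError(f"{path}: missing columns {missing}")
    out: list[CopyNumberSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            start, end = int(row["start"]), int(row["end"])
            if dialect == "zero_half_open":
                start += 1
            out.append(
                CopyNumberSegment(
                    subject_id=subject_id or row.get("subject", Path(path).stem),
                    chrom=row["chrom"],
                    start=start,
                    end=end,
                    log2_ratio=float(row["log2_ratio"]),
                    n_genes=int(row["n_genes"]),
                )
            )
        except (ValueError, MalformedRecordError) as exc:
            raise MalformedRecordError(f"{path} line {i}: {exc}") from exc
    return out


def write_segments(segments: Sequence[CopyNumberSegment], path: str | Path) -> None:
    rows = [
        {
            "subject": s.subject_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "log2_ratio": s.log2_ratio,
            "n_genes": s.n_genes,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fusions
# ---------------------------------------------------------------------------


def read_fusions(path: str | Path, subject_id: str | None = None) -> list[FusionEvent]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_5p", "gene_3p"):
        if col not in df.columns:
            raise MalformedRecordError(f"{path}: missing column {col}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            out.append(
                FusionEvent(
                    subject_id=subject_id or row.get("subject", Path(path).stem),
                    gene_5p=row["gene_5p"],
                    gene_3p=row["gene_3p"],
                    label=row.get("label", ""),
                )
            )
        except MalformedRecordError as exc:
            raise MalformedRecordError(f"{path} line {i}: {exc}") from exc
    return out


def write_fusions(fusions: Sequence[FusionEvent], path: str | Path) -> None:
    rows = [
        {"subject": f.subject_id, "gene_5p": f.gene_5p, "gene_3p": f.gene_3p, "label": f.label}
        for f in fusions
    ]
    pd.DataFrame(rows, columns=["subject", "gene_5p", "gene_3p", "label"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: str = "raw_counts") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Supports TSV (gene ids in the first column) and MatrixMarket ``.mtx``
    with ``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecar files.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(str(path))
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        genes = Path(str(path)[: -len(".mtx")] + ".genes.txt").read_text().split()
        samples = Path(str(path)[: -len(".mtx")] + ".samples.txt").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, scale=scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# drug-rule knowledge base
# ---------------------------------------------------------------------------


def read_knowledge_base(path: str | Path) -> DrugRuleSet:
    """Read the drug-gene rules knowledge base from TSV or JSON.

    Duplicate (drug, gene, tier, direction, mode) rows are collapsed into a
    single rule whose evidence concatenates the individual citations.
    Invalid rows are reported together with their positions.
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        df = pd.DataFrame(raw)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return DrugRuleSet([])
    required = ["drug", "gene", "tier", "direction", "mode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"{path}: missing columns {missing}")
    if "evidence" not in df.columns:
        df["evidence"] = ""
    rules: dict[tuple, DrugRule] = {}
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        key = (row["drug"], row["gene"], row["tier"], row["direction"], row["mode"])
        try:
            rule = DrugRule(
                drug=row["drug"],
                gene=row["gene"],
                tier=row["tier"],
                direction=row["direction"],
                mode=row["mode"],
                evidence=str(row.get("evidence", "") or ""),
            )
        except MalformedRecordError as exc:
            errors.append(f"line {i}: {exc}")
            continue
        if key in rules:
            prior = rules[key]
            merged = "; ".join(e for e in (prior.evidence, rule.evidence) if e)
            rules[key] = DrugRule(*key, evidence=merged)
        else:
            rules[key] = rule
    if errors:
        raise MalformedRecordError(f"{path}: invalid rules:\n" + "\n".join(errors))
    return DrugRuleSet(rules.values())


def write_knowledge_base(rules: DrugRuleSet, path: str | Path) -> None:
    rows = [
        {
            "drug": r.drug,
            "gene": r.gene,
            "tier": r.tier,
            "direction": r.direction,
            "mode": r.mode,
            "evidence": r.evidence,
        }
        for r in rules
    ]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2, sort_keys=True))
    else:
        pd.DataFrame(
            rows, columns=["drug", "gene", "tier", "direction", "mode", "evidence"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# arm map
# ---------------------------------------------------------------------------


def arm_map_from_cytoband(path: str | Path) -> ArmMap:
    """Build an ArmMap from a UCSC cytoBand file.

    cytoBand coordinates are 0-based half-open; each chromosome's p arm
    spans its p bands and the q arm its q bands.
    """
    df = pd.read_csv(
        Path(path),
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str, "stain": str},
    )
    arms: list[Arm] = []
    for (chrom, arm_letter), grp in df.assign(
        arm_letter=df["band"].str[0]
    ).groupby(["chrom", "arm_letter"], sort=True):
        if arm_letter not in ("p", "q"):
            continue
        chrom_label = chrom[3:] if chrom.startswith("chr") else chrom
        arms.append(
            Arm(
                arm_id=f"{chrom_label}{arm_letter}",
                chrom=chrom,
                start=int(grp["start"].min()) + 1,
                end=int(grp["end"].max()),
            )
        )
    return ArmMap(arms)


def read_arm_map(path: str | Path) -> ArmMap:
    """Read an arm table (columns arm_id, chrom, start, end; 1-based inclusive)."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"arm_id": str, "chrom": str})
    return ArmMap(
        Arm(row.arm_id, row.chrom, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    )


def write_arm_map(arm_map: ArmMap, path: str | Path) -> None:
    rows = [
        {"arm_id": a.arm_id, "chrom": a.chrom, "start": a.start, "end": a.end}
        for a in arm_map
    ]
    pd.DataFrame(rows, columns=["arm_id", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# inference map, lesions, milestones
# ---------------------------------------------------------------------------


def read_inference_map(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read the tier-2 gene-to-target map (columns gene, target_gene, evidence)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "target_gene"):
        if col not in df.columns:
            raise MalformedRecordError(f"{path}: missing column {col}")
    out: dict[str, list[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        out.setdefault(row["gene"], []).append(
            (row["target_gene"], row.get("evidence", ""))
        )
    return out


def read_lesions(path: str | Path) -> dict[str, LesionSeries]:
    """Read lesion-sum series (long TSV: subject, timepoint, sum_mm, ned).

    Timepoint 0 is baseline; higher timepoints follow in scan order. ``ned``
    is 0/1 and constant per subject.
    """
    df = pd.read_csv(Path(path), sep="\t")
    out: dict[str, LesionSeries] = {}
    for subject, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("timepoint")
        ned = bool(grp["ned"].iloc[0]) if "ned" in grp.columns else False
        baseline_rows = grp[grp["timepoint"] == 0]
        baseline = float(baseline_rows["sum_mm"].iloc[0]) if len(baseline_rows) else None
        sums = [float(x) for x in grp.loc[grp["timepoint"] > 0, "sum_mm"]]
        out[str(subject)] = LesionSeries(
            subject_id=str(subject),
            baseline_sum=baseline,
            timepoint_sums=sums,
            ned_flag=ned,
        )
    return out


def write_lesions(lesions: Mapping[str, LesionSeries], path: str | Path) -> None:
    rows = []
    for subject in sorted(lesions):
        series = lesions[subject]
        if series.baseline_sum is not None:
            rows.append(
                {"subject": subject, "timepoint": 0, "sum_mm": series.baseline_sum,
                 "ned": int(series.ned_flag)}
            )
        for t, s in enumerate(series.timepoint_sums, start=1):
            rows.append(
                {"subject": subject, "timepoint": t, "sum_mm": s,
                 "ned": int(series.ned_flag)}
            )
        if series.baseline_sum is None and not series.timepoint_sums:
            rows.append(
                {"subject": subject, "timepoint": -1, "sum_mm": np.nan,
                 "ned": int(series.ned_flag)}
            )
    pd.DataFrame(rows, columns=["subject", "timepoint", "sum_mm", "ned"]).to_csv(
        path, sep="\t", index=False
    )


def read_milestones(path: str | Path) -> dict[str, Milestones]:
    df = pd.read_csv(Path(path), sep="\t")
    out: dict[str, Milestones] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        kwargs = {
            name: (None if pd.isna(row.get(name)) else float(row[name]))
            for name in MILESTONE_ORDER
        }
        out[str(row["subject"])] = Milestones(subject_id=str(row["subject"]), **kwargs)
    return out


def write_milestones(milestones: Mapping[str, Milestones], path: str | Path) -> None:
    rows = []
    for subject in sorted(milestones):
        rec = {"subject": subject}
        rec.update(milestones[subject].as_dict())
        rows.append(rec)
    pd.DataFrame(rows, columns=["subject", *MILESTONE_ORDER]).to_csv(
        path, sep="\t", index=False
    )
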