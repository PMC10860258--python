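"""Arm-level CNV calling, cohort recurrence, TMB, and oncoprint assembly.

Arm-level events follow the gene-count / log2-ratio / arm-coverage rule:
segments with at least ``min_genes`` genes and |log2 ratio| at or beyond
``log2_thresh`` are kept, their overlap with each chromosome arm is
unioned per direction, and a gain or loss is emitted when the union
covers at least ``arm_fraction`` of the arm. All thresholds inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from mtbkit.io import (
    ArmMap,
    CohortBundle,
    CopyNumberSegment,
    SomaticVariant,
    TUMOR_TYPES,
)

__all__ = [
    "ArmEvent",
    "TMBResult",
    "OncoprintMatrix",
    "call_arm_events",
    "cohort_arm_recurrence",
    "compute_tmb",
    "build_oncoprint",
]


@dataclass(frozen=True)
class ArmEvent:
    """A called chromosome-arm gain or loss with its covered fraction."""

    subject_id: str
    arm_id: str
    direction: str  # gain | loss
    covered_fraction: float


@dataclass(frozen=True)
class TMBResult:
    """Tumor mutational burden: somatic point mutations per megabase."""

    subject_id: str
    n_point_mutations: int
    callable_mb: float
    tmb: float


@dataclass
class OncoprintMatrix:
    """Rows (arm events then genes) x subjects; cells are alteration-label sets."""

    cells: pd.DataFrame  # object dtype, each cell a frozenset of labels
    row_kinds: pd.Series  # "arm" or "gene" per row
    tumor_types: dict[str, str]

    def to_long(self) -> pd.DataFrame:
        """Long-format table (row, subject, label) of all non-empty cells."""
        records = []
        for row in self.cells.index:
            for subject in self.cells.columns:
                for label in sorted(self.cells.at[row, subject]):
                    records.append(
                        {"row": row, "subject": subject, "label": label}
                    )
        return pd.DataFrame(records, columns=["row", "subject", "label"])


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    total += cur_end - cur_start + 1
    return total


def call_arm_events(
    segments: Sequence[CopyNumberSegment],
    arms: ArmMap,
    min_genes: int = 50,
    log2_thresh: float = 0.5,
    arm_fraction: float = 0.5,
) -> list[ArmEvent]:
    """Call arm-level gains and losses from filtered copy-number segments.

    A segment qualifies when ``n_genes >= min_genes`` and its log2 ratio is
    ``>= log2_thresh`` (gain) or ``<= -log2_thresh`` (loss). Overlaps of
    qualifying segments with each arm are unioned per (subject, arm,
    direction); an event is emitted when the union covers at least
    ``arm_fraction`` of the arm. Segments on chromosomes absent from the
    arm map are skipped with a warning.
    """
    overlaps: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.n_genes < min_genes:
            continue
        if seg.log2_ratio >= log2_thresh:
            direction = "gain"
        elif seg.log2_ratio <= -log2_thresh:
            direction = "loss"
        else:
            continue
        chrom_arms = arms.arms_on(seg.chrom)
        if not chrom_arms:
            warnings.warn(
                f"segment on {seg.chrom} has no arm in the arm map; skipped",
                stacklevel=2,
            )
            continue
        for arm in chrom_arms:
            start = max(seg.start, arm.start)
            end = min(seg.end, arm.end)
            if start <= end:
                overlaps.setdefault(
                    (seg.subject_id, arm.arm_id, direction), []
                ).append((start, end))
    events = []
    for (subject, arm_id, direction), intervals in sorted(overlaps.items()):
        fraction = _union_length(intervals) / arms.arms[arm_id].length
        if fraction >= arm_fraction:
            events.append(ArmEvent(subject, arm_id, direction, fraction))
    return events


def cohort_arm_recurrence(
    events: Iterable[ArmEvent], min_subjects: int = 15
) -> pd.DataFrame:
    """Arm events recurrent across the cohort.

    An (arm, direction) pair is reported when at least ``min_subjects``
    distinct subjects carry it; multiple biopsies of one subject count once.
    """
    subjects_by_event: dict[tuple[str, str], set[str]] = {}
    for ev in events:
        subjects_by_event.setdefault((ev.arm_id, ev.direction), set()).add(
            ev.subject_id
        )
    rows = [
        {"arm_id": arm, "direction": direction, "n_subjects": len(subjects)}
        for (arm, direction), subjects in sorted(subjects_by_event.items())
        if len(subjects) >= min_subjects
    ]
    return pd.DataFrame(rows, columns=["arm_id", "direction", "n_subjects"])


def compute_tmb(
    variants: Sequence[SomaticVariant],
    callable_mb: float = 30.0,
    subject_id: str | None = None,
) -> TMBResult:
    """Somatic point mutations (SNVs only) per megabase of callable territory.

    The callable footprint is assay-specific and must be supplied; the
    default of 30 Mb corresponds to a typical whole exome.
    """
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    n = sum(1 for v in variants if v.variant_class == "SNV")
    if subject_id is None:
        subject_id = variants[0].subject_id if variants else ""
    return TMBResult(
        subject_id=subject_id,
        n_point_mutations=n,
        callable_mb=callable_mb,
        tmb=n / callable_mb,
    )


def build_oncoprint(
    bundle: CohortBundle,
    gene_panel: Sequence[str],
    recurrent_arms: pd.DataFrame | None = None,
) -> OncoprintMatrix:
    """Assemble the cohort alteration matrix.

    Rows are recurrent arm events (in recurrence-table order) followed by
    panel genes sorted by the number of altered subjects (descending, ties
    alphabetical). Columns are subjects grouped by tumor type
    (neuroblastoma, CNS, rare) and alphabetical within type. Gene cells
    collect labels SNV/indel/fusion; arm cells collect gain/loss.
    """
    if not len(gene_panel):
        raise ValueError("gene_panel must be non-empty")
    subjects = sorted(
        bundle.tumor_types,
        key=lambda s: (TUMOR_TYPES.index(bundle.tumor_types[s]), s),
    )
    panel = set(gene_panel)
    gene_cells: dict[str, dict[str, set[str]]] = {
        g: {s: set() for s in subjects} for g in gene_panel
    }
    for subject, events in bundle.events.items():
        if subject not in bundle.tumor_types:
            continue
        for v in events.variants:
            if v.gene in panel:
                label = "SNV" if v.variant_class == "SNV" else "indel"
                gene_cells[v.gene][subject].add(label)
        for f in events.fusions:
            for g in (f.gene_5p, f.gene_3p):
                if g in panel:
                    gene_cells[g][subject].add("fusion")

    def altered_count(gene: str) -> int:
        return sum(1 for s in subjects if gene_cells[gene][s])

    gene_order = sorted(gene_panel, key=lambda g: (-altered_count(g), g))

    rows: list[str] = []
    kinds: list[str] = []
    data: dict[str, dict[str, frozenset]] = {}
    if recurrent_arms is not None and len(recurrent_arms):
        arm_events_by_subject: dict[tuple[str, str], set[str]] = {}
        # re-derive per-subject arm events from the bundle's segments
        if bundle.arm_map is not None:
            all_events = call_arm_events(
                [seg for ev in bundle.events.values() for seg in ev.segments],
                bundle.arm_map,
            )
            for ev in all_events:
                arm_events_by_subject.setdefault(
                    (ev.arm_id, ev.direction), set()
                ).add(ev.subject_id)
        for rec in recurrent_arms.itertuples(index=False):
            row_id = f"{rec.arm_id}_{rec.direction}"
            rows.append(row_id)
            kinds.append("arm")
            carriers = arm_events_by_subject.get((rec.arm_id, rec.direction), set())
            data[row_id] = {
                s: frozenset({rec.direction}) if s in carriers else frozenset()
                for s in subjects
            }
    for gene in gene_order:
        rows.append(gene)
        kinds.append("gene")
        data[gene] = {s: frozenset(gene_cells[gene][s]) for s in subjects}

    cells = pd.DataFrame(
        [[data[r][s] for s in subjects] for r in rows],
        index=rows,
        columns=subjects,
        dtype=object,
    )
    return OncoprintMatrix(
        cells=cells,
        row_kinds=pd.Series(kinds, index=rows),
        tumor_types=dict(bundle.tumor_types),
    )
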