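"""Multi-biopsy genomic-evolution analytics.

Serial biopsies of one subject are compared as sets of canonical event
keys (protein-coding mutations, arm-level CNV events, fusions) via exact
Venn partitions, and as genes x biopsies NRZ matrices restricted to a
drug-targetable panel, with cells flagged when their gene backed a chosen
plan drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mtbkit.expression import NRZScoreTable
from mtbkit.io import SomaticEventSet
from mtbkit.landscape import ArmEvent

__all__ = [
    "BiopsySeriesPartition",
    "event_keys",
    "partition_events",
    "targetable_nrz_matrix",
]

EventKey = tuple


@dataclass
class BiopsySeriesPartition:
    """Exact Venn partition of event keys across 2-3 serial biopsies.

    ``regions`` maps each non-empty biopsy-label subset (frozenset) to the
    keys found in exactly those biopsies; percentages are of the union.
    """

    subject_id: str
    biopsy_labels: list[str]
    regions: dict[frozenset, set]
    union_size: int

    def counts(self) -> dict[frozenset, int]:
        return {region: len(keys) for region, keys in self.regions.items()}

    def percentages(self) -> dict[frozenset, float]:
        if self.union_size == 0:
            return {region: 0.0 for region in self.regions}
        return {
            region: 100.0 * len(keys) / self.union_size
            for region, keys in self.regions.items()
        }

    def shared_all(self) -> set:
        """Keys present in every biopsy."""
        return set(self.regions.get(frozenset(self.biopsy_labels), set()))


def event_keys(
    events: SomaticEventSet,
    arm_events: Sequence[ArmEvent] = (),
    protein_coding_only: bool = False,
) -> set[EventKey]:
    """Canonical comparable keys for one biopsy's events.

    Mutations key by (gene, protein_change) when a protein change is named,
    else by (chrom, pos, ref, alt); arm CNV events by (arm, direction);
    fusions by their unordered partner pair. ``protein_coding_only``
    restricts mutations to those with a named protein change.
    """
    keys: set[EventKey] = set()
    for v in events.variants:
        if v.protein_change:
            keys.add(("mut", v.gene, v.protein_change))
        elif not protein_coding_only:
            keys.add(("mut", v.chrom, v.pos, v.ref, v.alt))
    for ev in arm_events:
        keys.add(("cnv", ev.arm_id, ev.direction))
    for f in events.fusions:
        keys.add(("fusion", tuple(sorted((f.gene_5p, f.gene_3p)))))
    return keys


def partition_events(
    event_sets: Mapping[str, set],
    subject_id: str = "",
) -> BiopsySeriesPartition:
    """Exact set algebra over the 2^k - 1 regions of 2 or 3 biopsy sets."""
    labels = list(event_sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("partitioning requires 2 or 3 biopsy sets")
    union: set = set()
    for keys in event_sets.values():
        union |= set(keys)
    regions: dict[frozenset, set] = {}
    for key in union:
        membership = frozenset(l for l in labels if key in event_sets[l])
        regions.setdefault(membership, set()).add(key)
    # materialize empty regions so every subset is reported
    all_subsets = []
    for mask in range(1, 2 ** len(labels)):
        subset = frozenset(
            labels[i] for i in range(len(labels)) if mask & (1 << i)
        )
        all_subsets.append(subset)
    for subset in all_subsets:
        regions.setdefault(subset, set())
    return BiopsySeriesPartition(
        subject_id=subject_id,
        biopsy_labels=labels,
        regions=regions,
        union_size=len(union),
    )


def targetable_nrz_matrix(
    nrz_tables: Mapping[str, NRZScoreTable],
    gene_panel: Sequence[str],
    plan_genes: Mapping[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x biopsies Z matrix over a targetable panel, with drug flags.

    Returns ``(z, flagged)``: ``z`` holds NRZ scores (NaN where a gene is
    absent from a biopsy's table - missing, not zero) and ``flagged`` marks
    cells whose gene backed a drug chosen in that biopsy's treatment plan
    (``plan_genes`` maps biopsy label -> set of rationale genes).
    """
    if not gene_panel:
        raise ValueError("gene_panel must be non-empty")
    biopsies = list(nrz_tables)
    z = pd.DataFrame(np.nan, index=list(gene_panel), columns=biopsies)
    flagged = pd.DataFrame(False, index=list(gene_panel), columns=biopsies)
    for label, table in nrz_tables.items():
        present = [g for g in gene_panel if g in table.z.index]
        z.loc[present, label] = table.z.loc[present].to_numpy()
        if plan_genes and label in plan_genes:
            hits = [g for g in present if g in plan_genes[label]]
            flagged.loc[hits, label] = True
    return z, flagged
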