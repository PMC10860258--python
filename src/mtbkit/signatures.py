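"""96-context mutation catalogs and signature decomposition by NNLS.

Single-base substitutions are binned into the canonical 96 trinucleotide
classes (6 pyrimidine-centered substitution types x 16 flanking contexts;
purine-strand calls are reverse-complemented). A catalog ``m`` is
decomposed against a signature matrix ``W`` (96 x S, columns on the
simplex) by linear combination decomposition: the non-negative
least-squares fit ``e = argmin_{e>=0} ||W e - m||_2``, from which exposure
proportions ``pi = e / sum(e)`` are derived and, at cohort level, averaged
within tumor types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from mtbkit.io import MalformedRecordError, SomaticVariant

__all__ = [
    "CONTEXTS_96",
    "SUBSTITUTION_TYPES",
    "MutationCatalog",
    "SignatureMatrix",
    "ExposureVector",
    "context_bin",
    "catalog_from_variants",
    "decompose_lcd",
    "average_exposures_by_type",
]

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical bin order: substitution type major, then 5' flank, then 3' flank,
#: both lexicographic. Labels look like ``A[C>A]A``.
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)

_BIN_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}


@dataclass
class MutationCatalog:
    """Length-96 substitution-context counts for one subject."""

    subject_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have 96 bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXTS_96))


class SignatureMatrix:
    """A 96 x S matrix of signature profiles, columns summing to 1."""

    def __init__(self, profiles: np.ndarray, names: Sequence[str]) -> None:
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape[0] != 96:
            raise ValueError("signature matrix must have 96 rows")
        if profiles.shape[1] != len(names):
            raise ValueError("one name per signature column required")
        if np.any(profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        col_sums = profiles.sum(axis=0)
        if np.any(np.abs(col_sums - 1.0) > 1e-6):
            raise ValueError("signature columns must each sum to 1 (+-1e-6)")
        self.profiles = profiles
        self.names = list(names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SignatureMatrix":
        frame = frame.reindex(list(CONTEXTS_96))
        if frame.isna().any().any():
            raise ValueError("signature table is missing context bins")
        return cls(frame.to_numpy(), list(frame.columns))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=list(CONTEXTS_96), columns=self.names
        )

    @property
    def n_signatures(self) -> int:
        return len(self.names)


@dataclass
class ExposureVector:
    """Raw (mutation-count scale) and proportional signature exposures."""

    subject_id: str
    exposures: np.ndarray
    signature_names: list[str]

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if np.any(self.exposures < 0):
            raise ValueError("exposures must be non-negative")

    @property
    def proportions(self) -> np.ndarray:
        total = self.exposures.sum()
        if total <= 0:
            raise ValueError("proportions undefined for all-zero exposures")
        return self.exposures / total

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.signature_names)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def context_bin(context: str, ref: str, alt: str) -> int:
    """Map a trinucleotide context and substitution to its canonical bin.

    Purine-centered calls are reverse-complemented to the pyrimidine strand,
    so e.g. G>A at TGT lands in the same bin as C>T at ACA.
    """
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        raise ValueError(f"malformed context {context!r}")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"malformed substitution {ref}>{alt}")
    if context[1] != ref:
        raise ValueError(f"context center {context[1]!r} != ref {ref!r}")
    if ref in "AG":
        context = _revcomp(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return _BIN_INDEX[label]


def catalog_from_variants(
    variants: Sequence[SomaticVariant], subject_id: str | None = None
) -> MutationCatalog:
    """Bin a subject's SNVs into the 96-context catalog.

    Indels and SNVs lacking a context are ignored; the catalog total equals
    the number of context-bearing SNVs. Contexts are stored on the
    pyrimidine strand (see :class:`mtbkit.io.SomaticVariant`), so the
    substitution is complemented when the reference allele is a purine.
    """
    counts = np.zeros(96, dtype=int)
    if subject_id is None:
        subject_id = variants[0].subject_id if variants else ""
    for v in variants:
        if v.variant_class != "SNV" or v.trinucleotide_context is None:
            continue
        ctx = v.trinucleotide_context
        ref, alt = v.ref, v.alt
        if ref in "AG":
            # context is stored pyrimidine-stranded; flip the call to match
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        try:
            counts[context_bin(ctx, ref, alt)] += 1
        except ValueError as exc:
            raise MalformedRecordError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt}: {exc}"
            ) from exc
    return MutationCatalog(subject_id=subject_id, counts=counts)


def decompose_lcd(
    catalog: MutationCatalog,
    signatures: SignatureMatrix,
    exposure_cutoff: float = 0.0,
) -> ExposureVector:
    """Fit signature exposures to a catalog by non-negative least squares.

    ``exposure_cutoff`` (a proportion in [0, 1)) optionally zeroes
    signatures whose fitted proportion falls below it, refitting on the
    survivors; the default of 0 applies no cutoff.
    """
    m = catalog.counts.astype(float)
    if m.sum() < 1:
        raise ValueError("cannot decompose an all-zero catalog")
    W = signatures.profiles
    e, _ = nnls(W, m)
    if exposure_cutoff > 0 and e.sum() > 0:
        keep = (e / e.sum()) >= exposure_cutoff
        if keep.any() and not keep.all():
            e_sub, _ = nnls(W[:, keep], m)
            e = np.zeros_like(e)
            e[keep] = e_sub
    return ExposureVector(
        subject_id=catalog.subject_id,
        exposures=e,
        signature_names=list(signatures.names),
    )


def average_exposures_by_type(
    exposures: Iterable[ExposureVector],
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Unweighted mean exposure proportions per tumor-type label.

    Every exposure must carry a label; each output row sums to 1.
    """
    exposures = list(exposures)
    missing = [e.subject_id for e in exposures if e.subject_id not in labels]
    if missing:
        raise KeyError(f"no tumor-type label for subjects: {missing}")
    frame = pd.DataFrame(
        {e.subject_id: e.as_series() for e in exposures}
    ).T
    frame["tumor_type"] = [labels[s] for s in frame.index]
    return frame.groupby("tumor_type", sort=True).mean()
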