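"""Expression normalization and outlier scoring against reference panels.

Two statistics drive the expression tier of the matching algorithm:

* **NRZ** (normal reference Z-score): per-gene standardized distance of a
  tumor's expression from the mean of a whole-body panel of normal tissues
  (22 tissues in the reference design), flagged ``over``/``under`` at a
  threshold ``tau`` (default 2, inclusive).
* **CRC** (cancer-reference cumulative statistic): per-gene mid-rank
  empirical-CDF percentile of the tumor against a reference cohort of
  relapsed/refractory childhood tumors.

Counts are normalized by median-of-ratios size factors followed by a
log2 transform with pseudocount; precomputed normalized matrices are
accepted via the ExpressionMatrix ``scale`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtbkit.io import ExpressionMatrix

__all__ = [
    "NormalReference",
    "NRZScoreTable",
    "CRCScoreTable",
    "normalize_counts",
    "build_normal_reference",
    "nrz_score",
    "crc_score",
]


@dataclass
class NormalReference:
    """Per-gene location/scale summary of the normal-tissue panel.

    ``sigma`` is the n-1 sample SD floored at ``sd_floor`` so degenerate
    reference genes cannot produce infinite Z-scores.
    """

    gene_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    n_reference_samples: int
    sd_floor: float

    def __post_init__(self) -> None:
        if self.n_reference_samples < 2:
            raise ValueError("a normal reference needs at least 2 samples")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")
        if np.any(self.sigma < self.sd_floor):
            raise ValueError("sigma below sd_floor; reference was not floored")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu, "sigma": self.sigma}, index=self.gene_ids)


@dataclass
class NRZScoreTable:
    """Per-gene NRZ scores and over/under/neutral flags for one subject."""

    subject_id: str
    z: pd.Series
    flags: pd.Series
    tau: float
    unmatched_genes: list[str] = field(default_factory=list)

    def flagged(self, flag: str) -> list[str]:
        """Genes carrying the given flag (``over``, ``under`` or ``neutral``)."""
        return list(self.flags.index[self.flags == flag])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "flag": self.flags})


@dataclass
class CRCScoreTable:
    """Per-gene percentile of a tumor within the cancer-reference cohort."""

    subject_id: str
    percentile: pd.Series

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percentile": self.percentile})


def normalize_counts(
    matrix: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Median-of-ratios size-factor normalization followed by log2.

    Size factors are the per-sample median of count/geometric-mean ratios
    over genes with all-positive counts; the output value is
    ``log2(count / size_factor + pseudocount)``.
    """
    if matrix.scale != "raw_counts":
        raise ValueError("normalize_counts expects a raw_counts matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = matrix.values
    if counts.shape[1] < 1:
        raise ValueError("matrix must have at least one sample")
    zero_samples = counts.columns[(counts == 0).all(axis=0)]
    if len(zero_samples):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_geo_mean = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_geo_mean[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    normalized = np.log2(arr / size_factors[None, :] + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(normalized, index=counts.index, columns=counts.columns),
        scale="normalized_log",
    )


def build_normal_reference(
    reference: ExpressionMatrix, sd_floor: float = 0.1
) -> NormalReference:
    """Summarize the normal-tissue panel into per-gene mean and floored SD."""
    if reference.scale != "normalized_log":
        raise ValueError("normal reference must be on the normalized_log scale")
    n = reference.shape[1]
    if n < 2:
        raise ValueError("normal reference needs at least 2 samples")
    arr = reference.values.to_numpy(dtype=float)
    mu = arr.mean(axis=1)
    sigma = np.maximum(arr.std(axis=1, ddof=1), sd_floor)
    return NormalReference(
        gene_ids=reference.gene_ids,
        mu=mu,
        sigma=sigma,
        n_reference_samples=n,
        sd_floor=sd_floor,
    )


def nrz_score(
    tumor_sample: pd.Series,
    ref: NormalReference,
    tau: float = 2.0,
    subject_id: str | None = None,
) -> NRZScoreTable:
    """Score a tumor expression vector against the normal reference.

    ``z_g = (x_g - mu_g) / sigma_g``; genes with ``z >= tau`` are flagged
    ``over`` and ``z <= -tau`` flagged ``under`` (both inclusive). Tumor
    genes absent from the reference are reported, not scored.
    """
    ref_frame = ref.as_frame()
    shared = tumor_sample.index.intersection(ref_frame.index)
    unmatched = [g for g in tumor_sample.index if g not in set(shared)]
    if len(shared) == 0:
        raise ValueError("tumor vector shares no genes with the normal reference")
    x = tumor_sample.loc[shared].astype(float)
    mu = ref_frame.loc[shared, "mu"]
    sigma = ref_frame.loc[shared, "sigma"]
    z = (x - mu) / sigma
    flags = pd.Series("neutral", index=shared, dtype=object)
    flags[z >= tau] = "over"
    flags[z <= -tau] = "under"
    return NRZScoreTable(
        subject_id=subject_id or str(tumor_sample.name or "sample"),
        z=z,
        flags=flags,
        tau=tau,
        unmatched_genes=unmatched,
    )


def crc_score(
    tumor_sample: pd.Series,
    cancer_ref: ExpressionMatrix,
    subject_id: str | None = None,
) -> CRCScoreTable:
    """Mid-rank empirical-CDF percentile of a tumor vs the cancer reference.

    ``p_g = 100 * (#{ref < x} + 0.5 * #{ref == x}) / n_ref`` per gene, so
    ties contribute half weight and p is invariant under any strictly
    monotone transform applied jointly to tumor and reference.
    """
    if cancer_ref.shape[1] < 2:
        raise ValueError("cancer reference needs at least 2 samples")
    shared = tumor_sample.index.intersection(cancer_ref.values.index)
    if len(shared) == 0:
        raise ValueError("tumor vector shares no genes with the cancer reference")
    ref = cancer_ref.values.loc[shared].to_numpy(dtype=float)
    x = tumor_sample.loc[shared].to_numpy(dtype=float)[:, None]
    n = ref.shape[1]
    p = 100.0 * ((ref < x).sum(axis=1) + 0.5 * (ref == x).sum(axis=1)) / n
    return CRCScoreTable(
        subject_id=subject_id or str(tumor_sample.name or "sample"),
        percentile=pd.Series(p, index=shared),
    )
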