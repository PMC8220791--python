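"""Within-sample quantification measures: TPM, FPKM, and Z-score on TPM.

For gene i with fragment count q_i and effective length l_i (bases):

    FPKM_i = q_i / (l_i * sum_j q_j) * 1e9
    TPM_i  = (q_i / l_i) / sum_j (q_j / l_j) * 1e6

so every TPM column sums to 1e6 — TPM is compositional, FPKM is not.  TPM can
be recovered from FPKM alone by renormalizing the column to 1e6.

Genes with effective length 0 (shorter than the fragment length) must have
zero counts; they receive TPM = FPKM = 0 and are excluded from denominators.

The Z-score transform standardizes each gene across samples on the
log2(TPM+1) scale, centering at the median and dividing by the sample
standard deviation (n-1 denominator, computed about the mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, DegenerateSampleError, InvalidLengthError, QuantBenchError
from .matrix import ExpressionMatrix

SCALE_TPM = 1e6
SCALE_FPKM = 1e9


@dataclass
class LengthVector:
    """Per-gene effective lengths (bases), aligned to a gene order."""

    gene_ids: list[str]
    effective_length: np.ndarray

    def __post_init__(self) -> None:
        self.effective_length = np.asarray(self.effective_length, dtype=float)
        if len(self.gene_ids) != self.effective_length.shape[0]:
            raise ConsistencyError("length vector does not match gene_ids")
        if self.effective_length.size and self.effective_length.min() < 0:
            raise QuantBenchError("negative effective length")

    def aligned_to(self, gene_ids: list[str]) -> np.ndarray:
        if gene_ids == self.gene_ids:
            return self.effective_length
        by_id = dict(zip(self.gene_ids, self.effective_length))
        try:
            return np.array([by_id[g] for g in gene_ids])
        except KeyError as e:
            raise ConsistencyError(f"gene {e.args[0]!r} missing from lengths") from None


def _check_counts_lengths(counts: ExpressionMatrix, lengths: LengthVector) -> np.ndarray:
    if counts.scale != "linear":
        raise QuantBenchError("counts must be on the linear scale")
    l = lengths.aligned_to(counts.gene_ids)
    bad = (l == 0) & (counts.values > 0).any(axis=1)
    if bad.any():
        genes = [counts.gene_ids[i] for i in np.flatnonzero(bad)[:10]]
        raise InvalidLengthError(
            f"genes with positive counts but zero effective length: {genes}"
        )
    return l


def compute_fpkm(counts: ExpressionMatrix, lengths: LengthVector) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped fragments, per sample."""
    l = _check_counts_lengths(counts, lengths)
    totals = counts.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise DegenerateSampleError(
            f"all-zero counts in sample(s) {[counts.sample_ids[i] for i in zero]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = np.where(
            l[:, None] > 0,
            counts.values / (l[:, None] * totals[None, :]) * SCALE_FPKM,
            0.0,
        )
    return counts.with_values(fpkm, measure="fpkm")


def compute_tpm(counts: ExpressionMatrix, lengths: LengthVector) -> ExpressionMatrix:
    """Transcripts per million; every output column sums to 1e6."""
    l = _check_counts_lengths(counts, lengths)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(l[:, None] > 0, counts.values / l[:, None], 0.0)
    denom = rate.sum(axis=0)
    zero = np.flatnonzero(denom <= 0)
    if zero.size:
        raise DegenerateSampleError(
            f"all-zero counts in sample(s) {[counts.sample_ids[i] for i in zero]}"
        )
    return counts.with_values(rate / denom[None, :] * SCALE_TPM, measure="tpm")


def fpkm_to_tpm(fpkm: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM by renormalizing each column to 1e6."""
    if fpkm.measure != "fpkm":
        raise QuantBenchError(f"expected an fpkm matrix, got {fpkm.measure!r}")
    totals = fpkm.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise DegenerateSampleError(
            f"all-zero FPKM in sample(s) {[fpkm.sample_ids[i] for i in zero]}"
        )
    return fpkm.with_values(
        fpkm.values / totals[None, :] * SCALE_TPM, measure="tpm"
    )


def zscore_tpm(tpm: ExpressionMatrix, sd_about: str = "mean") -> ExpressionMatrix:
    """Per-gene Z-score of log2(TPM+1) across samples.

    Z_ij = (y_ij - median_j(y_i)) / SD_j(y_i) with y = log2(TPM+1) and SD the
    sample standard deviation (n-1).  ``sd_about`` selects whether the SD is
    computed about the mean (default, the formula as conventionally printed)
    or about the median.  Genes with zero SD get Z = 0 for every sample and
    are flagged in ``meta['zero_sd_genes']``.
    """
    if tpm.measure != "tpm":
        raise QuantBenchError(f"expected a tpm matrix, got {tpm.measure!r}")
    if tpm.n_samples < 2:
        raise QuantBenchError("Z-score needs at least 2 samples (SD undefined)")
    if sd_about not in ("mean", "median"):
        raise QuantBenchError(f"sd_about must be 'mean' or 'median', got {sd_about!r}")
    y = np.log2(tpm.values + 1.0)
    med = np.median(y, axis=1, keepdims=True)
    center = y.mean(axis=1, keepdims=True) if sd_about == "mean" else med
    n = tpm.n_samples
    sd = np.sqrt(((y - center) ** 2).sum(axis=1, keepdims=True) / (n - 1))
    flat = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (y - med) / sd_safe
    z[flat, :] = 0.0
    out = tpm.with_values(z, measure="zscore")
    out.meta["zero_sd_genes"] = [tpm.gene_ids[i] for i in np.flatnonzero(flat)]
    return out
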