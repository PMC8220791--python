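"""Between-sample count normalization: median-of-ratios and TMM.

Median-of-ratios (the DESeq / DESeq2 approach): build a "virtual reference
sample" as the per-gene geometric mean of counts over all samples; each
sample's size factor is the median, over genes with a positive reference, of
the ratio of its counts to the reference.  Genes with a zero anywhere drop
out of the reference (their geometric mean is zero).

TMM (weighted trimmed mean of M-values, the edgeR approach): for sample s
against reference sample r with library sizes N, using only genes positive
in both,

    M_g = log2((q_gs/N_s) / (q_gr/N_r))        gene-wise log-fold change
    A_g = 0.5 * log2((q_gs/N_s) * (q_gr/N_r))  average log abundance

the upper/lower tails of M (default 30%) and of A (default 5%) are trimmed
by rank, and the factor is 2**(weighted mean of the surviving M) with
precision weights from the delta-method variance of M:

    1/w_g = (N_s - q_gs)/(N_s q_gs) + (N_r - q_gr)/(N_r q_gr)

Factors are rescaled to geometric mean 1 so they are comparable across
reference choices.  Both methods assume most genes are not changing between
samples, which is exactly what dominant-transcript contamination violates
for compositional measures but not for these trimmed/median statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import (
    ConsistencyError,
    DegenerateSampleError,
    NoReferenceGeneError,
    QuantBenchError,
    TrimExhaustedError,
)
from .matrix import ExpressionMatrix


@dataclass
class NormalizationFactors:
    """Per-sample scaling factors plus the library sizes they pair with."""

    sample_ids: list[str]
    factor: np.ndarray
    method: str  # 'median_ratio' | 'tmm'
    library_size: np.ndarray

    def __post_init__(self) -> None:
        self.factor = np.asarray(self.factor, dtype=float)
        self.library_size = np.asarray(self.library_size, dtype=float)
        if not np.all(np.isfinite(self.factor)) or np.any(self.factor <= 0):
            raise QuantBenchError("normalization factors must be positive and finite")
        if self.method not in ("median_ratio", "tmm"):
            raise QuantBenchError(f"unknown normalization method {self.method!r}")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"sample_id": self.sample_ids, "factor": self.factor}
        ).to_csv(path, sep="\t", index=False)


def size_factors_median_ratio(
    counts: ExpressionMatrix, round_counts: bool = True
) -> NormalizationFactors:
    """Median-of-ratios size factors against the geometric-mean reference.

    ``round_counts`` rounds expected counts to the nearest integer first,
    mirroring the import path that feeds fractional RSEM expected counts
    into an integer-count framework; the effect on factors is negligible but
    reproducible.
    """
    if counts.n_samples < 2:
        raise QuantBenchError("median-of-ratios needs at least 2 samples")
    x = counts.values
    if round_counts:
        x = np.rint(x)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise NoReferenceGeneError(
            "no gene has positive counts in every sample; "
            "median-of-ratios reference is empty"
        )
    ref = np.exp(np.log(x[positive]).mean(axis=1))  # geometric mean per gene
    factors = np.median(x[positive] / ref[:, None], axis=0)
    return NormalizationFactors(
        sample_ids=list(counts.sample_ids),
        factor=factors,
        method="median_ratio",
        library_size=counts.values.sum(axis=0),
    )


def apply_factors(
    m: ExpressionMatrix, f: NormalizationFactors
) -> ExpressionMatrix:
    """Scale each sample by its normalization factor.

    median_ratio: column / factor.  tmm: column / (factor * library_size),
    rescaled by the mean library size so values stay on a count-like scale.
    """
    if list(m.sample_ids) != list(f.sample_ids):
        raise ConsistencyError(
            "sample sets of matrix and factors differ: "
            f"{m.sample_ids} vs {f.sample_ids}"
        )
    if f.method == "median_ratio":
        scaled = m.values / f.factor[None, :]
    else:
        eff_lib = f.factor * f.library_size
        scaled = m.values / eff_lib[None, :] * f.library_size.mean()
    return m.with_values(scaled, measure="normcount")


def _quantile_reference(values: np.ndarray) -> int:
    """Pick the sample whose upper-quartile count fraction is closest to the
    mean of those fractions (the standard TMM automatic reference)."""
    lib = values.sum(axis=0)
    f75 = np.array(
        [np.quantile(values[:, j] / lib[j], 0.75) for j in range(values.shape[1])]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    m: ExpressionMatrix,
    reference: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    weighted: bool = True,
) -> NormalizationFactors:
    """TMM scaling factors for every sample against one reference sample.

    ``reference`` is a sample id, or None for automatic selection.  The
    reference's own factor is 1 before the final rescaling of all factors to
    geometric mean 1.  Trimming keeps genes whose rank in M and in A falls
    inside the retained central band (average ranks, both bounds inclusive,
    so ties are kept).
    """
    if m.n_samples < 2:
        raise QuantBenchError("TMM needs at least 2 samples")
    x = m.values
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise DegenerateSampleError("sample with zero library size")
    if reference is None:
        ref_idx = _quantile_reference(x)
    else:
        ref_idx = m.sample_ids.index(reference)

    factors = np.ones(m.n_samples)
    qr = x[:, ref_idx]
    for j in range(m.n_samples):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            x[:, j], qr, lib[j], lib[ref_idx], logratio_trim, abs_trim, weighted
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    out = NormalizationFactors(
        sample_ids=list(m.sample_ids),
        factor=factors,
        method="tmm",
        library_size=lib,
    )
    return out


def _tmm_pair(
    qs: np.ndarray,
    qr: np.ndarray,
    ns: float,
    nr: float,
    logratio_trim: float,
    abs_trim: float,
    weighted: bool,
) -> float:
    """One TMM factor: sample (qs, ns) against reference (qr, nr)."""
    both = (qs > 0) & (qr > 0)
    if not both.any():
        raise TrimExhaustedError("no gene positive in both sample and reference")
    ps, pr = qs[both] / ns, qr[both] / nr
    M = np.log2(ps / pr)
    A = 0.5 * np.log2(ps * pr)
    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        raise TrimExhaustedError(
            "trimming removed every gene; reduce logratio_trim/abs_trim"
        )
    Mk = M[keep]
    if weighted:
        qs_k, qr_k = qs[both][keep], qr[both][keep]
        var = (ns - qs_k) / (ns * qs_k) + (nr - qr_k) / (nr * qr_k)
        w = 1.0 / var
    else:
        w = np.ones_like(Mk)
    return float(2.0 ** (np.sum(w * Mk) / np.sum(w)))


def tmm_on_tpm(
    tpm: ExpressionMatrix,
    reference: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    weighted: bool = True,
) -> ExpressionMatrix:
    """TMM-normalize a TPM matrix directly.

    TPM values are treated as abundances with library size equal to the
    column sum (1e6 by construction); each column is divided by its TMM
    factor.  Factors are stored in ``meta['tmm_factors']``.
    """
    if tpm.measure != "tpm":
        raise QuantBenchError(f"expected a tpm matrix, got {tpm.measure!r}")
    f = tmm_factors(
        tpm,
        reference=reference,
        logratio_trim=logratio_trim,
        abs_trim=abs_trim,
        weighted=weighted,
    )
    out = tpm.with_values(tpm.values / f.factor[None, :])
    out.meta["tmm_factors"] = f
    return out
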