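"""Replicate-reproducibility metrics: CV, intraclass correlations, top-k
abundance fractions.

Coefficient of variation (CV): per gene, sample SD (n-1) divided by the mean
across one model's replicates, on the *linear* scale; each model is
summarized by the median and interquartile range over genes with positive
mean.

Intraclass correlation (ICC): one-way random-effects components of variance,
Y_ij = u_i + e_ij, estimated by the Shrout & Fleiss ICC(1) formula

    ICC = (MS_between - MS_error) / (MS_between + (k - 1) MS_error)

Negative estimates (which arise when the true ICC is near zero and k is
small) are clamped to 0; the raw value is preserved for audit.  Two variants
are used: ICC_g treats genes as units within one model (reproducibility of
the whole profile across that model's replicates) and ICC_m treats models as
units for one gene (how well the gene separates models relative to replicate
noise).  Both are computed on log2(x+1) values.

Top-k abundance: per model, genes are ranked by their TPM sum across the
model's replicates; each replicate's fraction of total TPM carried by those
k genes diagnoses dominant-transcript load.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import QuantBenchError, UndefinedICCError
from .matrix import ExpressionMatrix, ModelGrouping


@dataclass
class CVSummary:
    model_id: str
    median_cv: float
    iqr_cv: float
    n_genes_used: int


@dataclass
class ICCResult:
    """One intraclass-correlation estimate with its ANOVA ingredients."""

    unit_id: str
    ms_between: float
    ms_error: float
    k: int
    var_between: float
    var_error: float
    icc_raw: float
    icc: float
    variant: str  # 'per_model_genes' (ICC_g) | 'per_gene_models' (ICC_m)


class ICCMResult(NamedTuple):
    per_gene: list[ICCResult]
    median_icc: float
    undefined_genes: list[str]


def gene_cv(values: np.ndarray) -> float:
    """Sample SD (n-1) over mean of one gene's replicate values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise QuantBenchError("CV needs at least 2 replicates")
    mean = v.mean()
    if mean <= 0:
        raise QuantBenchError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean)


def model_cv_summary(
    m: ExpressionMatrix, groups: ModelGrouping
) -> list[CVSummary]:
    """Median and IQR of per-gene CVs within each model's replicates.

    Restricted to genes with positive mean within the model; quartiles use
    linear interpolation.
    """
    if m.scale != "linear":
        raise QuantBenchError("CV is computed on linear-scale values")
    groups.require_replicates(2)
    out = []
    col_idx = {s: i for i, s in enumerate(m.sample_ids)}
    for model_id, samples in groups.items():
        sub = m.values[:, [col_idx[s] for s in samples]]
        means = sub.mean(axis=1)
        used = means > 0
        cvs = sub[used].std(axis=1, ddof=1) / means[used]
        q25, q50, q75 = np.percentile(cvs, [25, 50, 75])
        out.append(
            CVSummary(
                model_id=model_id,
                median_cv=float(q50),
                iqr_cv=float(q75 - q25),
                n_genes_used=int(used.sum()),
            )
        )
    return out


def _oneway_ms(y: np.ndarray) -> tuple[float, float]:
    """(MS_between, MS_error) of a complete units x k one-way layout."""
    n, k = y.shape
    row_means = y.mean(axis=1)
    grand = y.mean()
    ms_between = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_error = np.sum((y - row_means[:, None]) ** 2) / (n * (k - 1))
    return float(ms_between), float(ms_error)


def icc_oneway(
    matrix: np.ndarray, unit_id: str = "", variant: str = "per_model_genes"
) -> ICCResult:
    """One-way random-effects ICC(1) of a complete units x replicates matrix."""
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise QuantBenchError("ICC needs >= 2 units and >= 2 replicates")
    if np.isnan(y).any():
        raise QuantBenchError("ICC input must be complete (no NaN)")
    ms_between, ms_error = _oneway_ms(y)
    k = y.shape[1]
    if ms_between == 0 and ms_error == 0:
        raise UndefinedICCError(
            f"all values identical; ICC undefined for unit {unit_id!r}"
        )
    icc_raw = (ms_between - ms_error) / (ms_between + (k - 1) * ms_error)
    return ICCResult(
        unit_id=unit_id,
        ms_between=ms_between,
        ms_error=ms_error,
        k=k,
        var_between=(ms_between - ms_error) / k,
        var_error=ms_error,
        icc_raw=float(icc_raw),
        icc=float(max(icc_raw, 0.0)),
        variant=variant,
    )


def icc_g_per_model(
    m: ExpressionMatrix, groups: ModelGrouping
) -> list[ICCResult]:
    """ICC_g: genes as units, one estimate per model, all replicates used."""
    if m.scale != "log2p1" and m.measure != "zscore":
        raise QuantBenchError("ICC expects log2(x+1)-transformed values")
    groups.require_replicates(2)
    col_idx = {s: i for i, s in enumerate(m.sample_ids)}
    out = []
    for model_id, samples in groups.items():
        sub = m.values[:, [col_idx[s] for s in samples]]
        try:
            out.append(icc_oneway(sub, unit_id=model_id, variant="per_model_genes"))
        except UndefinedICCError as e:
            raise UndefinedICCError(f"model {model_id!r}: {e}") from None
    return out


def icc_m_per_gene(
    m: ExpressionMatrix, groups: ModelGrouping
) -> ICCMResult:
    """ICC_m: models as units, one estimate per gene.

    Every model is truncated to the minimum replicate count (its first r
    samples in sheet order) so each gene yields a complete models x r matrix.
    Genes whose matrix is all-identical have undefined ICC; they are listed
    separately and excluded from the median.
    """
    if m.scale != "log2p1" and m.measure != "zscore":
        raise QuantBenchError("ICC expects log2(x+1)-transformed values")
    groups.require_replicates(2)
    r = groups.min_replicates()
    col_idx = {s: i for i, s in enumerate(m.sample_ids)}
    model_ids = groups.model_ids
    cols = [
        [col_idx[s] for s in groups.samples_of(mid)[:r]] for mid in model_ids
    ]
    # stack to genes x models x r for vectorized ANOVA
    y = np.stack([m.values[:, c] for c in cols], axis=1)
    n_models = len(model_ids)
    row_means = y.mean(axis=2)
    grand = row_means.mean(axis=1)
    ms_between = r * ((row_means - grand[:, None]) ** 2).sum(axis=1) / (n_models - 1)
    ms_error = ((y - row_means[:, :, None]) ** 2).sum(axis=(1, 2)) / (
        n_models * (r - 1)
    )
    undefined = (ms_between == 0) & (ms_error == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc_raw = (ms_between - ms_error) / (ms_between + (r - 1) * ms_error)
    per_gene = []
    for i, gid in enumerate(m.gene_ids):
        if undefined[i]:
            continue
        raw = float(icc_raw[i])
        per_gene.append(
            ICCResult(
                unit_id=gid,
                ms_between=float(ms_between[i]),
                ms_error=float(ms_error[i]),
                k=r,
                var_between=float((ms_between[i] - ms_error[i]) / r),
                var_error=float(ms_error[i]),
                icc_raw=raw,
                icc=max(raw, 0.0),
                variant="per_gene_models",
            )
        )
    if not per_gene:
        raise UndefinedICCError("every gene has an all-identical matrix")
    median = float(np.median([g.icc for g in per_gene]))
    return ICCMResult(
        per_gene=per_gene,
        median_icc=median,
        undefined_genes=[m.gene_ids[i] for i in np.flatnonzero(undefined)],
    )


def top_k_abundance(
    tpm: ExpressionMatrix, groups: ModelGrouping, k: int = 5
) -> pd.DataFrame:
    """Fraction of total TPM carried by each model's top-k genes.

    Genes are ranked per model by the sum of TPM over that model's
    replicates (ties broken lexicographically by gene_id); fractions are per
    replicate, out of the fixed 1e6 TPM total.  Returns a DataFrame with
    columns model_id, sample_id, fraction, top_genes.
    """
    if tpm.measure != "tpm":
        raise QuantBenchError(f"expected a tpm matrix, got {tpm.measure!r}")
    if k > tpm.n_genes:
        raise QuantBenchError(f"k={k} exceeds gene count {tpm.n_genes}")
    col_idx = {s: i for i, s in enumerate(tpm.sample_ids)}
    rows = []
    for model_id, samples in groups.items():
        sub = tpm.values[:, [col_idx[s] for s in samples]]
        sums = sub.sum(axis=1)
        order = sorted(
            range(tpm.n_genes), key=lambda i: (-sums[i], tpm.gene_ids[i])
        )
        top = order[:k]
        top_genes = ",".join(tpm.gene_ids[i] for i in top)
        for s in samples:
            frac = tpm.values[top, col_idx[s]].sum() / 1e6
            rows.append((model_id, s, float(frac), top_genes))
    return pd.DataFrame(
        rows, columns=["model_id", "sample_id", "fraction", "top_genes"]
    )
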