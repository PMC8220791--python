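"""End-to-end comparison of quantification measures on a replicate dataset.

Builds the six measure scenarios — TPM, FPKM, median-of-ratios counts,
TMM counts, Z-score on TPM, TMM on TPM — then evaluates:

* hierarchical clustering concordance (discordant-model count and maximum
  merge height) under 1-Pearson and Euclidean distances;
* per-model CV summaries (linear measures only);
* ICC_g per model and ICC_m per gene on log2(x+1) values;
* top-k TPM abundance fractions per replicate.

Clustering runs on log2(x+1) values for linear measures (Z-scores as-is);
``cluster_scale='linear'`` is available for sensitivity checks.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, count_normalization as norm, metrics, quantification as quant, rsem_io
from .errors import QuantBenchError
from .matrix import ExpressionMatrix, ModelGrouping

logger = logging.getLogger("quantbench")

#: the six measure scenarios, in report order
MEASURES = ("tpm", "fpkm", "count_medratio", "count_tmm", "tpm_zscore", "tpm_tmm")
#: linear measures for which a CV is meaningful
CV_MEASURES = ("tpm", "fpkm", "count_medratio", "count_tmm", "tpm_tmm")
#: measures entering the ICC comparison
ICC_MEASURES = ("tpm", "fpkm", "count_medratio", "count_tmm")
METRICS = ("one_minus_pearson", "euclidean")


@dataclass
class PipelineOptions:
    cluster_scale: str = "log2p1"  # 'log2p1' | 'linear'
    linkage: str = "ward"  # 'ward' | 'complete'
    top_k: int = 5
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    tmm_weighted: bool = True
    zscore_sd_about: str = "mean"


@dataclass
class ComparisonReport:
    """All comparison tables plus the dendrograms they derive from."""

    discordance: pd.DataFrame  # rows measures, cols metrics: counts
    discordant_ids: dict[tuple[str, str], list[str]]
    max_height: pd.DataFrame  # rows measures, cols metrics: heights
    cv: pd.DataFrame  # model x measure medians (long form)
    icc_g: pd.DataFrame  # model x measure ICC_g
    icc_m_summary: pd.DataFrame  # measure -> median ICC_m, n undefined
    icc_m_per_gene: pd.DataFrame  # gene x measure clamped ICC_m
    top_k: pd.DataFrame  # model, sample, fraction
    dendrograms: dict[tuple[str, str], clustering.Dendrogram] = field(
        default_factory=dict
    )

    def write(self, out_dir: str | os.PathLike) -> None:
        """Write all tables (3-decimal TSVs plus a full-precision sidecar)."""
        os.makedirs(out_dir, exist_ok=True)

        def _tsv(df: pd.DataFrame, name: str, index: bool) -> None:
            df.to_csv(
                os.path.join(out_dir, name),
                sep="\t",
                index=index,
                float_format="%.3f",
            )
            df.to_csv(
                os.path.join(out_dir, name.replace(".tsv", ".fullprec.tsv")),
                sep="\t",
                index=index,
            )

        _tsv(self.discordance, "table1_discordance.tsv", index=True)
        _tsv(self.max_height, "table2_maxheight.tsv", index=True)
        _tsv(self.cv, "cv_by_model.tsv", index=False)
        _tsv(self.icc_g, "icc_g.tsv", index=False)
        _tsv(self.icc_m_summary, "icc_m_summary.tsv", index=False)
        _tsv(self.icc_m_per_gene, "icc_m_per_gene.tsv", index=False)
        _tsv(self.top_k, f"top{_topk_of(self.top_k)}_fractions.tsv", index=False)
        for (measure, metric), dend in self.dendrograms.items():
            path = os.path.join(out_dir, f"dendrogram_{measure}_{metric}.nwk")
            with open(path, "w") as fh:
                fh.write(dend.to_newick() + "\n")


def _topk_of(df: pd.DataFrame) -> int:
    genes = df["top_genes"].iloc[0] if len(df) else ""
    return len(genes.split(",")) if genes else 5


def build_measures(
    records_by_sample: dict,
    options: PipelineOptions | None = None,
) -> dict[str, ExpressionMatrix]:
    """Assemble all six measure matrices from per-sample RSEM records."""
    options = options or PipelineOptions()
    counts = rsem_io.assemble_matrix(records_by_sample, "count")
    tpm = rsem_io.assemble_matrix(records_by_sample, "tpm")
    fpkm = rsem_io.assemble_matrix(records_by_sample, "fpkm")

    medratio = norm.apply_factors(counts, norm.size_factors_median_ratio(counts))
    tmm = norm.apply_factors(
        counts,
        norm.tmm_factors(
            counts,
            logratio_trim=options.logratio_trim,
            abs_trim=options.abs_trim,
            weighted=options.tmm_weighted,
        ),
    )
    zscore = quant.zscore_tpm(tpm, sd_about=options.zscore_sd_about)
    tpm_tmm = norm.tmm_on_tpm(
        tpm,
        logratio_trim=options.logratio_trim,
        abs_trim=options.abs_trim,
        weighted=options.tmm_weighted,
    )
    return {
        "tpm": tpm,
        "fpkm": fpkm,
        "count_medratio": medratio,
        "count_tmm": tmm,
        "tpm_zscore": zscore,
        "tpm_tmm": tpm_tmm,
    }


def _clustering_input(m: ExpressionMatrix, options: PipelineOptions) -> ExpressionMatrix:
    if m.measure == "zscore" or options.cluster_scale == "linear":
        return m
    return rsem_io.log_transform(m)


def run_comparison(
    sample_sheet: str | os.PathLike | None = None,
    options: PipelineOptions | None = None,
    records_by_sample: dict | None = None,
    grouping: ModelGrouping | None = None,
) -> ComparisonReport:
    """Run the full measure comparison.

    Inputs are either a sample-sheet path (CSV referencing RSEM files) or
    pre-loaded ``records_by_sample`` plus a ``grouping``.
    """
    options = options or PipelineOptions()
    if records_by_sample is None:
        if sample_sheet is None:
            raise QuantBenchError("provide sample_sheet or records_by_sample")
        annotations = rsem_io.read_sample_sheet(sample_sheet)
        grouping = ModelGrouping(annotations)
        records_by_sample = rsem_io.load_samples(annotations)
    if grouping is None:
        raise QuantBenchError("grouping required with records_by_sample")
    if len(grouping.model_ids) < 2:
        raise QuantBenchError("need at least 2 models for a comparison")

    measures = build_measures(records_by_sample, options)
    logger.info(
        "assembled %d measures for %d genes x %d samples",
        len(measures),
        measures["tpm"].n_genes,
        measures["tpm"].n_samples,
    )

    disc = pd.DataFrame(index=list(MEASURES), columns=list(METRICS), dtype=float)
    disc.index.name = "measure"
    heights = disc.copy()
    discordant_ids: dict[tuple[str, str], list[str]] = {}
    dendrograms: dict[tuple[str, str], clustering.Dendrogram] = {}
    for name in MEASURES:
        cl_input = _clustering_input(measures[name], options)
        for metric in METRICS:
            if metric == "one_minus_pearson":
                d = clustering.pearson_dissimilarity(cl_input)
            else:
                d = clustering.euclidean_dissimilarity(cl_input)
            dend = clustering.ward_linkage(d, linkage=options.linkage)
            count, ids = clustering.discordant_models(dend, grouping)
            disc.loc[name, metric] = count
            heights.loc[name, metric] = clustering.max_height(dend)
            discordant_ids[(name, metric)] = ids
            dendrograms[(name, metric)] = dend
            logger.info(
                "clustering %s/%s: %d discordant, max height %.3f",
                name, metric, count, heights.loc[name, metric],
            )

    cv_rows = []
    for name in CV_MEASURES:
        for s in metrics.model_cv_summary(measures[name], grouping):
            cv_rows.append(
                (s.model_id, name, s.median_cv, s.iqr_cv, s.n_genes_used)
            )
    cv = pd.DataFrame(
        cv_rows, columns=["model_id", "measure", "median_cv", "iqr_cv", "n_genes"]
    )

    icc_g_rows = []
    icc_m_rows = []
    icc_m_gene_cols = {}
    for name in ICC_MEASURES:
        logm = rsem_io.log_transform(measures[name])
        for r in metrics.icc_g_per_model(logm, grouping):
            icc_g_rows.append((r.unit_id, name, r.icc, r.icc_raw))
        mres = metrics.icc_m_per_gene(logm, grouping)
        icc_m_rows.append((name, mres.median_icc, len(mres.undefined_genes)))
        icc_m_gene_cols[name] = pd.Series(
            {g.unit_id: g.icc for g in mres.per_gene}
        )
    icc_g = pd.DataFrame(
        icc_g_rows, columns=["model_id", "measure", "icc", "icc_raw"]
    )
    icc_m_summary = pd.DataFrame(
        icc_m_rows, columns=["measure", "median_icc_m", "n_undefined_genes"]
    )
    icc_m_per_gene = pd.DataFrame(icc_m_gene_cols)
    icc_m_per_gene.insert(0, "gene_id", icc_m_per_gene.index)
    icc_m_per_gene = icc_m_per_gene.reset_index(drop=True)

    top_k = metrics.top_k_abundance(measures["tpm"], grouping, k=options.top_k)

    return ComparisonReport(
        discordance=disc.astype(int),
        discordant_ids=discordant_ids,
        max_height=heights,
        cv=cv,
        icc_g=icc_g,
        icc_m_summary=icc_m_summary,
        icc_m_per_gene=icc_m_per_gene,
        top_k=top_k,
        dendrograms=dendrograms,
    )
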