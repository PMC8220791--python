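"""Synthetic replicate RNA-seq datasets in RSEM gene-level format.

The generator emulates a PDX-repository-like replicate design: a panel of
models (tumors), each implanted into a few mice, sequenced once per mouse.
Its statistical structure is exactly what the analysis stages assume:

* a shared gene baseline with per-model biological effects, so models are
  distinct but comparable (as tumors sharing a transcriptome are);
* per-replicate library-size variation (log-normal);
* negative-binomial count noise around the expected read allocation;
* a small set of *dominant* genes (rRNA/mitochondrial-like: very short,
  extremely highly expressed) that consume a molar fraction f of the
  sequenced pool.  In *contaminated* models f varies strongly across
  replicates; in clean models it stays in a narrow band.  Because TPM is
  compositional, a varying f shifts every other gene's TPM by the factor
  (1-f), which is the mechanism behind TPM's poor replicate concordance.

Reads are allocated proportionally to molar fraction times effective
length, then counts are drawn NB(mean, dispersion); TPM and FPKM fields are
filled by running the package's own quantification on the simulated counts,
so written files are internally consistent by construction.

All randomness comes from one numpy Generator in a fixed draw order, so a
(config, seed) pair reproduces the dataset bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .matrix import ExpressionMatrix, ModelGrouping, SampleAnnotation
from .quantification import LengthVector, compute_fpkm, compute_tpm
from .rsem_io import GeneQuantRecord

RSEM_HEADER = "gene_id\ttranscript_id(s)\tlength\teffective_length\texpected_count\tTPM\tFPKM"


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the benchmark conditions.

    Sizes mirror the replicate design the analysis targets: 20 models, 3
    replicates each with one 4-replicate model (61 samples).  Gene
    propensities are log-normal: theta_mg = exp(base_g + u_mg) with
    base_g ~ N(baseline_log_mean, baseline_log_sd) shared by all models and
    u_mg ~ N(0, model_effect_log_sd) per model, so the marginal spread stays
    log-normal while between-model distances remain commensurate with
    replicate noise.  Dominant genes are short (rRNA/mito-like) and take a
    molar fraction of the pool drawn per replicate from the contaminated or
    clean range.
    """

    n_genes: int = 2000
    n_models: int = 20
    replicates_per_model: int | list[int] = 3
    four_replicate_model_index: int = 0  # one model gets an extra replicate
    mean_library_size: float = 2e6
    library_size_cv: float = 0.2
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 2.0
    model_effect_log_sd: float = 0.21
    nb_dispersion: float = 0.05
    n_dominant_genes: int = 5
    dominant_length_range: tuple[float, float] = (120.0, 1500.0)
    contaminated_model_indices: tuple[int, ...] = (2, 7, 12, 17)
    dominant_fraction_range_contaminated: tuple[float, float] = (0.05, 0.5)
    dominant_fraction_range_clean: tuple[float, float] = (0.08, 0.12)
    gene_length_log_mean: float = float(np.log(2000.0))
    gene_length_log_sd: float = 0.5
    gene_length_bounds: tuple[float, float] = (200.0, 100000.0)
    effective_length_offset: float = 200.0
    seed: int = 20210622

    def validate(self) -> None:
        if self.n_dominant_genes >= self.n_genes:
            raise ConfigError("all genes dominant: nothing left to express")
        if self.mean_library_size <= 0:
            raise ConfigError("mean_library_size must be positive")
        for lo, hi in (
            self.dominant_fraction_range_contaminated,
            self.dominant_fraction_range_clean,
        ):
            if not (0 <= lo <= hi < 1):
                raise ConfigError("dominant fraction ranges must lie in [0, 1)")
        if any(
            i < 0 or i >= self.n_models for i in self.contaminated_model_indices
        ):
            raise ConfigError("contaminated model index out of range")
        if self.nb_dispersion < 0 or self.baseline_log_sd <= 0:
            raise ConfigError("scale parameters must be positive")

    def replicate_counts(self) -> list[int]:
        if isinstance(self.replicates_per_model, list):
            if len(self.replicates_per_model) != self.n_models:
                raise ConfigError("replicates_per_model list length mismatch")
            return list(self.replicates_per_model)
        counts = [int(self.replicates_per_model)] * self.n_models
        if 0 <= self.four_replicate_model_index < self.n_models:
            counts[self.four_replicate_model_index] += 1
        return counts

    def model_ids(self) -> list[str]:
        return [f"PDX-{i + 1:03d}" for i in range(self.n_models)]


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset (reproducible from config+seed)."""

    theta: dict[str, np.ndarray]  # model -> per-gene propensity
    dominant_fraction: dict[str, float]  # sample -> molar fraction f
    library_size: dict[str, float]  # sample -> N
    contaminated: dict[str, bool]  # model -> flag
    dominant_gene_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    lengths: np.ndarray | None = None
    effective_lengths: np.ndarray | None = None


def default_config(**overrides) -> SyntheticConfig:
    return replace(SyntheticConfig(), **overrides)


def clean_config(**overrides) -> SyntheticConfig:
    """Config with contamination switched off (all models in the clean band)."""
    return replace(
        SyntheticConfig(), contaminated_model_indices=(), **overrides
    )


def generate_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[dict[str, list[GeneQuantRecord]], list[SampleAnnotation], SyntheticTruth]:
    """Generate per-sample RSEM-style records, a sample sheet, and the truth.

    Draw order (one RNG stream): gene lengths, baseline log-expression,
    per-model effects, then per replicate (models in order, replicates in
    order): dominant fraction, library size, counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    G, D = config.n_genes, config.n_dominant_genes

    dominant_ids = [f"rRNA-mito-{i + 1}" for i in range(D)]
    other_ids = [f"gene-{i + 1:05d}" for i in range(G - D)]
    gene_ids = dominant_ids + other_ids
    dom = np.zeros(G, dtype=bool)
    dom[:D] = True

    lengths = np.empty(G)
    lengths[:D] = rng.uniform(*config.dominant_length_range, size=D)
    lengths[D:] = np.clip(
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, G - D),
        *config.gene_length_bounds,
    )
    lengths = np.rint(lengths)
    eff_len = np.maximum(lengths - config.effective_length_offset, 1.0)

    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)
    model_ids = config.model_ids()
    theta = {
        mid: np.exp(base + rng.normal(0, config.model_effect_log_sd, G))
        for mid in model_ids
    }

    # log-normal library size with the requested mean and CV
    sigma2 = np.log1p(config.library_size_cv**2)
    mu = np.log(config.mean_library_size) - sigma2 / 2

    contaminated = {
        mid: (i in config.contaminated_model_indices)
        for i, mid in enumerate(model_ids)
    }
    rep_counts = config.replicate_counts()

    samples: dict[str, list[GeneQuantRecord]] = {}
    annotations: list[SampleAnnotation] = []
    truth = SyntheticTruth(
        theta=theta,
        dominant_fraction={},
        library_size={},
        contaminated=contaminated,
        dominant_gene_ids=dominant_ids,
        gene_ids=gene_ids,
        lengths=lengths,
        effective_lengths=eff_len,
    )
    passages = ("P0", "P1", "P2")
    counts_cols = []
    sample_ids = []
    for mi, mid in enumerate(model_ids):
        th = theta[mid]
        nondom = th.copy()
        nondom[dom] = 0.0
        nondom_frac = nondom / nondom.sum()
        lo, hi = (
            config.dominant_fraction_range_contaminated
            if contaminated[mid]
            else config.dominant_fraction_range_clean
        )
        for rep in range(rep_counts[mi]):
            sid = f"{mid}-r{rep + 1}"
            f = float(rng.uniform(lo, hi))
            n_lib = float(rng.lognormal(mu, np.sqrt(sigma2)))
            molar = (1.0 - f) * nondom_frac
            molar[dom] = f / D if D else 0.0
            share = molar * eff_len
            share = share / share.sum()
            mean_counts = n_lib * share
            if config.nb_dispersion <= 1e-12:
                counts = rng.poisson(mean_counts).astype(float)
            else:
                r_nb = 1.0 / config.nb_dispersion
                p = r_nb / (r_nb + mean_counts)
                counts = rng.negative_binomial(r_nb, p).astype(float)
            counts_cols.append(counts)
            sample_ids.append(sid)
            truth.dominant_fraction[sid] = f
            truth.library_size[sid] = n_lib
            annotations.append(
                SampleAnnotation(
                    sample_id=sid,
                    model_id=mid,
                    passage=passages[rep % len(passages)],
                    file_path=f"{sid}.genes.results",
                )
            )

    counts_matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.array(counts_cols).T,
        measure="count",
    )
    lv = LengthVector(gene_ids=gene_ids, effective_length=eff_len)
    tpm = compute_tpm(counts_matrix, lv)
    fpkm = compute_fpkm(counts_matrix, lv)

    for j, sid in enumerate(sample_ids):
        samples[sid] = [
            GeneQuantRecord(
                gene_id=gene_ids[g],
                length=float(lengths[g]),
                effective_length=float(eff_len[g]),
                expected_count=float(counts_matrix.values[g, j]),
                tpm=float(tpm.values[g, j]),
                fpkm=float(fpkm.values[g, j]),
            )
            for g in range(G)
        ]
    return samples, annotations, truth


def write_rsem_files(
    samples: dict[str, list[GeneQuantRecord]],
    annotations: list[SampleAnnotation],
    out_dir: str | os.PathLike,
) -> list[str]:
    """Write one ``<sample>.genes.results`` per sample plus ``samples.csv``.

    Floats are written with ``repr`` (shortest round-trip form) so a
    write-read cycle reproduces values bit-exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for sid, records in samples.items():
        path = os.path.join(out_dir, f"{sid}.genes.results")
        with open(path, "w") as fh:
            fh.write(RSEM_HEADER + "\n")
            for r in records:
                fh.write(
                    f"{r.gene_id}\t{r.gene_id}_t1\t{r.length!r}\t"
                    f"{r.effective_length!r}\t{r.expected_count!r}\t"
                    f"{r.tpm!r}\t{r.fpkm!r}\n"
                )
        written.append(path)
    sheet = os.path.join(out_dir, "samples.csv")
    with open(sheet, "w") as fh:
        fh.write("sample_id,model_id,passage,file_path\n")
        for a in annotations:
            fh.write(
                f"{a.sample_id},{a.model_id},{a.passage},{a.sample_id}.genes.results\n"
            )
    written.append(sheet)
    return written


def grouping_from_annotations(annotations: list[SampleAnnotation]) -> ModelGrouping:
    return ModelGrouping(annotations)
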