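"""Reading RSEM gene-level result files and sample sheets; writing matrices.

RSEM ``*.genes.results`` files are tab-separated with one row per gene and
columns ``gene_id``, ``transcript_id(s)`` (older versions: ``transcript_id``),
``length``, ``effective_length``, ``expected_count``, ``TPM``, ``FPKM``.
Expected counts may be fractional (posterior expectations over ambiguous
alignments).  Unknown extra columns are ignored.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ParseError, QuantBenchError
from .matrix import ExpressionMatrix, ModelGrouping, SampleAnnotation

REQUIRED_COLUMNS = (
    "gene_id",
    "length",
    "effective_length",
    "expected_count",
    "TPM",
    "FPKM",
)

# column of GeneQuantRecord holding each assemblable measure
_MEASURE_FIELD = {"count": "expected_count", "tpm": "tpm", "fpkm": "fpkm"}


@dataclass
class GeneQuantRecord:
    """One gene's quantification in one sample, as read from an RSEM file."""

    gene_id: str
    length: float
    effective_length: float
    expected_count: float
    tpm: float
    fpkm: float

    def __post_init__(self) -> None:
        if self.expected_count < 0 or self.effective_length < 0:
            raise QuantBenchError(
                f"negative count/length for gene {self.gene_id!r}"
            )
        if self.effective_length > self.length:
            raise QuantBenchError(
                f"effective_length > length for gene {self.gene_id!r}"
            )


def read_rsem_genes(path: str | os.PathLike) -> list[GeneQuantRecord]:
    """Read an RSEM ``*.genes.results`` file into records, preserving order.

    Raises
    ------
    FormatError
        If a required column is missing from the header.
    ParseError
        If a numeric cell cannot be parsed (reported with its row number).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        records: list[GeneQuantRecord] = []
        seen: set[str] = set()
        for rownum, row in enumerate(reader, start=2):  # row 1 is the header
            vals = {}
            for col in REQUIRED_COLUMNS[1:]:
                try:
                    v = float(row[col])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}, row {rownum}: non-numeric value "
                        f"{row.get(col)!r} in column {col!r}"
                    ) from None
                if not math.isfinite(v):
                    raise ParseError(
                        f"{path}, row {rownum}: non-finite value in {col!r}"
                    )
                vals[col] = v
            gid = row["gene_id"]
            if gid in seen:
                raise ConsistencyError(f"{path}: duplicate gene_id {gid!r}")
            seen.add(gid)
            records.append(
                GeneQuantRecord(
                    gene_id=gid,
                    length=vals["length"],
                    effective_length=vals["effective_length"],
                    expected_count=vals["expected_count"],
                    tpm=vals["TPM"],
                    fpkm=vals["FPKM"],
                )
            )
    return records


def read_sample_sheet(path: str | os.PathLike) -> list[SampleAnnotation]:
    """Read a sample sheet CSV (``sample_id,model_id,passage,file_path``).

    Relative file paths are resolved against the sheet's directory.  Every
    model must have at least two samples, since all downstream analyses are
    replicate analyses.
    """
    base = os.path.dirname(os.fspath(path))
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "model_id", "passage", "file_path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    annotations = []
    for row in df.itertuples(index=False):
        fp = row.file_path
        if fp and not os.path.isabs(fp):
            fp = os.path.join(base, fp)
        annotations.append(
            SampleAnnotation(
                sample_id=row.sample_id,
                model_id=row.model_id,
                passage=row.passage,
                file_path=fp,
            )
        )
    grouping = ModelGrouping(annotations)  # checks sample_id uniqueness
    grouping.require_replicates(2)
    return annotations


def load_samples(
    annotations: list[SampleAnnotation],
) -> dict[str, list[GeneQuantRecord]]:
    """Read every annotated RSEM file, keyed by sample in sheet order."""
    return {a.sample_id: read_rsem_genes(a.file_path) for a in annotations}


def assemble_matrix(
    records_by_sample: dict[str, list[GeneQuantRecord]], measure: str
) -> ExpressionMatrix:
    """Stack per-sample records into a genes x samples ExpressionMatrix.

    Gene order is the file order of the first sample (canonical; no sorting).
    All samples must contain exactly the same gene set.
    """
    if measure not in _MEASURE_FIELD:
        raise QuantBenchError(
            f"measure {measure!r} not assemblable from RSEM records "
            f"(choose from {sorted(_MEASURE_FIELD)})"
        )
    if not records_by_sample:
        raise ConsistencyError("no samples provided")
    field = _MEASURE_FIELD[measure]
    sample_ids = list(records_by_sample)
    first = records_by_sample[sample_ids[0]]
    gene_ids = [r.gene_id for r in first]
    gene_set = set(gene_ids)
    cols = []
    for sid in sample_ids:
        recs = records_by_sample[sid]
        this_set = {r.gene_id for r in recs}
        if this_set != gene_set:
            diff = sorted(this_set.symmetric_difference(gene_set))
            raise ConsistencyError(
                f"sample {sid!r} gene set differs from first sample; "
                f"symmetric difference: {diff[:50]}"
            )
        by_id = {r.gene_id: r for r in recs}
        cols.append([getattr(by_id[g], field) for g in gene_ids])
    values = np.array(cols, dtype=float).T
    return ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, measure=measure
    )


def effective_lengths(records_by_sample: dict[str, list[GeneQuantRecord]]):
    """Effective-length vector taken from the first sample's records."""
    from .quantification import LengthVector

    first = next(iter(records_by_sample.values()))
    return LengthVector(
        gene_ids=[r.gene_id for r in first],
        effective_length=np.array([r.effective_length for r in first]),
    )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform; refuses to double-transform."""
    if m.scale != "linear":
        raise QuantBenchError("matrix is already log2(x+1)-transformed")
    return m.with_values(np.log2(m.values + 1.0), scale="log2p1")


def write_matrix_tsv(m: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write a matrix as TSV: first column gene_id, one column per sample."""
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix_tsv(
    path: str | os.PathLike, measure: str, scale: str = "linear"
) -> ExpressionMatrix:
    df = pd.read_csv(
        path, sep="\t", index_col="gene_id", float_precision="round_trip"
    )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        measure=measure,
        scale=scale,
    )
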