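"""Core in-memory containers: expression matrices and replicate groupings.

An :class:`ExpressionMatrix` is a genes x samples array tagged with the
quantification *measure* it holds (raw expected counts, TPM, FPKM,
normalized counts, or per-gene Z-scores) and the *scale* it is on (linear or
log2(x+1)).  Tagging the measure/scale lets downstream stages enforce their
preconditions (e.g. CV wants linear values, ICC wants log2(x+1)) instead of
silently producing nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConsistencyError, QuantBenchError

MEASURES = ("count", "tpm", "fpkm", "normcount", "zscore")
SCALES = ("linear", "log2p1")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with measure and scale tags.

    Parameters
    ----------
    gene_ids : list of str
        Row labels, in a fixed canonical order (all samples share it).
    sample_ids : list of str
        Column labels.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; float64.
    measure : {'count', 'tpm', 'fpkm', 'normcount', 'zscore'}
    scale : {'linear', 'log2p1'}
    meta : dict
        Free-form annotations (e.g. zero-variance gene flags, TMM factors).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    measure: str
    scale: str = "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ConsistencyError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.measure not in MEASURES:
            raise QuantBenchError(f"unknown measure {self.measure!r}")
        if self.scale not in SCALES:
            raise QuantBenchError(f"unknown scale {self.scale!r}")
        if (
            self.scale == "linear"
            and self.measure != "zscore"
            and self.values.size
            and np.nanmin(self.values) < 0
        ):
            raise QuantBenchError(
                f"negative entries in a linear-scale {self.measure} matrix"
            )

    # -- convenience -----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def with_values(
        self, values: np.ndarray, measure: str | None = None, scale: str | None = None
    ) -> "ExpressionMatrix":
        """Copy of this matrix with new values (and optionally new tags)."""
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            measure=self.measure if measure is None else measure,
            scale=self.scale if scale is None else scale,
            meta=dict(self.meta),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            measure=self.measure,
            scale=self.scale,
            meta=dict(self.meta),
        )


@dataclass
class SampleAnnotation:
    """One sample-sheet row: sample identity, replicate group, source file."""

    sample_id: str
    model_id: str
    passage: str = ""
    file_path: str = ""


class ModelGrouping:
    """Mapping sample -> model that defines replicate groups.

    Replicate order within a model is sample-sheet order, which matters for
    the first-r truncation rule used by the per-gene intraclass correlation.
    """

    def __init__(self, annotations: list[SampleAnnotation]):
        seen: set[str] = set()
        self._model_of: dict[str, str] = {}
        self._groups: dict[str, list[str]] = {}
        for a in annotations:
            if a.sample_id in seen:
                raise ConsistencyError(f"duplicate sample_id {a.sample_id!r}")
            seen.add(a.sample_id)
            self._model_of[a.sample_id] = a.model_id
            self._groups.setdefault(a.model_id, []).append(a.sample_id)
        self.annotations = list(annotations)

    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations]

    @property
    def model_ids(self) -> list[str]:
        return list(self._groups)

    def model_of(self, sample_id: str) -> str:
        try:
            return self._model_of[sample_id]
        except KeyError:
            raise ConsistencyError(f"sample {sample_id!r} has no model assignment")

    def samples_of(self, model_id: str) -> list[str]:
        return list(self._groups[model_id])

    def items(self) -> Iterator[tuple[str, list[str]]]:
        for m, s in self._groups.items():
            yield m, list(s)

    def require_replicates(self, minimum: int = 2) -> None:
        bad = [m for m, s in self._groups.items() if len(s) < minimum]
        if bad:
            raise ConsistencyError(
                f"models with fewer than {minimum} replicates: {bad}"
            )

    def min_replicates(self) -> int:
        return min(len(s) for s in self._groups.values())
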