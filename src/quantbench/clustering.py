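"""Sample dissimilarities, Ward.D2 agglomerative clustering, and the two
dendrogram summaries used to judge replicate concordance.

Samples are clustered on 1 - Pearson correlation or Euclidean distance.
Linkage follows the Ward.D2 convention: the Lance-Williams recurrence is
applied to *squared* dissimilarities,

    d(k, i u j)^2 = ((n_i+n_k) d_ki^2 + (n_j+n_k) d_kj^2 - n_k d_ij^2)
                    / (n_i + n_j + n_k)

and merge heights are reported on the unsquared scale.  On 1 - r input the
heights are therefore not bounded by 2.  Ties are broken by the smallest
(cluster_a, cluster_b) id pair, making the dendrogram fully deterministic.

A replicate group ("model") is *concordant* when some internal node of the
dendrogram contains exactly that group's samples — an exclusive clade.  The
discordant-model count and the maximum merge height are the two headline
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConsistencyError, DegenerateSampleError, QuantBenchError
from .matrix import ExpressionMatrix, ModelGrouping


@dataclass
class DissimilarityMatrix:
    """Symmetric sample-sample dissimilarities with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray
    metric: str  # 'one_minus_pearson' | 'euclidean'

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ConsistencyError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ConsistencyError("dissimilarity matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ConsistencyError("dissimilarity diagonal is not zero")
        if self.d.size and self.d.min() < -1e-12:
            raise QuantBenchError("negative dissimilarities")
        # enforce exact symmetry / zero diagonal after the tolerance check
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` holds (cluster_a, cluster_b, height, size) per merge, with
    scipy id conventions: leaves are 0..n-1, the cluster created by merge t
    has id n+t.  Heights are not guaranteed monotone (Ward on non-Euclidean
    dissimilarities can invert).
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-name set of every internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([s]) for i, s in enumerate(self.leaf_ids)
        }
        out = []
        for t, (a, b, _h, _sz) in enumerate(self.merges):
            merged = sets[a] | sets[b]
            sets[n + t] = merged
            out.append(merged)
        return out

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-style (n-1) x 4 linkage matrix."""
        return np.array(
            [[a, b, h, sz] for a, b, h, sz in self.merges], dtype=float
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: _esc(s) for i, s in enumerate(self.leaf_ids)}
        for t, (a, b, h, _sz) in enumerate(self.merges):
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + t] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + t] = h
        root = n + len(self.merges) - 1
        return node[root] + ";"

    def to_merge_table(self):
        import pandas as pd

        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )


def _esc(name: str) -> str:
    return name.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "|").replace(":", "|").replace(";", "|")


def pearson_dissimilarity(m: ExpressionMatrix) -> DissimilarityMatrix:
    """1 - Pearson correlation between sample columns, over all genes."""
    if m.n_samples < 2:
        raise QuantBenchError("need at least 2 samples")
    sd = m.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateSampleError(
            f"zero-variance sample column(s): {[m.sample_ids[i] for i in flat]}"
        )
    r = np.corrcoef(m.values, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return DissimilarityMatrix(
        sample_ids=list(m.sample_ids), d=d, metric="one_minus_pearson"
    )


def euclidean_dissimilarity(m: ExpressionMatrix) -> DissimilarityMatrix:
    """Euclidean distance between sample columns over all genes."""
    if m.n_samples < 2:
        raise QuantBenchError("need at least 2 samples")
    d = squareform(pdist(m.values.T, metric="euclidean"))
    return DissimilarityMatrix(
        sample_ids=list(m.sample_ids), d=d, metric="euclidean"
    )


def ward_linkage(d: DissimilarityMatrix, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering under Ward.D2 (default) or complete linkage.

    Deterministic: among pairs tied at the minimal criterion, the smallest
    (cluster_a, cluster_b) id pair merges first.
    """
    if linkage not in ("ward", "complete"):
        raise QuantBenchError(f"unknown linkage {linkage!r}")
    n = len(d.sample_ids)
    if n < 2:
        raise QuantBenchError("need at least 2 samples to cluster")
    # working criterion: squared dissimilarities for ward, plain for complete
    crit = d.d**2 if linkage == "ward" else d.d.copy()

    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    active = crit.copy()
    np.fill_diagonal(active, np.inf)
    # map position -> cluster id; positions are compacted as clusters merge
    pos_id = list(range(n))

    for t in range(n - 1):
        k = len(pos_id)
        # find minimal entry; break ties by smallest sorted (id_a, id_b)
        best: tuple = (np.inf, (np.inf, np.inf), -1, -1)
        for i in range(k):
            for j in range(i + 1, k):
                v = active[i, j]
                pair = tuple(sorted((pos_id[i], pos_id[j])))
                if v < best[0] or (v == best[0] and pair < best[1]):
                    best = (v, pair, i, j)
        v, (ida, idb), i, j = best
        height = np.sqrt(max(v, 0.0)) if linkage == "ward" else v
        new_id = n + t
        new_size = sizes[ida] + sizes[idb]
        merges.append((ida, idb, float(height), new_size))

        # Lance-Williams update for every other active cluster; weights must
        # follow the positions i/j, not the sorted id pair
        ni, nj = sizes[pos_id[i]], sizes[pos_id[j]]
        new_row = np.empty(k)
        for c in range(k):
            if c in (i, j):
                new_row[c] = np.inf
                continue
            nk = sizes[pos_id[c]]
            if linkage == "ward":
                new_row[c] = (
                    (ni + nk) * active[c, i]
                    + (nj + nk) * active[c, j]
                    - nk * v
                ) / (ni + nj + nk)
            else:
                new_row[c] = max(active[c, i], active[c, j])

        # replace row/col i with the merged cluster, drop row/col j
        active[i, :] = new_row
        active[:, i] = new_row
        active[i, i] = np.inf
        active = np.delete(np.delete(active, j, axis=0), j, axis=1)
        pos_id[i] = new_id
        del pos_id[j]
        sizes[new_id] = new_size

    return Dendrogram(merges=merges, leaf_ids=list(d.sample_ids))


def discordant_models(
    dend: Dendrogram, groups: ModelGrouping
) -> tuple[int, list[str]]:
    """Count replicate groups that do not form an exclusive clade.

    A model is concordant iff some internal node's leaf set equals exactly
    that model's replicate set.  Returns (count, discordant model ids in
    grouping order).
    """
    for leaf in dend.leaf_ids:
        groups.model_of(leaf)  # raises if unassigned
    clades = set(dend.leaf_sets())
    discordant = []
    for model_id, samples in groups.items():
        want = frozenset(samples)
        if len(want) == 1:
            continue  # a singleton is trivially its own clade (a leaf)
        if want not in clades:
            discordant.append(model_id)
    return len(discordant), discordant


def max_height(dend: Dendrogram) -> float:
    """Maximum merge height (the root merge under Ward)."""
    if not dend.merges:
        raise QuantBenchError("dendrogram has no merges")
    return max(h for _a, _b, h, _sz in dend.merges)
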