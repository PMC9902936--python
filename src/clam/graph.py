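"""Per-dataset KNN graphs and their fusion into a trans-omics neighborhood.

Within one omics layer every gene is linked to its ``k`` most similar genes,
with the similarities normalised into weights ``w_xy = S_xy / sum_z S_xz``
so that each gene's outgoing weights sum to one. Graphs from different
layers are then fused: a gene measured in ``m`` layers contributes its
``m x k`` neighbor lists with every weight divided by that gene's own ``m``,
and duplicated (gene, neighbor) pairs are merged by summing — duplicated
neighbors therefore end up with higher weight, which is the point of the
fusion. The neighbor relation is directed and never symmetrized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import mutual_info_score

from .containers import CLAMError, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["Similarity", "NeighborhoodGraph", "similarity", "knn_weights", "fuse"]

MEASURES = ("pearson", "euclidean", "mutual_information")


@dataclass
class Similarity:
    """Symmetric gene x gene similarity table.

    ``values`` holds the non-negative similarity used for neighbor search
    (|r| under Pearson); ``signs`` retains the sign of the raw correlation
    so downstream steps can orient anti-correlated genes.
    """

    values: pd.DataFrame
    signs: pd.DataFrame | None = None
    measure: str = "pearson"

    def lookup(self, x: str, y: str) -> float:
        return float(self.values.at[x, y])


@dataclass
class NeighborhoodGraph:
    """Directed weighted KNN graph over genes.

    ``neighbors[x]`` is a list of ``(neighbor, weight, similarity)`` tuples;
    outgoing weights sum to one per gene. ``dataset_counts[x]`` records in
    how many omics layers ``x`` was measured (1 for per-dataset graphs).
    """

    objects: List[str]
    neighbors: Dict[str, List[Tuple[str, float, float]]]
    k: int
    source: str
    dataset_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dataset_counts:
            self.dataset_counts = {g: 1 for g in self.objects}

    def weight_sums(self) -> pd.Series:
        return pd.Series(
            {g: sum(w for _, w, _ in nbrs) for g, nbrs in self.neighbors.items()}
        )

    def neighbor_ids(self, gene: str) -> List[str]:
        return [nbr for nbr, _, _ in self.neighbors[gene]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, nbr, w, s)
            for g in self.objects
            for nbr, w, s in self.neighbors[g]
        ]
        return pd.DataFrame(rows, columns=["object", "neighbor", "weight", "similarity"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _pearson_similarity(matrix: ExpressionMatrix, absolute: bool) -> Similarity:
    values = matrix.values
    sd = values.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        logger.warning(
            "similarity[%s]: %d zero-variance genes; their correlations set to 0",
            matrix.dataset_id,
            flat.size,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    signs = np.where(corr >= 0, 1.0, -1.0)
    sim = np.abs(corr) if absolute else np.clip(corr, 0.0, None)
    np.fill_diagonal(sim, 0.0)  # diagonal excluded from neighbor search
    genes = matrix.genes
    return Similarity(
        values=pd.DataFrame(sim, index=genes, columns=genes),
        signs=pd.DataFrame(signs, index=genes, columns=genes),
        measure="pearson",
    )


def _euclidean_similarity(matrix: ExpressionMatrix) -> Similarity:
    dist = squareform(pdist(matrix.values, metric="euclidean"))
    sim = 1.0 / (1.0 + dist)
    np.fill_diagonal(sim, 0.0)
    genes = matrix.genes
    return Similarity(
        values=pd.DataFrame(sim, index=genes, columns=genes), measure="euclidean"
    )


def _mutual_information_similarity(matrix: ExpressionMatrix) -> Similarity:
    values = matrix.values
    n_samples = values.shape[1]
    n_bins = max(2, int(np.floor(np.sqrt(n_samples))))
    # equal-frequency bins: rank each profile, split ranks into n_bins blocks
    ranks = values.argsort(axis=1).argsort(axis=1)
    binned = (ranks * n_bins) // n_samples
    n = len(matrix.genes)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi = mutual_info_score(binned[i], binned[j])
            sim[i, j] = sim[j, i] = mi
    genes = matrix.genes
    return Similarity(
        values=pd.DataFrame(sim, index=genes, columns=genes),
        measure="mutual_information",
    )


def similarity(
    matrix: ExpressionMatrix,
    measure: str = "pearson",
    absolute: bool = True,
) -> Similarity:
    """Compute the symmetric gene x gene similarity table of one layer.

    Parameters
    ----------
    measure
        ``"pearson"`` (|r|, or positive part with ``absolute=False``),
        ``"euclidean"`` (1/(1+d)) or ``"mutual_information"``
        (equal-frequency binning with max(2, floor(sqrt(n_samples))) bins).
    absolute
        Under Pearson, admit strongly anti-correlated genes as neighbors by
        taking |r| (default); the sign is retained separately either way.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown similarity measure {measure!r}")
    if matrix.n_missing():
        raise CLAMError("similarity requires a fully imputed matrix")
    if measure == "pearson":
        if len(matrix.samples) < 3:
            raise CLAMError("pearson similarity needs >= 3 samples")
        return _pearson_similarity(matrix, absolute)
    if measure == "euclidean":
        return _euclidean_similarity(matrix)
    return _mutual_information_similarity(matrix)


def knn_weights(sim: Similarity, k: int, source: str | None = None) -> NeighborhoodGraph:
    """Build the directed KNN graph with weights ``w_xy = S_xy / sum S_xz``.

    For each gene the ``min(k, n-1)`` largest-similarity neighbors are
    selected, ties at the cut broken by lexicographic gene id. A gene with
    no positive-similarity neighbor receives uniform weights over its k
    nearest (with a warning); neighbors with similarity exactly 0 among an
    otherwise positive list are dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = list(sim.values.index)
    n = len(genes)
    if n < 2:
        raise CLAMError("need at least 2 genes to build a KNN graph")
    k_eff = min(k, n - 1)
    values = sim.values.to_numpy()
    neighbors: Dict[str, List[Tuple[str, float, float]]] = {}
    for i, gene in enumerate(genes):
        sims = values[i]
        cand = np.delete(np.arange(n), i)
        cand_sorted = sorted(cand, key=lambda j: (-sims[j], genes[j]))
        top = cand_sorted[:k_eff]
        top_sims = np.array([sims[j] for j in top])
        if np.all(top_sims <= 0):
            logger.warning(
                "knn_weights[%s]: gene %r has no positive-similarity neighbor; "
                "using uniform weights",
                source or sim.measure,
                gene,
            )
            neighbors[gene] = [
                (genes[j], 1.0 / k_eff, float(sims[j])) for j in top
            ]
            continue
        keep = [(j, s) for j, s in zip(top, top_sims) if s > 0]
        total = sum(s for _, s in keep)
        neighbors[gene] = [(genes[j], s / total, float(s)) for j, s in keep]
    return NeighborhoodGraph(
        objects=genes, neighbors=neighbors, k=k, source=source or "dataset"
    )


def fuse(graphs: Sequence[NeighborhoodGraph]) -> NeighborhoodGraph:
    """Fuse per-dataset KNN graphs into the trans-omics neighborhood graph.

    Every gene's incoming lists are concatenated with weights divided by
    that gene's own dataset count ``m``; duplicate (gene, neighbor) pairs
    are merged by summing their weights. Per-gene weights still sum to one.
    The retained similarity of a merged edge is the plain mean over the
    layers in which the edge occurs (weights carry the 1/m probability
    bookkeeping; halving similarities as well would make densities
    incomparable between genes measured in different numbers of layers).
    """
    if not graphs:
        raise ValueError("need at least one graph to fuse")
    counts: Dict[str, int] = {}
    for graph in graphs:
        for gene in graph.objects:
            counts[gene] = counts.get(gene, 0) + 1
    merged: Dict[str, Dict[str, List[float]]] = {}
    for graph in graphs:
        for gene in graph.objects:
            m = counts[gene]
            bucket = merged.setdefault(gene, {})
            for nbr, w, s in graph.neighbors[gene]:
                if nbr in bucket:
                    bucket[nbr][0] += w / m
                    bucket[nbr][1] += s
                    bucket[nbr][2] += 1
                else:
                    bucket[nbr] = [w / m, s, 1]
    objects = sorted(merged)
    neighbors = {
        gene: [
            (nbr, wsc[0], wsc[1] / wsc[2])
            for nbr, wsc in sorted(bucket.items(), key=lambda kv: (-kv[1][0], kv[0]))
        ]
        for gene, bucket in merged.items()
    }
    k = max(g.k for g in graphs)
    return NeighborhoodGraph(
        objects=objects,
        neighbors=neighbors,
        k=k,
        source="fused",
        dataset_counts=counts,
    )
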