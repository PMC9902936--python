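"""Module identification by local approximation of membership vectors.

Each gene's density is the mean similarity to its graph neighbors. Genes
denser than every neighbor are cluster centers, genes less dense than every
neighbor are outliers, everything else is ordinary. Given ``M`` centers,
every gene carries a membership vector of length ``M + 1`` (last slot =
outlier probability): centers and outliers are one-hot and held fixed,
ordinary genes start uniform at ``1/(M+1)`` and are updated synchronously
by the weighted average of their neighbors' vectors,
``p_x <- sum_{y in KNN(x)} w_xy p_y``, until the largest per-gene change
falls below tolerance. The objective ``E = sum_x ||p_x - sum_y w_xy p_y||^2``
is recorded per sweep. Final modules are the argmax of the converged
vectors, with ties to the lowest cluster index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CLAMError, ExpressionMatrix, InteractionDB, ModuleSet
from .graph import NeighborhoodGraph, Similarity, fuse, knn_weights, similarity
from . import io as _io
from .prior import reweight_graph

logger = logging.getLogger(__name__)

__all__ = [
    "DensityTable",
    "MembershipState",
    "compute_density",
    "find_centers_outliers",
    "init_membership",
    "iterate",
    "assign",
    "run_clam",
]

ROLE_CENTER = "center"
ROLE_OUTLIER = "outlier"
ROLE_ORDINARY = "ordinary"


@dataclass
class DensityTable:
    """Per-gene local density and structural role."""

    density: pd.Series
    roles: pd.Series  # "center" | "outlier" | "ordinary"

    @property
    def centers(self) -> List[str]:
        return sorted(self.roles.index[self.roles == ROLE_CENTER])

    @property
    def outliers(self) -> List[str]:
        return sorted(self.roles.index[self.roles == ROLE_OUTLIER])


@dataclass
class MembershipState:
    """Membership vectors over ``M`` clusters plus the outlier slot.

    ``membership`` is genes x (M + 1); column ``i < M`` corresponds to the
    cluster seeded by ``centers[i]``, the last column is the outlier slot.
    """

    membership: pd.DataFrame
    centers: List[str]
    outliers: List[str]
    objective_path: List[float] = field(default_factory=list)
    free_residual_path: List[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def compute_density(graph: NeighborhoodGraph) -> pd.Series:
    """Density of each gene: mean retained similarity over its neighbors."""
    return pd.Series(
        {
            gene: float(np.mean([s for _, _, s in nbrs]))
            for gene, nbrs in graph.neighbors.items()
        }
    ).loc[graph.objects]


def find_centers_outliers(
    graph: NeighborhoodGraph,
    density: pd.Series,
    outlier_threshold: float | str | None = "mean",
) -> DensityTable:
    """Assign center/outlier/ordinary roles by strict density comparison.

    A gene is a center when its density is strictly greater than that of
    every gene in its neighbor list. Outlier prototypes depend on
    ``outlier_threshold``:

    * ``None`` — the strict local rule: a gene strictly less dense than
      every one of its neighbors is an outlier.
    * ``"mean"`` (default) or a float — a density threshold in the spirit
      of the outlier threshold of the local-approximation procedure this
      follows: every gene with density below the cutoff (the global mean
      density, or the given value) becomes a fixed outlier prototype, and
      local density minima *above* the cutoff stay ordinary. Without this
      guard the least-dense member inside an otherwise tight module acts
      as an absorbing outlier prototype and drains its own module's
      membership, while genuinely unclustered low-density genes supply
      too few prototypes to be recognised as noise.

    Ties in the strict comparisons make a gene ordinary. At least one
    center is required.
    """
    roles = {}
    if outlier_threshold is None:
        for gene in graph.objects:
            nbr_density = density.loc[graph.neighbor_ids(gene)]
            own = density.loc[gene]
            if (own > nbr_density).all():
                roles[gene] = ROLE_CENTER
            elif (own < nbr_density).all():
                roles[gene] = ROLE_OUTLIER
            else:
                roles[gene] = ROLE_ORDINARY
    else:
        cutoff = (
            float(density.mean())
            if outlier_threshold == "mean"
            else float(outlier_threshold)
        )
        for gene in graph.objects:
            nbr_density = density.loc[graph.neighbor_ids(gene)]
            own = density.loc[gene]
            if (own > nbr_density).all() and own >= cutoff:
                roles[gene] = ROLE_CENTER
            elif own < cutoff:
                roles[gene] = ROLE_OUTLIER
            else:
                roles[gene] = ROLE_ORDINARY
    table = DensityTable(density=density, roles=pd.Series(roles).loc[graph.objects])
    if not table.centers:
        raise CLAMError(
            "no cluster centers found; try a smaller k (denser data yields "
            "local density maxima only when neighborhoods are not too wide)"
        )
    return table


def init_membership(table: DensityTable) -> MembershipState:
    """One-hot centers and outliers, uniform 1/(M+1) for ordinary genes."""
    centers = table.centers
    outliers = table.outliers
    M = len(centers)
    genes = list(table.roles.index)
    vectors = np.full((len(genes), M + 1), 1.0 / (M + 1))
    index = {g: i for i, g in enumerate(genes)}
    for slot, c in enumerate(centers):
        vectors[index[c]] = 0.0
        vectors[index[c], slot] = 1.0
    for o in outliers:
        vectors[index[o]] = 0.0
        vectors[index[o], M] = 1.0
    columns = [f"cluster_{i + 1}" for i in range(M)] + ["outlier"]
    return MembershipState(
        membership=pd.DataFrame(vectors, index=genes, columns=columns),
        centers=centers,
        outliers=outliers,
    )


def _weight_matrix(graph: NeighborhoodGraph, genes: List[str]) -> sp.csr_matrix:
    index = {g: i for i, g in enumerate(genes)}
    rows, cols, vals = [], [], []
    for gene in genes:
        i = index[gene]
        for nbr, w, _ in graph.neighbors[gene]:
            rows.append(i)
            cols.append(index[nbr])
            vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(genes), len(genes)))


def iterate(
    state: MembershipState,
    graph: NeighborhoodGraph,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MembershipState:
    """Run the synchronous fixed-point iteration to convergence.

    Ordinary genes are replaced by the weighted average of their neighbors'
    vectors each sweep; centers and outliers stay one-hot. Stops when the
    largest absolute per-entry change drops below ``tol``. When the weight
    rows do not sum to one (prior renormalisation off) each updated vector
    is projected back to the simplex by L1 normalisation.

    Two residual paths are recorded per sweep: ``objective_path`` is the
    full objective ``E`` summed over every gene, and ``free_residual_path``
    restricts the sum to the ordinary (updated) genes — the part the
    iteration drives to zero, which decreases monotonically; the terms of
    the fixed prototypes can fluctuate transiently.
    """
    genes = list(state.membership.index)
    W = _weight_matrix(graph, genes)
    P = state.membership.to_numpy().copy()
    fixed = np.zeros(len(genes), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in state.centers + state.outliers:
        fixed[gene_pos[g]] = True
    row_sums = np.asarray(W.sum(axis=1)).ravel()
    needs_projection = not np.allclose(row_sums, 1.0, atol=1e-9)

    def residuals(P: np.ndarray) -> tuple:
        resid = P - W @ P
        sq = resid * resid
        return float(sq.sum()), float(sq[~fixed].sum())

    e_full, e_free = residuals(P)
    objective_path, free_residual_path = [e_full], [e_free]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new = W @ P
        if needs_projection:
            totals = new.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            new = new / totals
        new[fixed] = P[fixed]
        delta = np.abs(new - P).max()
        P = new
        e_full, e_free = residuals(P)
        objective_path.append(e_full)
        free_residual_path.append(e_free)
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "membership iteration did not converge in %d sweeps (E = %.3g)",
            max_iter,
            objective_path[-1],
        )
    # simplex conservation check (tolerance mirrors the graph invariant)
    sums = P.sum(axis=1)
    if needs_projection is False and not np.allclose(sums, 1.0, atol=1e-6):
        raise CLAMError("membership vectors left the probability simplex")
    return MembershipState(
        membership=pd.DataFrame(P, index=genes, columns=state.membership.columns),
        centers=state.centers,
        outliers=state.outliers,
        objective_path=objective_path,
        free_residual_path=free_residual_path,
        n_iter=n_iter,
        converged=converged,
    )


def solve_membership(state: MembershipState, graph: NeighborhoodGraph) -> pd.DataFrame:
    """Exact fixed point by direct linear solve (reference for small graphs).

    Solves ``(I - W_oo) P_o = W_of P_f`` for the ordinary block; centers and
    outliers keep their one-hot vectors. Only intended for small instances.
    """
    genes = list(state.membership.index)
    W = _weight_matrix(graph, genes).toarray()
    P = state.membership.to_numpy().copy()
    fixed = np.zeros(len(genes), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in state.centers + state.outliers:
        fixed[gene_pos[g]] = True
    free = ~fixed
    if free.any():
        Woo = W[np.ix_(free, free)]
        Wof = W[np.ix_(free, fixed)]
        A = np.eye(Woo.shape[0]) - Woo
        P[free] = np.linalg.solve(A, Wof @ P[fixed])
    return pd.DataFrame(P, index=genes, columns=state.membership.columns)


def assign(state: MembershipState, min_module_size: Optional[int] = None) -> ModuleSet:
    """Hard assignment: each gene goes to its argmax slot.

    Ties break toward the lowest cluster index; the outlier slot, being
    last, loses every tie. Modules smaller than ``min_module_size`` (when
    given) are folded into the outlier set.
    """
    P = state.membership.to_numpy()
    M = state.n_clusters
    best = P.argmax(axis=1)  # argmax takes the first maximum -> lowest index
    modules: Dict[str, set] = {}
    outliers: set = set()
    for gene, slot in zip(state.membership.index, best):
        if slot == M:
            outliers.add(gene)
        else:
            modules.setdefault(f"module_{slot + 1}", set()).add(gene)
    if min_module_size:
        for name in sorted(modules):
            if len(modules[name]) < min_module_size:
                outliers |= modules.pop(name)
    return ModuleSet.from_dict(modules, outliers)


def run_clam(
    datasets: Sequence[ExpressionMatrix],
    interactions: Optional[InteractionDB] = None,
    k: int = 10,
    measure: str = "pearson",
    absolute_corr: bool = True,
    use_prior: bool = True,
    prior_temperature: float = 1.0,
    include_pathways: bool = True,
    renormalize_prior: bool = True,
    merge_identifiers: bool = True,
    max_missing_fraction: float = 0.20,
    impute_k: Optional[int] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_module_size: Optional[int] = None,
    outlier_threshold: float | str | None = "mean",
    return_state: bool = False,
):
    """Full pipeline: preprocess, per-dataset KNN, fuse, prior, cluster.

    Deterministic: the core path contains no randomness. With
    ``merge_identifiers=False`` genes are namespaced ``<gene>@<dataset>`` so
    identical identifiers on different omics layers stay distinct objects.
    Returns the hard :class:`ModuleSet`, or ``(modules, state, table, graph)``
    when ``return_state`` is set.
    """
    if not datasets:
        raise CLAMError("need at least one expression dataset")
    prepared = []
    for ds in datasets:
        ds2 = ds if merge_identifiers else ds.namespaced()
        if ds2.n_missing():
            ds2 = _io.preprocess(
                ds2, max_missing_fraction=max_missing_fraction, k=impute_k or k
            )
        prepared.append(ds2)
    graphs = [
        knn_weights(
            similarity(ds, measure=measure, absolute=absolute_corr),
            k,
            source=ds.dataset_id,
        )
        for ds in prepared
    ]
    fused = fuse(graphs)
    if use_prior and interactions is not None and not interactions.is_empty():
        fused = reweight_graph(
            fused,
            interactions,
            temperature=prior_temperature,
            include_pathways=include_pathways,
            renormalize=renormalize_prior,
        )
    density = compute_density(fused)
    table = find_centers_outliers(fused, density, outlier_threshold=outlier_threshold)
    state = iterate(init_membership(table), fused, tol=tol, max_iter=max_iter)
    modules = assign(state, min_module_size=min_module_size)
    if return_state:
        return modules, state, table, fused
    return modules
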