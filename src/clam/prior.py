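"""Co-regulatory prior: interaction-derived edge reweighting of the graph.

For each gene ``g1`` a local co-regulatory network is assembled from the
interaction database: the miRNAs and TFs that target ``g1``, its direct
PPI partners and (optionally) the pathways containing it. With
``n1 + n2 + n3`` such anchors, every edge leaving ``g1`` in that network
carries weight ``1/(n1+n2+n3)``; a shared regulator that targets ``n4`` of
``g1``'s graph neighbors passes ``1/n4`` of its mass to each, so a
neighbor reached through a shared regulator scores
``1/(n1+n2+n3) * 1/n4`` and a direct PPI partner scores ``1/(n1+n2+n3)``.
Contributions over multiple connecting paths sum; neighbors outside the
co-regulatory network score zero. The scores are turned into a prior
probability over the neighbor list by a softmax and multiplied into the
graph weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy.special import softmax

from .containers import CLAMError, InteractionDB
from .graph import NeighborhoodGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CoRegScores",
    "coregulation_scores",
    "prior_probabilities",
    "apply_prior",
    "reweight_graph",
]


@dataclass
class CoRegScores:
    """Co-regulation scores of one gene against its neighbor list."""

    gene: str
    scores: Dict[str, float]
    n_mirna: int
    n_tf: int
    n_ppi: int
    n_pathway: int = 0

    @property
    def denominator(self) -> int:
        return self.n_mirna + self.n_tf + self.n_ppi + self.n_pathway


def coregulation_scores(
    gene: str,
    neighbors: Sequence[str],
    db: InteractionDB,
    include_pathways: bool = True,
) -> CoRegScores:
    """Score each neighbor of ``gene`` by the co-regulatory network.

    Pathway co-membership, when enabled, is treated like a TF-style shared
    regulator: each pathway containing ``gene`` counts once in the
    denominator and splits ``1/n4`` over the neighbors it contains.
    A gene with no regulators or partners at all scores every neighbor 0.
    """
    if not neighbors:
        raise CLAMError(f"gene {gene!r} has an empty neighbor list")
    neighbor_set = set(neighbors)
    mirnas = db.regulators_of(gene, "mirna")
    tfs = db.regulators_of(gene, "tf")
    partners = db.ppi_partners(gene)
    pathways = (
        {p for p, members in db.pathways.items() if gene in members}
        if include_pathways
        else set()
    )
    denom = len(mirnas) + len(tfs) + len(partners) + len(pathways)
    scores = {nbr: 0.0 for nbr in neighbors}
    if denom == 0:
        return CoRegScores(gene, scores, len(mirnas), len(tfs), len(partners), len(pathways))
    unit = 1.0 / denom
    for regulator_set, table in ((mirnas, db.mirna_targets), (tfs, db.tf_targets)):
        for reg in regulator_set:
            shared = neighbor_set & set(table[reg]) - {gene}
            if shared:
                share = unit / len(shared)
                for nbr in shared:
                    scores[nbr] += share
    for pw in pathways:
        shared = neighbor_set & set(db.pathways[pw]) - {gene}
        if shared:
            share = unit / len(shared)
            for nbr in shared:
                scores[nbr] += share
    for nbr in neighbor_set & partners:
        scores[nbr] += unit
    return CoRegScores(gene, scores, len(mirnas), len(tfs), len(partners), len(pathways))


def prior_probabilities(
    scores: CoRegScores, temperature: float = 1.0
) -> Dict[str, float]:
    """Softmax transform of co-regulation scores into a prior over neighbors.

    ``p_i = exp(c_i / tau) / sum_j exp(c_j / tau)``; all-zero scores yield
    the uniform prior, which leaves the graph untouched after
    renormalisation.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    names = list(scores.scores)
    raw = np.array([scores.scores[n] for n in names]) / temperature
    probs = softmax(raw)
    return dict(zip(names, probs))


def apply_prior(
    graph: NeighborhoodGraph,
    priors: Dict[str, Dict[str, float]],
    renormalize: bool = True,
) -> NeighborhoodGraph:
    """Replace each weight by ``w_xy * prior_xy``.

    With ``renormalize`` (default) each gene's outgoing weights are rescaled
    to sum to one afterwards, keeping membership propagation on the
    probability simplex.
    """
    neighbors = {}
    for gene in graph.objects:
        try:
            gene_priors = priors[gene]
        except KeyError as exc:
            raise CLAMError(f"no prior vector for gene {gene!r}") from exc
        updated = []
        for nbr, w, s in graph.neighbors[gene]:
            if nbr not in gene_priors:
                raise CLAMError(f"no prior for edge {gene!r} -> {nbr!r}")
            updated.append((nbr, w * gene_priors[nbr], s))
        if renormalize:
            total = sum(w for _, w, _ in updated)
            if total <= 0:
                raise CLAMError(f"prior annihilated all weights of {gene!r}")
            updated = [(nbr, w / total, s) for nbr, w, s in updated]
        neighbors[gene] = updated
    return NeighborhoodGraph(
        objects=list(graph.objects),
        neighbors=neighbors,
        k=graph.k,
        source=graph.source,
        dataset_counts=dict(graph.dataset_counts),
    )


def reweight_graph(
    graph: NeighborhoodGraph,
    db: InteractionDB,
    temperature: float = 1.0,
    include_pathways: bool = True,
    renormalize: bool = True,
) -> NeighborhoodGraph:
    """Full prior pass: score, softmax and reweight every gene's edges."""
    priors = {
        gene: prior_probabilities(
            coregulation_scores(
                gene, graph.neighbor_ids(gene), db, include_pathways=include_pathways
            ),
            temperature=temperature,
        )
        for gene in graph.objects
    }
    return apply_prior(graph, priors, renormalize=renormalize)
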