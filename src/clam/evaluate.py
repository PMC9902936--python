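"""Agreement metrics between observed and known module collections.

Four scores are computed. Relevance is the mean, over observed modules, of
the best Jaccard index against any known module; recovery swaps the roles.
Precision is a gene-pair score: for every gene ``g`` and every partner
``g'`` co-clustered with it in at least one observed module, the term

    min(|M'_g n M'_g'|, |M_g n M_g'|) * Phi(g, g') / |M'_g n M'_g'|

is averaged over partners and then over the gene universe, where
``M'_g`` / ``M_g`` are the observed / known modules containing ``g`` and
``Phi`` is the mean best-Jaccard of the observed modules containing both
genes against the known modules containing both. Recall swaps observed and
known. Conventions for the degenerate cases: when no known module contains
both genes, ``Phi = 0``; when no observed module contains both, the pair
contributes 0; a gene in no observed module has only itself as partner and
contributes 0.

Raw scores are normalised by the average score of ``B`` permuted versions
of the known modules (gene labels permuted over the union of known-module
genes, module sizes preserved), and the four normalised scores are summed
up by their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence

import numpy as np

from .containers import CLAMError, ModuleSet

__all__ = [
    "MetricsReport",
    "jaccard",
    "relevance",
    "recovery",
    "precision",
    "recall",
    "raw_metrics",
    "permute_modules",
    "normalize_scores",
    "overall_score",
    "crossvalidate",
]

METRIC_NAMES = ("precision", "recall", "relevance", "recovery")


@dataclass
class MetricsReport:
    """Raw, permutation-normalised and overall module-agreement scores."""

    raw: Dict[str, float]
    normalized: Dict[str, float] = field(default_factory=dict)
    overall: float = float("nan")
    B: int = 0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "raw": self.raw,
            "normalized": self.normalized,
            "overall": self.overall,
            "B": self.B,
            "seed": self.seed,
        }


def jaccard(a: FrozenSet[str], b: FrozenSet[str]) -> float:
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def relevance(observed: ModuleSet, known: ModuleSet) -> float:
    """Mean best Jaccard of each observed module against the known set."""
    if not observed.modules or not known.modules:
        raise CLAMError("relevance needs nonempty module sets on both sides")
    known_modules = list(known.modules.values())
    return float(
        np.mean(
            [
                max(jaccard(m_obs, m_known) for m_known in known_modules)
                for m_obs in observed.modules.values()
            ]
        )
    )


def recovery(observed: ModuleSet, known: ModuleSet) -> float:
    """Mean best Jaccard of each known module against the observed set."""
    return relevance(known, observed)


def _pair_agreement(
    primary: ModuleSet, reference: ModuleSet, universe: FrozenSet[str]
) -> float:
    """Gene-pair agreement with ``primary`` in the observed role.

    ``precision = _pair_agreement(observed, known, G)`` and recall swaps the
    two collections.
    """
    if not universe >= (primary.genes() | reference.genes()):
        raise CLAMError("universe must contain every module member")
    p_of: Dict[str, set] = {g: set() for g in universe}
    r_of: Dict[str, set] = {g: set() for g in universe}
    for name, members in primary.modules.items():
        for g in members:
            p_of[g].add(name)
    for name, members in reference.modules.items():
        for g in members:
            r_of[g].add(name)
    # partners co-clustered with g in >= 1 primary module, g included
    partners: Dict[str, set] = {g: {g} for g in universe}
    for members in primary.modules.values():
        for g in members:
            partners[g] |= members

    phi_cache: Dict[tuple, float] = {}

    def phi(p_both: frozenset, r_both: frozenset) -> float:
        # mean over primary modules containing both genes of the best
        # Jaccard against the reference modules containing both
        key = (p_both, r_both)
        if key not in phi_cache:
            if not r_both:
                phi_cache[key] = 0.0
            else:
                ref_sets = [reference.modules[m] for m in r_both]
                phi_cache[key] = float(
                    np.mean(
                        [
                            max(jaccard(primary.modules[m], r) for r in ref_sets)
                            for m in p_both
                        ]
                    )
                )
        return phi_cache[key]

    total = 0.0
    for g in universe:
        terms = []
        for g2 in partners[g]:
            p_both = frozenset(p_of[g] & p_of[g2])
            if not p_both:
                terms.append(0.0)
                continue
            r_both = frozenset(r_of[g] & r_of[g2])
            ratio = min(len(p_both), len(r_both)) / len(p_both)
            terms.append(ratio * phi(p_both, r_both))
        total += float(np.mean(terms))
    return total / len(universe)


def precision(
    observed: ModuleSet, known: ModuleSet, universe: FrozenSet[str]
) -> float:
    return _pair_agreement(observed, known, universe)


def recall(observed: ModuleSet, known: ModuleSet, universe: FrozenSet[str]) -> float:
    return _pair_agreement(known, observed, universe)


def raw_metrics(
    observed: ModuleSet, known: ModuleSet, universe: Optional[FrozenSet[str]] = None
) -> Dict[str, float]:
    if universe is None:
        universe = observed.genes() | known.genes()
    return {
        "precision": precision(observed, known, universe),
        "recall": recall(observed, known, universe),
        "relevance": relevance(observed, known),
        "recovery": recovery(observed, known),
    }


def permute_modules(known: ModuleSet, rng: np.random.Generator) -> ModuleSet:
    """Permute gene labels over the union of known-module genes.

    Module count and sizes are preserved; membership is rewired by a single
    random bijection of the gene universe onto itself.
    """
    pool = sorted(known.genes())
    mapping = dict(zip(pool, rng.permutation(pool)))
    return ModuleSet.from_dict(
        {
            name: {mapping[g] for g in members}
            for name, members in known.modules.items()
        }
    )


def normalize_scores(
    observed: ModuleSet,
    known: ModuleSet,
    universe: Optional[FrozenSet[str]] = None,
    B: int = 500,
    seed: int = 0,
) -> MetricsReport:
    """Normalise raw scores by the mean over ``B`` permuted known-module sets.

    A permuted baseline of exactly 0 makes the normalised score infinite;
    it is capped at ``inf`` and flagged through the value itself.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if universe is None:
        universe = observed.genes() | known.genes()
    raw = raw_metrics(observed, known, universe)
    rng = np.random.default_rng(seed)
    baseline = {name: [] for name in METRIC_NAMES}
    for _ in range(B):
        permuted = permute_modules(known, rng)
        scores = raw_metrics(observed, permuted, universe)
        for name in METRIC_NAMES:
            baseline[name].append(scores[name])
    normalized = {}
    for name in METRIC_NAMES:
        mean_b = float(np.mean(baseline[name]))
        normalized[name] = raw[name] / mean_b if mean_b > 0 else float("inf")
    return MetricsReport(
        raw=raw,
        normalized=normalized,
        overall=overall_score(normalized),
        B=B,
        seed=seed,
    )


def overall_score(normalized: Dict[str, float]) -> float:
    """Harmonic mean of the four normalised scores; 0 if any score is 0."""
    values = [normalized[name] for name in METRIC_NAMES]
    if any(v == 0 for v in values):
        return 0.0
    return len(values) / sum(1.0 / v for v in values)


def crossvalidate(
    known: ModuleSet,
    runner: Callable[[ModuleSet], ModuleSet],
    folds: int = 5,
    seed: int = 0,
    universe: Optional[FrozenSet[str]] = None,
    B: int = 0,
) -> tuple:
    """Module-level k-fold cross-validation harness.

    The known modules are partitioned into ``folds`` groups; for each fold
    the ``runner`` receives the training modules (e.g. to restrict the
    interaction prior) and its detected modules are scored against the
    held-out fold. Returns ``(per_fold_reports, mean_raw_scores)``.
    """
    names = sorted(known.modules)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(names) < folds:
        raise CLAMError(f"{len(names)} modules cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(names))
    fold_members: List[List[str]] = [order[i::folds] for i in range(folds)]
    reports = []
    for held_out in fold_members:
        train = ModuleSet.from_dict(
            {n: known.modules[n] for n in names if n not in held_out}
        )
        test = ModuleSet.from_dict({n: known.modules[n] for n in held_out})
        observed = runner(train)
        if B > 0:
            reports.append(
                normalize_scores(observed, test, universe=universe, B=B, seed=seed)
            )
        else:
            reports.append(MetricsReport(raw=raw_metrics(observed, test, universe)))
    mean_raw = {
        name: float(np.mean([r.raw[name] for r in reports])) for name in METRIC_NAMES
    }
    return reports, mean_raw
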