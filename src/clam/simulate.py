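"""Seeded synthetic multi-omics studies with planted co-expression modules.

Each planted module is driven by one latent factor per sample: member
gene ``g`` has profile ``s_g * (a_g * f + sqrt(1 - a_g^2) * eps)`` with an
independent noise draw per omics layer. The loadings ``a_g`` are drawn
uniformly from ``sqrt(rho) +- loading_spread`` (clipped below 1), so the
module has hub structure — some genes track the factor tightly, others
loosely — as real co-expression modules do, while the mean pairwise |r|
stays at ``E[a]^2 ~= rho``. A configurable fraction of members load
negatively (sign ``s = -1``) so the orientation step of the survival
analysis is exercised.
Background genes are independent noise. Layers share a configurable
fraction of genes and samples. The interaction network contains one
module-specific TF covering a configurable fraction of each module's genes
plus random decoy edges. Survival times are exponential with log-hazard
proportional to the per-patient co-expression SD of one designated causal
module, with independent exponential censoring, so the survival signal the
screen looks for exists by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import CLAMError, ExpressionMatrix, InteractionDB, ModuleSet
from .evaluate import recovery, relevance

__all__ = ["SimulationConfig", "SimulatedStudy", "generate", "truth_comparison"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference scenario used throughout the tests:
    two omics layers over 50 samples each, five planted modules of 20
    genes on a background of 200 independent genes, within-module
    correlation 0.8 and a TF covering half of each module's genes.
    """

    n_modules: int = 5
    module_size: Tuple[int, int] = (20, 20)
    n_background: int = 200
    n_samples: int = 50
    n_datasets: int = 2
    gene_overlap: float = 0.6
    sample_overlap: float = 0.5
    rho_within: float = 0.8
    loading_spread: float = 0.15
    noise_sd: float = 1.0
    negative_fraction: float = 0.25
    interaction_fidelity: float = 0.5
    decoy_rate: float = 0.1
    baseline_hazard: float = 0.1
    survival_effect: float = 1.5
    censoring_rate: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "gene_overlap",
            "sample_overlap",
            "interaction_fidelity",
            "censoring_rate",
            "missing_rate",
            "negative_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise CLAMError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.rho_within < 1.0:
            raise CLAMError("rho_within must lie in (0, 1)")
        for name in ("n_modules", "n_background", "n_samples", "n_datasets"):
            if getattr(self, name) < 1:
                raise CLAMError(f"{name} must be >= 1")
        if self.module_size[0] < 2 or self.module_size[0] > self.module_size[1]:
            raise CLAMError("module_size must be a (low, high) range with low >= 2")


@dataclass
class SimulatedStudy:
    """Everything one run of the generator produces."""

    datasets: List[ExpressionMatrix]
    interactions: InteractionDB
    truth: ModuleSet
    clinical: pd.DataFrame
    causal_module: str
    true_signs: Dict[str, float]
    config: SimulationConfig


def _sample_names(config: SimulationConfig, rng: np.random.Generator):
    """Per-dataset sample lists sharing ``sample_overlap`` of each list."""
    n_shared = int(round(config.sample_overlap * config.n_samples))
    shared = [f"s_shared_{i:03d}" for i in range(n_shared)]
    per_dataset = []
    for d in range(config.n_datasets):
        unique = [
            f"s_d{d}_{i:03d}" for i in range(config.n_samples - n_shared)
        ]
        per_dataset.append(shared + unique)
    return per_dataset


def generate(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic study; byte-identical given the same config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = [
        int(rng.integers(config.module_size[0], config.module_size[1] + 1))
        for _ in range(config.n_modules)
    ]
    module_names = [f"true_{m + 1}" for m in range(config.n_modules)]
    genes: List[str] = []
    gene_module: Dict[str, int] = {}
    for m, size in enumerate(sizes):
        for j in range(size):
            g = f"g_m{m + 1}_{j:03d}"
            genes.append(g)
            gene_module[g] = m
    for j in range(config.n_background):
        g = f"g_bg_{j:04d}"
        genes.append(g)
        gene_module[g] = -1

    # layer membership: shared genes appear in every layer, the rest in one
    gene_layers: Dict[str, List[int]] = {}
    for g in genes:
        if rng.random() < config.gene_overlap or config.n_datasets == 1:
            gene_layers[g] = list(range(config.n_datasets))
        else:
            gene_layers[g] = [int(rng.integers(config.n_datasets))]

    sample_lists = _sample_names(config, rng)
    all_samples = sorted({s for lst in sample_lists for s in lst})
    sample_pos = {s: i for i, s in enumerate(all_samples)}
    factors = rng.standard_normal((config.n_modules, len(all_samples)))

    signs = {
        g: (-1.0 if (gene_module[g] >= 0 and rng.random() < config.negative_fraction) else 1.0)
        for g in genes
    }

    root_rho = np.sqrt(config.rho_within)
    loadings = {
        g: float(
            np.clip(
                rng.uniform(
                    root_rho - config.loading_spread,
                    root_rho + config.loading_spread,
                ),
                0.05,
                0.999,
            )
        )
        for g in genes
        if gene_module[g] >= 0
    }
    datasets = []
    for d in range(config.n_datasets):
        samples = sample_lists[d]
        cols = [sample_pos[s] for s in samples]
        layer_genes = [g for g in genes if d in gene_layers[g]]
        values = np.empty((len(layer_genes), len(samples)))
        for i, g in enumerate(layer_genes):
            noise = rng.standard_normal(len(samples))
            m = gene_module[g]
            if m >= 0:
                a = loadings[g]
                base = a * factors[m, cols] + np.sqrt(1.0 - a * a) * noise
                values[i] = signs[g] * config.noise_sd * base
            else:
                values[i] = config.noise_sd * noise
        frame = pd.DataFrame(values, index=layer_genes, columns=samples)
        if config.missing_rate > 0:
            mask = rng.random(frame.shape) < config.missing_rate
            frame = frame.mask(mask)
        datasets.append(ExpressionMatrix(frame, dataset_id=f"omics_{d + 1}"))

    # interactions: one TF per module covering interaction_fidelity of its
    # genes, plus decoy TF edges to random genes
    tf_edges = []
    for m, name in enumerate(module_names):
        members = [g for g in genes if gene_module[g] == m]
        n_cover = int(round(config.interaction_fidelity * len(members)))
        covered = list(rng.choice(members, size=n_cover, replace=False)) if n_cover else []
        for g in covered:
            tf_edges.append((f"TF_{name}", g))
    n_decoys = int(round(config.decoy_rate * max(len(tf_edges), config.n_modules * 10)))
    for j in range(n_decoys):
        target = genes[int(rng.integers(len(genes)))]
        tf_edges.append((f"TF_decoy_{j:03d}", target))
    interactions = InteractionDB.from_edges(tf_edges=tf_edges)

    truth = ModuleSet.from_dict(
        {
            name: {g for g in genes if gene_module[g] == m}
            for m, name in enumerate(module_names)
        },
        outliers={g for g in genes if gene_module[g] == -1},
    )

    # survival: hazard tied to the per-patient co-expression SD of the
    # causal module, computed from its true aligned factors in layer 0
    causal = module_names[0]
    layer0 = datasets[0]
    causal_genes = [g for g in truth.modules[causal] if g in layer0.data.index]
    patients = layer0.samples
    block = layer0.data.loc[causal_genes, patients]
    if config.missing_rate > 0:
        block = block.fillna(block.mean(axis=1).mean())
    z = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=0), axis=0)
    aligned = z.mul(pd.Series({g: signs[g] for g in causal_genes}), axis=0)
    sigma = aligned.std(axis=0, ddof=0)
    sigma_z = (sigma - sigma.mean()) / sigma.std(ddof=0)
    hazard = config.baseline_hazard * np.exp(config.survival_effect * sigma_z.to_numpy())
    event_times = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_rate = config.baseline_hazard * config.censoring_rate / (
            1.0 - config.censoring_rate
        )
        censor_times = rng.exponential(1.0 / censor_rate, size=len(patients))
    else:
        censor_times = np.full(len(patients), np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    clinical = pd.DataFrame(
        {"sample_id": patients, "time": observed, "event": event}
    )

    return SimulatedStudy(
        datasets=datasets,
        interactions=interactions,
        truth=truth,
        clinical=clinical,
        causal_module=causal,
        true_signs=signs,
        config=config,
    )


def truth_comparison(detected: ModuleSet, truth: ModuleSet) -> Dict[str, float]:
    """ARI plus relevance/recovery of a detected module set against truth.

    Hard labels with outliers as one extra class; genes missing from either
    side's assignment are treated as outliers for the ARI.
    """
    if not detected.modules or not truth.modules:
        raise CLAMError("truth comparison needs nonempty module sets")
    universe = sorted(detected.all_genes() | truth.all_genes())
    det = detected.labels().reindex(universe).fillna("<outlier>")
    tru = truth.labels().reindex(universe).fillna("<outlier>")
    return {
        "ari": float(adjusted_rand_score(tru, det)),
        "relevance": relevance(detected, truth),
        "recovery": recovery(detected, truth),
    }
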