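"""Model/Results surface over the module-detection pipeline.

``CLAM`` holds the data and hyper-parameters; ``fit()`` executes the
pipeline (preprocess -> per-dataset KNN -> fusion -> co-regulatory prior ->
density roles -> membership iteration -> hard assignment) and returns a
:class:`CLAMResults` carrying the modules together with every intermediate
quantity a user may want to inspect: membership vectors, densities, roles,
the objective path and the fused graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .containers import ExpressionMatrix, InteractionDB, ModuleSet
from .cluster import DensityTable, MembershipState, run_clam
from .graph import NeighborhoodGraph
from . import io as _io

__all__ = ["CLAM", "CLAMResults"]


class CLAM:
    """Trans-omics co-expression module detection model.

    Parameters
    ----------
    datasets
        One or more expression layers (genes x samples); gene and sample
        sets may differ between layers.
    interactions
        Known molecular interactions used for the co-regulatory prior;
        ``None`` (or an empty database) disables the prior.
    k
        Neighbor count per dataset (default 10).
    measure
        Similarity measure: ``"pearson"`` (default), ``"euclidean"`` or
        ``"mutual_information"``.
    absolute_corr
        Under Pearson, use |r| so anti-correlated genes are neighbors.
    use_prior, prior_temperature, include_pathways, renormalize_prior
        Prior-stage switches; see :mod:`clam.prior`.
    merge_identifiers
        Merge identical gene ids across layers into one object (default);
        otherwise ids are namespaced ``<gene>@<dataset>``.
    """

    def __init__(
        self,
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
    ) -> None:
        self.datasets = list(datasets)
        self.interactions = interactions
        self.k = k
        self.measure = measure
        self.absolute_corr = absolute_corr
        self.use_prior = use_prior
        self.prior_temperature = prior_temperature
        self.include_pathways = include_pathways
        self.renormalize_prior = renormalize_prior
        self.merge_identifiers = merge_identifiers
        self.max_missing_fraction = max_missing_fraction
        self.impute_k = impute_k
        self.tol = tol
        self.max_iter = max_iter
        self.min_module_size = min_module_size
        self.outlier_threshold = outlier_threshold

    @classmethod
    def from_files(cls, expression_paths: Sequence[str], **kwargs) -> "CLAM":
        datasets = [_io.read_expression(p) for p in expression_paths]
        return cls(datasets, **kwargs)

    def fit(self) -> "CLAMResults":
        modules, state, table, graph = run_clam(
            self.datasets,
            self.interactions,
            k=self.k,
            measure=self.measure,
            absolute_corr=self.absolute_corr,
            use_prior=self.use_prior,
            prior_temperature=self.prior_temperature,
            include_pathways=self.include_pathways,
            renormalize_prior=self.renormalize_prior,
            merge_identifiers=self.merge_identifiers,
            max_missing_fraction=self.max_missing_fraction,
            impute_k=self.impute_k,
            tol=self.tol,
            max_iter=self.max_iter,
            min_module_size=self.min_module_size,
            outlier_threshold=self.outlier_threshold,
            return_state=True,
        )
        return CLAMResults(self, modules, state, table, graph)


@dataclass
class CLAMResults:
    """Fitted module structure plus diagnostics."""

    model: CLAM
    modules: ModuleSet
    state: MembershipState
    density_table: DensityTable
    graph: NeighborhoodGraph

    @property
    def membership(self) -> pd.DataFrame:
        """Converged membership vectors, genes x (M + 1)."""
        return self.state.membership

    @property
    def objective_path(self) -> list:
        """Objective E per sweep (squared residual of the approximation)."""
        return self.state.objective_path

    @property
    def n_iter(self) -> int:
        return self.state.n_iter

    @property
    def converged(self) -> bool:
        return self.state.converged

    @property
    def centers(self) -> list:
        return self.state.centers

    @property
    def outlier_genes(self) -> frozenset:
        return self.modules.outliers

    def per_gene_table(self) -> pd.DataFrame:
        """Gene-level table: module, role, density and membership scores."""
        labels = self.modules.labels()
        table = pd.DataFrame(
            {
                "module": labels,
                "role": self.density_table.roles,
                "density": self.density_table.density,
            }
        )
        return table.join(self.state.membership)

    def summary(self) -> str:
        sizes = self.modules.sizes()
        lines = [
            "CLAM module detection results",
            "=" * 46,
            f"datasets:          {len(self.model.datasets)}"
            f" ({', '.join(d.dataset_id for d in self.model.datasets)})",
            f"objects clustered: {len(self.state.membership)}",
            f"k (per dataset):   {self.model.k}",
            f"similarity:        {self.model.measure}"
            + (" (|r|)" if self.model.measure == "pearson" and self.model.absolute_corr else ""),
            f"prior:             {'on' if self.model.use_prior and self.model.interactions is not None and not self.model.interactions.is_empty() else 'off'}",
            f"cluster centers:   {len(self.centers)}",
            f"modules found:     {len(self.modules)}",
            f"outlier genes:     {len(self.modules.outliers)}",
            f"iterations:        {self.n_iter} "
            + ("(converged)" if self.converged else "(NOT converged)"),
            f"final objective E: {self.objective_path[-1]:.6g}",
            "-" * 46,
            "module sizes:",
        ]
        for name, size in sizes.items():
            lines.append(f"  {name:<14s} {size:>5d}")
        return "\n".join(lines)

    def save(self, gmt_path, table_path=None) -> None:
        _io.write_gene_sets(self.modules, gmt_path)
        if table_path is not None:
            self.per_gene_table().to_csv(
                table_path, sep="\t", index_label="gene", float_format="%.10g"
            )
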