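"""Shared in-memory containers for expression data, interactions and modules.

Expression data are carried as a genes x samples :class:`pandas.DataFrame`
tagged with the identity of the omics layer it came from; interaction
resources are plain adjacency maps; module collections are named gene sets
with an explicit outlier slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "InteractionDB", "ModuleSet", "CLAMError", "FormatError"]


class CLAMError(Exception):
    """Base class for errors raised by this package."""


class FormatError(CLAMError):
    """A file did not conform to the expected tabular format."""


@dataclass
class ExpressionMatrix:
    """One omics layer: real-valued expression of genes across samples.

    Parameters
    ----------
    data
        Genes x samples frame; ``NaN`` marks a missing measurement.
    dataset_id
        Short identifier of the omics layer (e.g. ``"rna"``, ``"protein"``).
    """

    data: pd.DataFrame
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError(
                f"duplicate gene identifiers in dataset {self.dataset_id!r}"
            )
        if self.data.columns.has_duplicates:
            raise FormatError(
                f"duplicate sample identifiers in dataset {self.dataset_id!r}"
            )

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def namespaced(self) -> "ExpressionMatrix":
        """Rename every gene to ``<gene>@<dataset_id>``.

        Used when identical identifiers measured on different omics layers
        must be kept as distinct clustering objects.
        """
        renamed = self.data.copy()
        renamed.index = [f"{g}@{self.dataset_id}" for g in renamed.index]
        return ExpressionMatrix(renamed, dataset_id=self.dataset_id)


def _symmetrize(edges: Iterable[tuple]) -> Dict[str, set]:
    adj: Dict[str, set] = {}
    for a, b in edges:
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


@dataclass
class InteractionDB:
    """Known molecular interactions used to build the co-regulatory prior.

    ``tf_targets`` and ``mirna_targets`` map a regulator to its target genes;
    ``ppi`` is a symmetric adjacency map of protein-protein interaction
    partners (no self edges); ``pathways`` maps a pathway id to its member
    gene set.
    """

    tf_targets: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    mirna_targets: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    ppi: Dict[str, set] = field(default_factory=dict)
    pathways: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        tf_edges: Iterable[tuple] = (),
        mirna_edges: Iterable[tuple] = (),
        ppi_edges: Iterable[tuple] = (),
        pathways: Mapping[str, Iterable[str]] | None = None,
    ) -> "InteractionDB":
        tf: Dict[str, set] = {}
        for reg, target in tf_edges:
            tf.setdefault(reg, set()).add(target)
        mirna: Dict[str, set] = {}
        for reg, target in mirna_edges:
            mirna.setdefault(reg, set()).add(target)
        return cls(
            tf_targets={r: frozenset(t) for r, t in tf.items()},
            mirna_targets={r: frozenset(t) for r, t in mirna.items()},
            ppi=_symmetrize(ppi_edges),
            pathways={p: frozenset(g) for p, g in (pathways or {}).items()},
        )

    def ppi_partners(self, gene: str) -> set:
        return self.ppi.get(gene, set())

    def regulators_of(self, gene: str, kind: str) -> set:
        """Regulators (of ``kind`` 'tf' or 'mirna') that target ``gene``."""
        table = self.tf_targets if kind == "tf" else self.mirna_targets
        return {reg for reg, targets in table.items() if gene in targets}

    def is_empty(self) -> bool:
        return not (self.tf_targets or self.mirna_targets or self.ppi or self.pathways)


@dataclass
class ModuleSet:
    """A collection of named gene modules plus an outlier gene set.

    Each gene belongs to exactly one module or to the outlier set when the
    collection comes from a hard clustering; collections of known modules
    (e.g. TF target sets) may overlap freely.
    """

    modules: Dict[str, FrozenSet[str]]
    outliers: FrozenSet[str] = frozenset()

    @classmethod
    def from_dict(
        cls, modules: Mapping[str, Iterable[str]], outliers: Iterable[str] = ()
    ) -> "ModuleSet":
        return cls(
            modules={name: frozenset(members) for name, members in modules.items()},
            outliers=frozenset(outliers),
        )

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules.items())

    def genes(self) -> FrozenSet[str]:
        """Union of all module members (outliers excluded)."""
        out: set = set()
        for members in self.modules.values():
            out |= members
        return frozenset(out)

    def all_genes(self) -> FrozenSet[str]:
        return self.genes() | self.outliers

    def labels(self) -> pd.Series:
        """Hard labels: module name per gene, ``"<outlier>"`` for outliers.

        Only meaningful for partitions (hard clusterings).
        """
        lab = {}
        for name, members in self.modules.items():
            for g in members:
                lab[g] = name
        for g in self.outliers:
            lab[g] = "<outlier>"
        return pd.Series(lab).sort_index()

    def sizes(self) -> pd.Series:
        return pd.Series({n: len(m) for n, m in self.modules.items()}).sort_index()
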