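"""Readers, writers and preprocessing for the package's tabular formats.

Expression matrices are genes-in-rows TSV with a header row of sample ids;
gene sets use the GMT convention (name, description, tab-separated members);
interaction resources are two-column edge lists; clinical tables carry
``sample_id``, ``time`` and ``event`` columns.

Preprocessing follows the standard recipe for merged omics tables: genes
with more than a fixed fraction of missing values are dropped, and the
remaining gaps are filled by KNN imputation over the gene axis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import CLAMError, ExpressionMatrix, FormatError, InteractionDB, ModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "filter_missing",
    "impute_knn",
    "preprocess",
    "read_gene_sets",
    "write_gene_sets",
    "read_interactions",
    "read_clinical",
    "write_clinical",
    "ImputationError",
]

#: Accepted spellings of a missing value in TSV cells (case-insensitive).
MISSING_MARKERS = ("", "na", "nan", "null")


class ImputationError(CLAMError):
    """KNN imputation could not fill every gap."""


def _na_values() -> list:
    out = []
    for marker in MISSING_MARKERS:
        out.extend({marker, marker.upper(), marker.capitalize(), marker.lower()})
    return sorted(set(out))


def read_expression(path, dataset_id: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    The first column holds gene identifiers, the header row sample
    identifiers. Empty cells and "NA"/"NaN"/"null" (any case) are missing.
    Duplicate gene rows are collapsed by their mean; duplicate sample ids
    are an error.
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"duplicate sample ids in {path}: {dupes}")
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_na_values(),
            keep_default_na=False,
            dtype=str,
        )
    except Exception as exc:  # malformed TSV structure
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    frame.index.name = None
    frame.columns.name = None
    try:
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from exc
    if frame.index.has_duplicates:
        # collapse duplicate gene rows by mean, keeping first-seen order
        order = frame.index.drop_duplicates()
        frame = frame.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(frame, dataset_id=dataset_id or path.stem)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def filter_missing(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.20
) -> ExpressionMatrix:
    """Drop genes whose missing fraction strictly exceeds the threshold.

    A gene with exactly ``max_missing_fraction`` missing values is kept;
    removal requires *more* than the threshold. Idempotent.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = matrix.data.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise CLAMError(
            f"all genes exceed the {max_missing_fraction:.0%} missing-value "
            f"threshold in dataset {matrix.dataset_id!r}"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_missing[%s]: dropped %d of %d genes (> %.0f%% missing)",
            matrix.dataset_id,
            n_dropped,
            len(keep),
            100 * max_missing_fraction,
        )
    return ExpressionMatrix(matrix.data.loc[keep], dataset_id=matrix.dataset_id)


def impute_knn(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries by distance-weighted KNN over the gene axis.

    For each gene with a gap, the ``k`` genes nearest by Euclidean distance
    over co-observed samples (rescaled by sqrt of the observed fraction)
    that carry a value in the gapped sample donate a 1/distance-weighted
    mean. Genes with no co-observed samples against any other gene cannot
    be imputed and raise :class:`ImputationError`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.n_missing() == 0:
        return matrix
    values = matrix.values
    observed = ~np.isnan(values)
    # any gene with a gap must co-observe >= 1 sample with some other gene
    gapped = np.where(~observed.all(axis=1))[0]
    co_counts = observed.astype(int) @ observed.astype(int).T
    np.fill_diagonal(co_counts, 0)
    for i in gapped:
        if co_counts[i].max() == 0:
            raise ImputationError(
                f"gene {matrix.genes[i]!r} shares no observed sample with any other gene"
            )
    imputer = KNNImputer(
        n_neighbors=min(k, len(matrix.genes) - 1), weights="distance"
    )
    filled = imputer.fit_transform(values)
    if filled.shape != values.shape or np.isnan(filled).any():
        raise ImputationError("imputation left missing entries behind")
    frame = pd.DataFrame(filled, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, dataset_id=matrix.dataset_id)


def preprocess(
    matrix: ExpressionMatrix,
    max_missing_fraction: float = 0.20,
    k: int = 10,
) -> ExpressionMatrix:
    """Missing-value filter followed by KNN imputation."""
    return impute_knn(filter_missing(matrix, max_missing_fraction), k=k)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> ModuleSet:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    modules = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in modules:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            modules[name] = members
    return ModuleSet(modules=modules)


def write_gene_sets(modules: ModuleSet, path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name in sorted(modules.modules):
            members = "\t".join(sorted(modules.modules[name]))
            handle.write(f"{name}\t{description}\t{members}\n")
        if modules.outliers:
            members = "\t".join(sorted(modules.outliers))
            handle.write(f"<outlier>\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------


def _read_edges(path, label: str) -> list:
    """Tolerant two-column TSV edge reader; malformed lines are skipped."""
    edges = []
    skipped = 0
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                skipped += 1
                continue
            edges.append((fields[0], fields[1]))
    if skipped:
        logger.warning("%s: skipped %d malformed lines in %s", label, skipped, path)
    return edges


def read_interactions(
    tf_path=None, mirna_path=None, ppi_path=None, pathway_path=None
) -> InteractionDB:
    """Assemble an :class:`InteractionDB` from any subset of edge resources.

    PPI edges are symmetrized and self edges dropped; absent resources
    yield empty maps.
    """
    tf_edges = _read_edges(tf_path, "tf") if tf_path else ()
    mirna_edges = _read_edges(mirna_path, "mirna") if mirna_path else ()
    ppi_edges = _read_edges(ppi_path, "ppi") if ppi_path else ()
    pathways = (
        {name: members for name, members in read_gene_sets(pathway_path).modules.items()}
        if pathway_path
        else None
    )
    return InteractionDB.from_edges(tf_edges, mirna_edges, ppi_edges, pathways)


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------


def read_clinical(path) -> pd.DataFrame:
    """Read a survival table with columns ``sample_id``, ``time``, ``event``."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"clinical table {path} must have columns {sorted(required)}"
        )
    if table["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample ids in clinical table {path}")
    if (table["time"] < 0).any():
        raise FormatError(f"negative survival time in clinical table {path}")
    if not table["event"].isin([0, 1]).all():
        raise FormatError(f"event column of {path} must be 0/1")
    return table[["sample_id", "time", "event"]].reset_index(drop=True)


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
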