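"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .containers import CLAMError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run.

    Serializable to/from a single YAML file; unknown keys are rejected so a
    typo cannot silently fall back to a default.
    """

    # neighborhood
    k: int = 10
    measure: str = "pearson"
    absolute_corr: bool = True
    # prior
    prior_enabled: bool = True
    prior_temperature: float = 1.0
    prior_include_pathways: bool = True
    prior_renormalize: bool = True
    # io / preprocessing
    merge_identifiers: bool = True
    max_missing_fraction: float = 0.20
    impute_k: Optional[int] = None
    # clustering
    tol: float = 1e-6
    max_iter: int = 500
    min_module_size: Optional[int] = None
    outlier_threshold: object = "mean"
    # evaluation
    permutations: int = 500
    folds: int = 5
    # survival
    survival_mode: str = "sd"
    alpha: float = 0.05
    # global
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise CLAMError("k must be >= 1")
        if self.measure not in ("pearson", "euclidean", "mutual_information"):
            raise CLAMError(f"unknown similarity measure {self.measure!r}")
        if self.survival_mode not in ("sd", "mean", "single_gene"):
            raise CLAMError(f"unknown survival mode {self.survival_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CLAMError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def clam_kwargs(self) -> dict:
        return dict(
            k=self.k,
            measure=self.measure,
            absolute_corr=self.absolute_corr,
            use_prior=self.prior_enabled,
            prior_temperature=self.prior_temperature,
            include_pathways=self.prior_include_pathways,
            renormalize_prior=self.prior_renormalize,
            merge_identifiers=self.merge_identifiers,
            max_missing_fraction=self.max_missing_fraction,
            impute_k=self.impute_k,
            tol=self.tol,
            max_iter=self.max_iter,
            min_module_size=self.min_module_size,
            outlier_threshold=self.outlier_threshold,
        )
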