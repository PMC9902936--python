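"""Module-based survival analysis.

For each module the member genes are z-scored across patients, sign-aligned
so that every gene correlates non-negatively with the module consensus, and
the per-patient standard deviation sigma_i of the aligned z-scores is taken
as the statistic: low sigma means the module's genes are tightly
co-expressed in that patient, high sigma means the co-expression is lost.
Patients are split at the median of the statistic (ties go to the
"<= median" group) and the two survival curves are compared with the
log-rank test. Two comparison modes accompany the sigma statistic: the
per-patient mean of the aligned z-scores, and the expression of a single
reference gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from statsmodels.stats.multitest import multipletests

from .containers import CLAMError, ExpressionMatrix, ModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleSurvivalResult",
    "ModuleSurvival",
    "orient_genes",
    "coexpression_sd",
    "logrank_split",
    "survival_screen",
]

MODES = ("sd", "mean", "single_gene")


@dataclass
class ModuleSurvivalResult:
    """Outcome of one module's survival split in one mode."""

    module: str
    mode: str
    statistic: pd.Series  # per-patient value used for the split
    groups: pd.Series  # "high" (> median) / "low" (<= median) per patient
    chi_square: float
    p_value: float
    group_sizes: Dict[str, int]
    signs: pd.Series = field(default_factory=pd.Series)
    degenerate: bool = False

    def km_coordinates(self, clinical: pd.Series | pd.DataFrame) -> Dict[str, pd.DataFrame]:
        """Kaplan-Meier curve coordinates (time, survival) per group."""
        clin = _indexed_clinical(clinical)
        out = {}
        for label in ("low", "high"):
            idx = self.groups.index[self.groups == label]
            if len(idx) == 0:
                continue
            km = KaplanMeierFitter()
            km.fit(clin.loc[idx, "time"], clin.loc[idx, "event"], label=label)
            frame = km.survival_function_.reset_index()
            frame.columns = ["time", "survival"]
            out[label] = frame
        return out


def _indexed_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" in clinical.columns:
        return clinical.set_index("sample_id")[["time", "event"]]
    return clinical[["time", "event"]]


def orient_genes(expression: pd.DataFrame) -> pd.Series:
    """Choose a sign per gene so all genes track the module consensus.

    ``expression`` is the module's genes x samples block. The gene with the
    largest summed absolute correlation to the others is the reference
    (+1, ties by lexicographic gene id); every other gene takes the sign of
    its correlation with the reference (zero correlation keeps +1).
    Zero-variance genes must be removed beforehand.
    """
    if expression.shape[0] < 2:
        raise CLAMError("orientation needs at least 2 genes")
    if expression.shape[1] < 3:
        raise CLAMError("orientation needs at least 3 shared samples")
    corr = expression.T.corr()
    strength = corr.abs().sum(axis=1) - 1.0  # drop the self term
    best = strength.max()
    reference = sorted(strength.index[strength == best])[0]
    signs = np.where(corr[reference] >= 0, 1.0, -1.0)
    return pd.Series(signs, index=corr.index)


def _aligned_zscores(
    module_genes: List[str], expression: ExpressionMatrix | pd.DataFrame
) -> tuple:
    """Z-score (population sd) each module gene and apply orientation signs.

    Returns ``(aligned genes x samples frame, signs)``; zero-variance genes
    are dropped with a log message.
    """
    frame = expression.data if isinstance(expression, ExpressionMatrix) else expression
    present = [g for g in module_genes if g in frame.index]
    missing = set(module_genes) - set(present)
    if missing:
        logger.info("survival: %d module genes not in expression", len(missing))
    block = frame.loc[present]
    sd = block.std(axis=1, ddof=0)
    flat = sd.index[sd == 0].tolist()
    if flat:
        logger.warning("survival: dropping zero-variance genes %s", flat)
        block = block.drop(index=flat)
        sd = sd.drop(index=flat)
    if block.shape[0] < 2:
        raise CLAMError("module reduced below 2 usable genes")
    z = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)
    signs = orient_genes(z)
    aligned = z.mul(signs, axis=0)
    return aligned, signs


def coexpression_sd(
    module_genes: List[str],
    expression: ExpressionMatrix | pd.DataFrame,
    clinical: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Per-patient standard deviation of the sign-aligned z-scores.

    Population (n) denominators are used both for the z-scores and for the
    per-patient spread across module genes. When a clinical table is given
    the samples are first intersected with it.
    """
    aligned, _ = _aligned_zscores(module_genes, expression)
    if clinical is not None:
        clin = _indexed_clinical(clinical)
        shared = [s for s in aligned.columns if s in clin.index]
        dropped = aligned.shape[1] - len(shared)
        if dropped:
            logger.info("survival: dropped %d samples without clinical data", dropped)
        aligned = aligned[shared]
    return aligned.std(axis=0, ddof=0)


def logrank_split(
    statistic: pd.Series,
    clinical: pd.DataFrame,
    mode: str = "sd",
    module: str = "module",
    signs: Optional[pd.Series] = None,
) -> ModuleSurvivalResult:
    """Median split of the per-patient statistic plus two-group log-rank test.

    Patients with statistic strictly greater than the median form the
    "high" group, the rest (ties included) the "low" group. A constant
    statistic leaves one group empty; the result is flagged degenerate with
    p = 1.
    """
    clin = _indexed_clinical(clinical)
    shared = [s for s in statistic.index if s in clin.index]
    stat = statistic.loc[shared]
    if len(stat) < 4:
        raise CLAMError("need at least 4 patients with clinical data")
    median = float(np.median(stat))
    groups = pd.Series(
        np.where(stat > median, "high", "low"), index=stat.index
    )
    sizes = {"high": int((groups == "high").sum()), "low": int((groups == "low").sum())}
    if min(sizes.values()) == 0:
        logger.warning("survival[%s/%s]: constant statistic, degenerate split", module, mode)
        return ModuleSurvivalResult(
            module=module,
            mode=mode,
            statistic=stat,
            groups=groups,
            chi_square=0.0,
            p_value=1.0,
            group_sizes=sizes,
            signs=signs if signs is not None else pd.Series(dtype=float),
            degenerate=True,
        )
    high = groups == "high"
    test = _lifelines_logrank(
        clin.loc[stat.index[high], "time"],
        clin.loc[stat.index[~high], "time"],
        event_observed_A=clin.loc[stat.index[high], "event"],
        event_observed_B=clin.loc[stat.index[~high], "event"],
    )
    return ModuleSurvivalResult(
        module=module,
        mode=mode,
        statistic=stat,
        groups=groups,
        chi_square=float(test.test_statistic),
        p_value=float(test.p_value),
        group_sizes=sizes,
        signs=signs if signs is not None else pd.Series(dtype=float),
    )


def _module_statistic(
    module_genes: List[str],
    expression: ExpressionMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
    mode: str,
) -> tuple:
    aligned, signs = _aligned_zscores(module_genes, expression)
    clin = _indexed_clinical(clinical)
    shared = [s for s in aligned.columns if s in clin.index]
    aligned = aligned[shared]
    if mode == "sd":
        return aligned.std(axis=0, ddof=0), signs
    if mode == "mean":
        return aligned.mean(axis=0), signs
    if mode == "single_gene":
        # use the orientation reference gene's raw expression (Fig.-4A-style
        # single-gene comparison); it is the gene with the largest summed
        # absolute correlation to the rest of the module
        frame = expression.data if isinstance(expression, ExpressionMatrix) else expression
        strength = aligned.T.corr().abs().sum(axis=1)
        reference = sorted(strength.index[strength == strength.max()])[0]
        return frame.loc[reference, shared], signs
    raise ValueError(f"unknown survival mode {mode!r}")


def survival_screen(
    modules: ModuleSet,
    expression: ExpressionMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
    modes: tuple = MODES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the median-split log-rank test for every module and mode.

    Returns a table ranked by p-value within each mode, with
    Benjamini-Hochberg adjusted p-values reported alongside the raw ones.
    Individual results (with per-patient statistics and KM coordinates)
    are attached in the ``result`` column.
    """
    records = []
    for mode in modes:
        for name in sorted(modules.modules):
            genes = sorted(modules.modules[name])
            try:
                stat, signs = _module_statistic(genes, expression, clinical, mode)
                result = logrank_split(stat, clinical, mode=mode, module=name, signs=signs)
            except CLAMError as exc:
                logger.warning("survival[%s/%s]: skipped (%s)", name, mode, exc)
                continue
            records.append(result)
    if not records:
        return pd.DataFrame(
            columns=["module", "mode", "chi_square", "p", "p_adj", "n_high", "n_low", "significant", "result"]
        )
    table = pd.DataFrame(
        {
            "module": [r.module for r in records],
            "mode": [r.mode for r in records],
            "chi_square": [r.chi_square for r in records],
            "p": [r.p_value for r in records],
            "n_high": [r.group_sizes["high"] for r in records],
            "n_low": [r.group_sizes["low"] for r in records],
            "result": records,
        }
    )
    adjusted = []
    for mode in table["mode"].unique():
        mask = table["mode"] == mode
        adjusted.append(
            pd.Series(
                multipletests(table.loc[mask, "p"], method="fdr_bh")[1],
                index=table.index[mask],
            )
        )
    table["p_adj"] = pd.concat(adjusted)
    table["significant"] = table["p_adj"] < alpha
    table = table.sort_values(["mode", "p"], kind="stable").reset_index(drop=True)
    return table[
        ["module", "mode", "chi_square", "p", "p_adj", "n_high", "n_low", "significant", "result"]
    ]


class ModuleSurvival:
    """Model object for the module-based survival screen.

    Parameters mirror :func:`survival_screen`; ``fit`` returns the ranked
    results table wrapped with a ``summary()``.
    """

    def __init__(
        self,
        modules: ModuleSet,
        expression: ExpressionMatrix | pd.DataFrame,
        clinical: pd.DataFrame,
        alpha: float = 0.05,
    ) -> None:
        self.modules = modules
        self.expression = expression
        self.clinical = clinical
        self.alpha = alpha

    def fit(self, modes: tuple = MODES) -> "ModuleSurvivalResults":
        table = survival_screen(
            self.modules, self.expression, self.clinical, modes=modes, alpha=self.alpha
        )
        return ModuleSurvivalResults(self, table)


@dataclass
class ModuleSurvivalResults:
    model: ModuleSurvival
    table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Module-based survival screen",
            "=" * 58,
            f"modules tested: {len(self.model.modules)}   alpha = {self.model.alpha}",
            f"{'module':<14s}{'mode':<13s}{'chi2':>8s}{'p':>10s}{'p_adj':>10s}",
            "-" * 58,
        ]
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['module']:<14s}{row['mode']:<13s}"
                f"{row['chi_square']:>8.3f}{row['p']:>10.2g}{row['p_adj']:>10.2g}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        self.table.drop(columns=["result"]).to_csv(path, sep="\t", index=False)
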