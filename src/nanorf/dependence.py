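"""Knockout dependence features.

A protein's *dependence* on a knocked-out factor is its averaged
knockout/wild-type chromosomal abundance ratio across that condition's
biological replicates, on the log2 scale: negative values mean the protein is
depleted from mitotic chromosomes when the factor is missing. These
per-condition dependences are both the quantities inspected directly (volcano
plots, residual percentages) and the feature matrix the random-forest
fractionation consumes.

Averaging is done on log2 ratios, i.e. the geometric mean of the replicate
ratios, because SILAC ratios are multiplicative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, ValidationError
from .quantio import QuantTable, ExperimentDesign


@dataclass
class DependenceProfile:
    """Per-protein, per-condition mean log2(knockout/wild-type) ratios.

    A cell is present iff at least one replicate of that condition was
    quantified for the protein; ``replicate_counts`` records how many were.
    """

    proteins: pd.DataFrame  # identity metadata, index protein_id
    values: pd.DataFrame  # proteins x conditions, log2 scale, NaN = missing
    replicate_counts: pd.DataFrame  # same shape, ints
    imputed: bool = False  # True once gaps were median-filled; counts stay observed

    def __post_init__(self) -> None:
        if not (
            self.values.index.equals(self.replicate_counts.index)
            and list(self.values.columns) == list(self.replicate_counts.columns)
        ):
            raise ValidationError("values and replicate_counts shapes differ")
        if not self.imputed:
            present = self.values.notna().to_numpy()
            counted = self.replicate_counts.to_numpy() >= 1
            if not np.array_equal(present, counted):
                raise ValidationError(
                    "a dependence value must be present iff replicate_count >= 1"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def residual_percent(self) -> pd.DataFrame:
        """Dependences re-expressed as percent of wild-type level (100 * 2**v)."""
        return residual_percent(self.values)

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.to_csv(path, sep="\t", index_label="protein_id", float_format="%.6g",
                   na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DependenceProfile":
        vals = pd.read_csv(path, sep="\t", index_col="protein_id",
                           na_values=["NA"], keep_default_na=False)
        counts = vals.notna().astype(int)
        proteins = pd.DataFrame(
            {"gene_name": "", "is_reverse": False, "is_contaminant": False},
            index=vals.index,
        )
        return cls(proteins, vals, counts)


def residual_percent(values):
    """Percent of wild-type abundance remaining: 100 * 2**log2ratio."""
    return 100.0 * np.exp2(values)


def normalize_to_reference(table: QuantTable, reference_id: str) -> QuantTable:
    """Divide every ratio by the reference protein's ratio in the same experiment.

    Used to correct for variable chromosome recovery by anchoring on an
    invariant protein (histone H4 in the original workflow); the reference's
    own ratios become exactly 1.
    """
    if reference_id not in table.ratios.index:
        raise ValidationError(f"reference protein {reference_id!r} not in table")
    ref = table.ratios.loc[reference_id]
    absent = [e for e in table.experiments if not math.isfinite(ref[e])]
    if absent:
        raise ValidationError(
            f"reference {reference_id!r} has no ratio in experiment(s): {absent}"
        )
    return QuantTable(table.proteins, table.ratios.div(ref, axis=1))


def compute_dependence(
    table: QuantTable,
    design: ExperimentDesign,
    keep_flagged: bool = False,
) -> DependenceProfile:
    """Average replicate log2 ratios into one dependence per (protein, condition).

    The value is the arithmetic mean of log2(ratio) over present replicates
    (equivalently the log2 geometric mean ratio); missing when no replicate is
    present. Decoy/contaminant rows are dropped unless ``keep_flagged``.
    """
    table = table.filtered(keep_flagged)
    missing_exp = [e for e in design.experiments if e not in table.ratios.columns]
    if missing_exp:
        raise DesignError(f"designed experiments absent from table: {missing_exp}")
    logr = np.log2(table.ratios)
    vals = {}
    counts = {}
    for cond in design.conditions:
        exps = design.experiments_for(cond)
        block = logr[exps]
        counts[cond] = block.notna().sum(axis=1)
        vals[cond] = block.mean(axis=1, skipna=True)
    values = pd.DataFrame(vals)
    counts = pd.DataFrame(counts).astype(int)
    return DependenceProfile(table.proteins.copy(), values, counts)


def impute_missing(profile: DependenceProfile) -> DependenceProfile:
    """Replace each missing dependence by the median of its condition column.

    Present cells are never altered and replicate counts stay as observed
    (so imputed cells remain identifiable). Idempotent.
    """
    empty = [c for c in profile.conditions if profile.values[c].notna().sum() == 0]
    if empty:
        raise ValidationError(f"cannot impute all-missing condition(s): {empty}")
    filled = profile.values.fillna(profile.values.median(axis=0, skipna=True))
    return DependenceProfile(
        profile.proteins, filled, profile.replicate_counts, imputed=True
    )


def volcano_table(
    table: QuantTable,
    design: ExperimentDesign,
    condition: str,
    keep_flagged: bool = False,
) -> pd.DataFrame:
    """Per-protein mean log2 ratio and one-sample t test for one condition.

    For each protein with >= 2 present replicates: the mean log2 ratio, a
    two-sided one-sample t test of the replicate log2 ratios against 0, and
    Benjamini-Hochberg adjusted p-values across proteins. Proteins with < 2
    present replicates, or zero replicate variance (t undefined), get missing
    p-values.
    """
    if condition not in design.conditions:
        raise DesignError(f"unknown condition {condition!r}")
    exps = design.experiments_for(condition)
    if len(exps) < 2:
        raise DesignError(f"condition {condition!r} has < 2 replicates")
    table = table.filtered(keep_flagged)
    block = np.log2(table.ratios[exps])

    n = block.notna().sum(axis=1)
    mean = block.mean(axis=1, skipna=True)
    sd = block.std(axis=1, ddof=1, skipna=True)

    pvals = pd.Series(np.nan, index=block.index)
    ok = (n >= 2) & (sd > 0)
    if ok.any():
        tstat = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
        pvals.loc[ok] = 2.0 * stats.t.sf(np.abs(tstat), df=n[ok] - 1)

    padj = pd.Series(np.nan, index=block.index)
    tested = pvals.notna()
    if tested.any():
        padj.loc[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "protein_id": block.index,
            "mean_log2_ratio": mean,
            "n_replicates": n,
            "p_value": pvals,
            "p_adjusted": padj,
        }
    ).set_index("protein_id")
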