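"""Readers and writers for all on-disk artifacts.

The quantification input is the tab-separated protein-level output of an
upstream search engine (one row per protein group, per-experiment SILAC
heavy/light ratio columns). Experiment designs, training-set definitions and
score tables are small TSV/YAML files of our own dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError, DesignError, TrainingError

#: tokens in ratio cells that mean "not quantified"
MISSING_TOKENS = {"", "NaN", "nan", "NA"}

DEFAULT_RATIO_PREFIX = "Ratio H/L normalized"

ORIENTATIONS = ("ko_over_wt", "wt_over_ko")


@dataclass(frozen=True)
class ProteinRecord:
    """Identity metadata for one protein group.

    ``is_reverse`` and ``is_contaminant`` are decoy/contaminant flags assigned
    upstream; flagged rows are carried through I/O but excluded from analysis
    modules by default.
    """

    protein_id: str
    gene_name: str = ""
    is_reverse: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")


@dataclass
class ExperimentDesign:
    """Maps ratio columns to (condition, replicate, label orientation).

    ``orientation`` records which way the isotope labels were swapped:
    ``ko_over_wt`` means the stored ratio is already knockout/wild-type,
    ``wt_over_ko`` means it must be inverted on read.
    """

    table: pd.DataFrame  # columns: experiment, condition, replicate, orientation

    REQUIRED = ("experiment", "condition", "replicate", "orientation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        t = self.table
        if t["experiment"].duplicated().any():
            dupes = sorted(t.loc[t["experiment"].duplicated(), "experiment"])
            raise DesignError(f"duplicate experiment names in design: {dupes}")
        pairs = t[["condition", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise DesignError("duplicate (condition, replicate) pairs in design")
        if (t["replicate"] < 1).any():
            raise DesignError("replicate indices must be >= 1")
        bad = set(t["orientation"]) - set(ORIENTATIONS)
        if bad:
            raise DesignError(f"unknown orientations: {sorted(bad)}")

    @property
    def experiments(self) -> list[str]:
        return list(self.table["experiment"])

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.table["condition"]))

    def experiments_for(self, condition: str) -> list[str]:
        rows = self.table[self.table["condition"] == condition]
        if rows.empty:
            raise DesignError(f"condition {condition!r} has no designed experiments")
        return list(rows["experiment"])

    def orientation_of(self, experiment: str) -> str:
        rows = self.table[self.table["experiment"] == experiment]
        if rows.empty:
            raise DesignError(f"experiment {experiment!r} not in design")
        return rows["orientation"].iloc[0]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, str]]
    ) -> "ExperimentDesign":
        return cls(
            pd.DataFrame(records, columns=list(cls.REQUIRED)).astype(
                {"replicate": int}
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExperimentDesign":
        df = pd.read_csv(path, sep="\t", dtype={"experiment": str, "condition": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class QuantTable:
    """Proteins x experiments matrix of oriented SILAC ratios.

    ``ratios`` is indexed by protein_id with one column per experiment;
    missing cells are NaN, present cells strictly positive and always mean
    knockout/wild-type regardless of the original label orientation.
    """

    proteins: pd.DataFrame  # index protein_id; columns gene_name, is_reverse, is_contaminant
    ratios: pd.DataFrame  # index protein_id; columns experiments; float

    def __post_init__(self) -> None:
        if not self.proteins.index.equals(self.ratios.index):
            raise ValidationError("proteins and ratios indexed by different protein_ids")
        if self.proteins.index.duplicated().any():
            dupes = sorted(self.proteins.index[self.proteins.index.duplicated()])
            raise FormatError(f"duplicate protein_id(s): {dupes}")
        if self.ratios.columns.duplicated().any():
            raise ValidationError("experiment names must be unique")
        vals = self.ratios.to_numpy(float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValidationError("all present ratios must be strictly positive")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.proteins.index)

    @property
    def experiments(self) -> list[str]:
        return list(self.ratios.columns)

    def filtered(self, keep_flagged: bool = False) -> "QuantTable":
        """Drop decoy and contaminant rows (the default for all analysis)."""
        if keep_flagged:
            return self
        keep = ~(self.proteins["is_reverse"] | self.proteins["is_contaminant"])
        return QuantTable(self.proteins.loc[keep], self.ratios.loc[keep])

    def records(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(pid, row["gene_name"], bool(row["is_reverse"]),
                          bool(row["is_contaminant"]))
            for pid, row in self.proteins.iterrows()
        ]

    @classmethod
    def from_arrays(
        cls,
        protein_ids: Sequence[str],
        experiments: Sequence[str],
        ratios: np.ndarray,
        gene_names: Sequence[str] | None = None,
        is_reverse: Sequence[bool] | None = None,
        is_contaminant: Sequence[bool] | None = None,
    ) -> "QuantTable":
        n = len(protein_ids)
        proteins = pd.DataFrame(
            {
                "gene_name": list(gene_names) if gene_names is not None else [""] * n,
                "is_reverse": list(is_reverse) if is_reverse is not None else [False] * n,
                "is_contaminant": list(is_contaminant)
                if is_contaminant is not None
                else [False] * n,
            },
            index=pd.Index(protein_ids, name="protein_id"),
        )
        rmat = pd.DataFrame(
            np.asarray(ratios, float), index=proteins.index, columns=list(experiments)
        )
        return cls(proteins, rmat)

    def to_tsv(self, path: str | Path, column_prefix: str = DEFAULT_RATIO_PREFIX) -> None:
        """Write back out in the proteinGroups-style dialect (oriented ko/wt)."""
        out = pd.DataFrame(index=self.proteins.index)
        out.insert(0, "Protein IDs", self.proteins.index)
        out["Gene names"] = self.proteins["gene_name"]
        for e in self.experiments:
            col = self.ratios[e].map(lambda v: "" if not math.isfinite(v) else f"{v:.6g}")
            out[f"{column_prefix} {e}"] = col
        out["Reverse"] = np.where(self.proteins["is_reverse"], "+", "")
        out["Potential contaminant"] = np.where(self.proteins["is_contaminant"], "+", "")
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TrainingSet:
    """A named complex: its known members (positives) plus the shared
    background set (e.g. cytoplasmic/ribosomal contaminants) used as negatives."""

    name: str
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positives:
            raise TrainingError(f"training set {self.name!r}: empty positives")
        overlap = self.positives & self.negatives
        if overlap:
            raise TrainingError(
                f"training set {self.name!r}: proteins both positive and negative: "
                f"{sorted(overlap)}"
            )

    def restrict(self, universe: Iterable[str]) -> "TrainingSet":
        u = set(universe)
        return TrainingSet(self.name, frozenset(self.positives & u),
                           frozenset(self.negatives & u))


def _parse_ratio(token: str, row: int, column: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return math.nan
    try:
        v = float(token)
    except ValueError as exc:
        raise FormatError(f"row {row}, column {column!r}: unparsable ratio {token!r}") from exc
    if math.isnan(v):
        return math.nan
    if v <= 0:
        raise ValidationError(
            f"row {row}, column {column!r}: non-positive ratio {v}"
        )
    return v


def read_protein_groups(
    path: str | Path,
    design: ExperimentDesign,
    column_prefix: str = DEFAULT_RATIO_PREFIX,
) -> QuantTable:
    """Read a proteinGroups-style TSV into an oriented :class:`QuantTable`.

    For each designed experiment ``E`` the column ``"<column_prefix> E"`` must
    exist. Cells that are empty or a missing-token become NaN. Experiments
    whose design orientation is ``wt_over_ko`` are inverted (x -> 1/x) so every
    stored ratio means knockout/wild-type. The protein_id of a group is the
    first accession in its ID list (the razor convention). Decoy and
    contaminant rows are kept but flagged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = next((c for c in ("Protein IDs", "Majority protein IDs", "protein_id")
                   if c in df.columns), None)
    if id_col is None:
        raise FormatError("no protein ID column ('Protein IDs') found")

    wanted = {e: f"{column_prefix} {e}" for e in design.experiments}
    absent = [col for col in wanted.values() if col not in df.columns]
    if absent:
        raise FormatError(f"missing ratio column(s): {absent}")

    protein_ids = [s.split(";")[0].strip() for s in df[id_col]]
    gene_names = (
        [s.split(";")[0].strip() for s in df["Gene names"]]
        if "Gene names" in df.columns
        else [""] * len(df)
    )
    rev = (
        df["Reverse"].str.strip().eq("+")
        if "Reverse" in df.columns
        else pd.Series(False, index=df.index)
    )
    cont_col = next(
        (c for c in ("Potential contaminant", "Contaminant") if c in df.columns), None
    )
    cont = (
        df[cont_col].str.strip().eq("+")
        if cont_col
        else pd.Series(False, index=df.index)
    )

    mat = np.empty((len(df), len(design.experiments)))
    for j, exp in enumerate(design.experiments):
        col = wanted[exp]
        parsed = [
            _parse_ratio(tok, i, col) for i, tok in enumerate(df[col])
        ]
        vals = np.array(parsed, float)
        if design.orientation_of(exp) == "wt_over_ko":
            vals = 1.0 / vals
        mat[:, j] = vals

    return QuantTable.from_arrays(
        protein_ids, design.experiments, mat,
        gene_names=gene_names, is_reverse=list(rev), is_contaminant=list(cont),
    )


def read_training_sets(path: str | Path) -> list[TrainingSet]:
    """Read named complexes + the shared negatives list from a YAML file.

    Layout::

        negatives: [RPL3, RPL4, ...]
        complexes:
          condensin_I: [SMC2, SMC4, CAPD2, CAPG, CAPH]
          cohesin: [SMC1, SMC3, SCC1, SA2]
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "complexes" not in doc:
        raise FormatError("training-set file must map 'complexes' (and 'negatives')")
    negatives = frozenset(str(x) for x in doc.get("negatives", []))
    sets = []
    for name, members in doc["complexes"].items():
        if not members:
            raise TrainingError(f"training set {name!r}: empty positives")
        sets.append(TrainingSet(str(name), frozenset(str(m) for m in members), negatives))
    return sets


def write_training_sets(sets: Sequence[TrainingSet], path: str | Path) -> None:
    doc = {
        "negatives": sorted(sets[0].negatives) if sets else [],
        "complexes": {ts.name: sorted(ts.positives) for ts in sets},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_scores_table(results, path: str | Path) -> None:
    """Write fractionation scores as TSV, one row per protein.

    Accepts a single FractionationResults, a sequence of them, or a
    MultiRFResults; numeric values round-trip at 6 significant digits.
    """
    frame = _scores_frame(results)
    if frame.empty:
        raise ValidationError("refusing to write an empty score table")
    out = frame.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: f"{v:.6g}" if math.isfinite(v) else "NA")
    out.to_csv(path, sep="\t", index=True, index_label="protein_id")


def _scores_frame(results) -> pd.DataFrame:
    if hasattr(results, "to_frame"):
        return results.to_frame()
    if isinstance(results, pd.DataFrame):
        return results
    parts = [r.to_frame() for r in results]
    if not parts:
        raise ValidationError("no results to write")
    return pd.concat(parts, axis=1)


def read_scores_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="protein_id", na_values=["NA"],
                     keep_default_na=False)
    for c in df.columns:
        if c.startswith("label"):
            continue
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df
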