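"""Many fractionations at once: score matrix, branch clustering, candidates.

Running nanoRF against a panel of target complexes gives every protein a
profile of membership scores, one per complex. Hierarchically clustering
those profiles groups proteins into *branches*; unlabeled proteins that land
in the same branch as a complex's training members are its candidate novel
members, ranked by their score in that complex's column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import TrainingError, ValidationError
from .dependence import DependenceProfile
from .quantio import TrainingSet
from .rf import NanoRF, RFConfig, FractionationResults

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "ward")


@dataclass
class MultiRFResults:
    """Proteins x complexes score matrix with per-complex quality metrics."""

    scores: pd.DataFrame  # proteins x complexes, in [0, 1]
    training: pd.DataFrame  # same shape; 'positive' | 'negative' | 'unlabeled'
    thresholds: pd.Series  # complex -> MCC-optimal threshold
    qualities: pd.DataFrame  # complex -> (auc, mcc)
    results: dict[str, FractionationResults]

    def __post_init__(self) -> None:
        s = self.scores.to_numpy(float)
        if np.any((s < 0) | (s > 1)):
            raise ValidationError("scores must lie in [0, 1]")

    @property
    def complexes(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.scores.index)

    def poorly_fractionated(self, min_auc: float = 0.9) -> list[str]:
        """Target complexes whose ROC quality fell below ``min_auc``."""
        return list(self.qualities.index[self.qualities["auc"] < min_auc])

    def to_frame(self) -> pd.DataFrame:
        parts = {}
        for c in self.complexes:
            parts[f"score_{c}"] = self.scores[c]
            parts[f"label_{c}"] = self.training[c]
        return pd.DataFrame(parts)

    def summary(self) -> str:
        lines = [
            f"multi-nanoRF: {len(self.complexes)} complexes x "
            f"{len(self.scores)} proteins",
            "=" * 52,
            f"{'complex':<22}{'AUC':>8}{'MCC':>8}{'thresh':>9}",
        ]
        for c in self.complexes:
            lines.append(
                f"{c:<22}{self.qualities.loc[c, 'auc']:>8.3f}"
                f"{self.qualities.loc[c, 'mcc']:>8.3f}"
                f"{self.thresholds[c]:>9.3f}"
            )
        return "\n".join(lines)


@dataclass
class BranchPartition:
    """A cut dendrogram over protein score profiles.

    ``assignment`` maps every clustered protein to a branch index 1..n;
    branches are numbered by first appearance in dendrogram leaf order, so
    branch blocks are contiguous when rows are leaf-ordered.
    """

    assignment: pd.Series  # protein_id -> branch index (1..n_branches)
    n_branches: int
    linkage_matrix: np.ndarray | None  # None when reloaded from a flat table
    leaf_order: list[str]

    def __post_init__(self) -> None:
        found = set(self.assignment.unique())
        expected = set(range(1, self.n_branches + 1))
        if found != expected:
            raise ValidationError(
                f"branch indices {sorted(found)} != 1..{self.n_branches}"
            )

    def members(self, branch: int) -> list[str]:
        return list(self.assignment.index[self.assignment == branch])

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BranchPartition":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        assignment = df["branch"].astype(int)
        return cls(assignment, int(assignment.max()), None, list(assignment.index))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        if self.linkage_matrix is None:
            raise ValidationError("partition has no dendrogram (loaded from TSV)")
        tree = hierarchy.to_tree(self.linkage_matrix)
        ids = list(self.assignment.index)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"branch": self.assignment}).to_csv(
            path, sep="\t", index_label="protein_id"
        )


class MultiNanoRF:
    """Panel model: one independent nanoRF per training set.

    Column ``j`` is fit with seed ``config.seed + j`` so forests are
    independent yet the whole matrix is reproducible; a set failing the
    per-fractionation preconditions aborts the run with its name (sets are
    never silently dropped).
    """

    def __init__(
        self,
        profile: DependenceProfile,
        training_sets: Sequence[TrainingSet],
        config: RFConfig | None = None,
    ) -> None:
        if len(training_sets) < 2:
            raise TrainingError("multi-nanoRF needs at least 2 training sets")
        names = [ts.name for ts in training_sets]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate complex names: {names}")
        self.profile = profile
        self.training_sets = list(training_sets)
        self.config = config or RFConfig()

    def fit(self) -> MultiRFResults:
        cols, labels, thr, qual, results = {}, {}, {}, {}, {}
        for j, ts in enumerate(self.training_sets):
            cfg = replace(self.config, seed=self.config.seed + j)
            try:
                res = NanoRF(self.profile, ts, cfg).fit()
            except (TrainingError, ValidationError) as exc:
                raise TrainingError(f"training set {ts.name!r}: {exc}") from exc
            cols[ts.name] = res.scores
            labels[ts.name] = res.in_training
            thr[ts.name] = res.threshold
            qual[ts.name] = {"auc": res.auc, "mcc": res.best_mcc}
            results[ts.name] = res
        return MultiRFResults(
            scores=pd.DataFrame(cols),
            training=pd.DataFrame(labels),
            thresholds=pd.Series(thr, name="threshold"),
            qualities=pd.DataFrame(qual).T[["auc", "mcc"]],
            results=results,
        )


def run_multi(
    profile: DependenceProfile,
    sets: Sequence[TrainingSet],
    cfg: RFConfig | None = None,
) -> MultiRFResults:
    """Convenience wrapper: ``MultiNanoRF(profile, sets, cfg).fit()``."""
    return MultiNanoRF(profile, sets, cfg).fit()


def cluster_branches(
    matrix: MultiRFResults,
    n_branches: int,
    distance: str = "euclidean",
    linkage: str = "ward",
) -> BranchPartition:
    """Agglomerative clustering of protein score profiles, cut to n branches.

    Rows are sorted lexicographically by protein_id before computing the
    linkage, making the partition invariant to input row order. With the
    ``correlation`` distance, zero-variance profiles (e.g. all-zero scores)
    are treated as uncorrelated with everything (distance 1).
    """
    if distance not in DISTANCES:
        raise ValidationError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValidationError("ward linkage requires euclidean distance")
    scores = matrix.scores.sort_index()
    n = len(scores)
    if n_branches < 1 or n_branches > n:
        raise ValidationError(
            f"n_branches={n_branches} out of range for {n} proteins"
        )
    d = pdist(scores.to_numpy(float), metric=distance)
    if distance == "correlation":
        d = np.nan_to_num(d, nan=1.0)
    Z = hierarchy.linkage(d, method=linkage)
    raw = hierarchy.cut_tree(Z, n_clusters=n_branches).ravel()
    order = hierarchy.leaves_list(Z)
    leaf_ids = [scores.index[i] for i in order]
    # renumber branches 1..k by first appearance along the dendrogram leaves
    relabel: dict[int, int] = {}
    for i in order:
        if raw[i] not in relabel:
            relabel[raw[i]] = len(relabel) + 1
    assignment = pd.Series(
        [relabel[b] for b in raw], index=scores.index, name="branch"
    )
    return BranchPartition(assignment, n_branches, Z, leaf_ids)


def predict_candidates(
    matrix: MultiRFResults,
    partition: BranchPartition,
    ts: TrainingSet,
) -> pd.DataFrame:
    """Rank unlabeled proteins sharing a branch with the target complex.

    A branch qualifies when it contains at least half of the complex's
    training positives (those present in the matrix). Candidates are the
    unlabeled proteins of qualifying branches — training members excluded —
    ranked by their score in the target complex's column (ties broken by
    protein_id).
    """
    if ts.name not in matrix.complexes:
        raise ValidationError(f"complex {ts.name!r} not among matrix columns")
    assigned = partition.assignment
    pos = sorted(ts.positives & set(assigned.index))
    if not pos:
        raise TrainingError(f"{ts.name!r}: no training positive was clustered")
    counts = assigned.loc[pos].value_counts()
    qualifying = set(counts.index[counts >= len(pos) / 2.0])
    labeled = ts.positives | ts.negatives
    rows = []
    for pid, branch in assigned.items():
        if branch in qualifying and pid not in labeled:
            rows.append((pid, int(branch), float(matrix.scores.loc[pid, ts.name])))
    out = pd.DataFrame(rows, columns=["protein_id", "branch", "score"])
    out = out.sort_values(
        ["score", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return out


def export_heatmap(
    matrix: MultiRFResults,
    partition: BranchPartition,
    path: str | Path,
    figure_path: str | Path | None = None,
) -> None:
    """Write the branch-ordered score matrix as TSV (row order = leaf order).

    Branch blocks are contiguous because branches are numbered in leaf order.
    Optionally also renders a heat-map figure.
    """
    if set(partition.assignment.index) != set(matrix.protein_ids):
        raise ValidationError("partition and matrix cover different proteins")
    ordered = matrix.scores.loc[partition.leaf_order]
    out = ordered.copy()
    out.insert(0, "branch", partition.assignment.loc[partition.leaf_order])
    out.to_csv(path, sep="\t", index_label="protein_id", float_format="%.6g")
    if figure_path is not None:
        from . import plots

        plots.heatmap_figure(ordered, partition, figure_path)
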