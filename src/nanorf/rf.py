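"""Small-training-set random-forest fractionation ("nanoRF").

A forest of classification trees is trained to separate the known members of
one complex (positives, often fewer than 10 proteins) from a curated
background set (negatives), using the per-condition knockout dependences as
features. Every protein in the dataset is then scored by the forest's vote
fraction. Training proteins are scored only by the trees for which they were
out-of-bag — the "adjusted" score — so that members and candidates live on a
comparable, non-self-fit scale. Fractionation quality is summarised by the
ROC curve / AUC and the best Matthews correlation coefficient over score
thresholds; the MCC-optimal threshold is the membership cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.tree import DecisionTreeClassifier

from .errors import TrainingError, ValidationError
from .dependence import DependenceProfile
from .quantio import TrainingSet


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters.

    ``features_per_split="auto"`` applies the sqrt(p) rule, the random-forest
    default; ``class_weighting="balanced"`` reweights each tree's bootstrap
    sample so a handful of positives is not swamped by the background set.
    """

    n_trees: int = 1000
    features_per_split: int | str = "auto"
    seed: int = 0
    class_weighting: str = "balanced"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be positive")
        if self.n_trees < 100:
            import warnings

            warnings.warn("n_trees < 100: scores too noisy for reported results")
        if self.class_weighting not in ("balanced", "none"):
            raise ValidationError("class_weighting must be 'balanced' or 'none'")
        if self.features_per_split != "auto" and int(self.features_per_split) < 1:
            raise ValidationError("features_per_split must be positive or 'auto'")

    def max_features(self, n_features: int) -> int:
        if self.features_per_split == "auto":
            return max(1, int(round(math.sqrt(n_features))))
        return min(int(self.features_per_split), n_features)


@dataclass
class FractionationResults:
    """Scores and quality metrics of one complex's in-silico fractionation."""

    complex_name: str
    scores: pd.Series  # protein_id -> adjusted RF score in [0, 1]
    in_training: pd.Series  # protein_id -> 'positive' | 'negative' | 'unlabeled'
    threshold: float
    auc: float
    best_mcc: float
    roc_points: np.ndarray  # (n, 2) of (FPR, TPR), (0,0) .. (1,1)
    config: RFConfig
    oob_fallback_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = self.scores.to_numpy(float)
        if np.any((s < 0) | (s > 1)):
            raise ValidationError("scores must lie in [0, 1]")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.scores.index)

    def predicted_members(self) -> pd.Series:
        """Scores of proteins above the MCC-optimal threshold, descending."""
        hits = self.scores[self.scores > self.threshold]
        return hits.sort_values(ascending=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                f"score_{self.complex_name}": self.scores,
                f"label_{self.complex_name}": self.in_training,
                f"above_threshold_{self.complex_name}": (
                    self.scores > self.threshold
                ).astype(int),
            }
        )

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc_points, columns=["fpr", "tpr"])

    def summary(self) -> str:
        n = len(self.scores)
        npos = int((self.in_training == "positive").sum())
        nneg = int((self.in_training == "negative").sum())
        ncand = int(
            ((self.in_training == "unlabeled") & (self.scores > self.threshold)).sum()
        )
        lines = [
            f"nanoRF fractionation: {self.complex_name}",
            "=" * 46,
            f"proteins scored        {n:>10d}",
            f"training positives     {npos:>10d}",
            f"training negatives     {nneg:>10d}",
            f"trees                  {self.config.n_trees:>10d}",
            f"seed                   {self.config.seed:>10d}",
            f"AUC (out-of-bag)       {self.auc:>10.3f}",
            f"best MCC               {self.best_mcc:>10.3f}",
            f"score threshold        {self.threshold:>10.3f}",
            f"unlabeled above cut    {ncand:>10d}",
        ]
        if self.oob_fallback_ids:
            lines.append(
                f"full-forest fallback for: {', '.join(self.oob_fallback_ids)}"
            )
        return "\n".join(lines)


class NanoRF:
    """Fractionation model for one target complex.

    Parameters
    ----------
    profile : DependenceProfile
        Imputed (complete) feature matrix of per-condition dependences.
    training_set : TrainingSet
        Positives (complex members) and negatives (background) present in the
        profile; each must retain at least 2 members after intersection.
    config : RFConfig, optional

    ``fit()`` grows ``config.n_trees`` trees, each on a bootstrap of the
    labeled rows with ``features_per_split`` candidate conditions per split,
    and returns a :class:`FractionationResults`. Rows are canonically sorted
    by protein_id first, so results do not depend on input row order; with a
    fixed seed the fit is fully reproducible.
    """

    def __init__(
        self,
        profile: DependenceProfile,
        training_set: TrainingSet,
        config: RFConfig | None = None,
    ) -> None:
        if not profile.is_complete():
            raise ValidationError(
                "profile has missing cells; run impute_missing() first"
            )
        self.config = config or RFConfig()
        # canonical order: reproducibility independent of input file order
        self.values = profile.values.sort_index()
        universe = set(self.values.index)
        self.training_set = training_set.restrict(universe)
        if len(self.training_set.positives) < 2:
            raise TrainingError(
                f"{training_set.name!r}: fewer than 2 positives present in profile"
            )
        if len(self.training_set.negatives) < 2:
            raise TrainingError(
                f"{training_set.name!r}: fewer than 2 negatives present in profile"
            )

    def fit(self) -> FractionationResults:
        X = self.values.to_numpy(float)
        ids = np.asarray(self.values.index)
        pos = np.isin(ids, sorted(self.training_set.positives))
        neg = np.isin(ids, sorted(self.training_set.negatives))
        labeled_idx = np.flatnonzero(pos | neg)
        y = pos[labeled_idx].astype(int)
        n_lab = len(labeled_idx)
        X_lab = X[labeled_idx]

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        max_feat = cfg.max_features(X.shape[1])
        cw = "balanced" if cfg.class_weighting == "balanced" else None

        total_votes = np.zeros(len(ids))
        oob_votes = np.zeros(n_lab)
        oob_counts = np.zeros(n_lab, dtype=int)
        n_grown = 0

        for _ in range(cfg.n_trees):
            boot = rng.integers(0, n_lab, size=n_lab)
            yb = y[boot]
            if yb.min() == yb.max():  # single-class bootstrap cannot grow a tree
                continue
            n_grown += 1
            tree = DecisionTreeClassifier(
                max_features=max_feat,
                class_weight=cw,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X_lab[boot], yb)
            votes = tree.predict(X)
            total_votes += votes
            oob = np.ones(n_lab, dtype=bool)
            oob[boot] = False
            oob_votes[oob] += votes[labeled_idx[oob]]
            oob_counts[oob] += 1

        if n_grown == 0:
            raise TrainingError(
                f"{self.training_set.name!r}: no two-class bootstrap in "
                f"{cfg.n_trees} draws"
            )
        scores = total_votes / n_grown
        fallback = []
        adj = np.empty(n_lab)
        for k in range(n_lab):
            if oob_counts[k] == 0:
                adj[k] = scores[labeled_idx[k]]
                fallback.append(str(ids[labeled_idx[k]]))
            else:
                adj[k] = oob_votes[k] / oob_counts[k]
        scores[labeled_idx] = adj

        labels = np.where(pos, "positive", np.where(neg, "negative", "unlabeled"))
        auc_val = auc(adj, y)
        thr, mcc = best_threshold(adj, y)
        fpr, tpr, _ = roc_curve(y, adj)
        roc_pts = np.column_stack([fpr, tpr])
        if not np.allclose(roc_pts[0], [0, 0]):
            roc_pts = np.vstack([[0.0, 0.0], roc_pts])
        if not np.allclose(roc_pts[-1], [1, 1]):
            roc_pts = np.vstack([roc_pts, [1.0, 1.0]])

        return FractionationResults(
            complex_name=self.training_set.name,
            scores=pd.Series(scores, index=self.values.index, name="score"),
            in_training=pd.Series(labels, index=self.values.index, name="label"),
            threshold=float(thr),
            auc=float(auc_val),
            best_mcc=float(mcc),
            roc_points=roc_pts,
            config=cfg,
            oob_fallback_ids=tuple(fallback),
        )


def fractionate(
    profile: DependenceProfile, ts: TrainingSet, cfg: RFConfig | None = None
) -> FractionationResults:
    """Convenience wrapper: ``NanoRF(profile, ts, cfg).fit()``."""
    return NanoRF(profile, ts, cfg).fit()


def sample_background(
    profile: DependenceProfile,
    exclude: Sequence[str],
    n: int = 30,
    seed: int = 0,
) -> frozenset[str]:
    """Seeded uniform sample of unlabeled proteins to serve as negatives.

    Fallback for datasets without a curated background (contaminant) list;
    prefer a curated set when one exists — a random sample can include
    undiscovered complex members.
    """
    pool = sorted(set(profile.values.index) - set(exclude))
    if len(pool) < n:
        raise TrainingError(f"only {len(pool)} proteins available to sample")
    rng = np.random.default_rng(seed)
    return frozenset(str(x) for x in rng.choice(pool, size=n, replace=False))


def _check_labels(labels: np.ndarray) -> None:
    if labels.sum() < 1 or (1 - labels).sum() < 1:
        raise ValidationError("need at least one positive and one negative")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney probability, ties counted 1/2)."""
    y = np.asarray(labels, int)
    _check_labels(y)
    s = np.asarray(scores, float)
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def mcc_at_threshold(
    scores: Sequence[float], labels: Sequence[int], t: float
) -> float:
    """Matthews correlation of the prediction rule ``score > t``.

    Returns 0 when any factor of the denominator is 0 (a degenerate
    confusion table carries no correlation signal).
    """
    y = np.asarray(labels, int)
    _check_labels(y)
    pred = np.asarray(scores, float) > t
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def best_threshold(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """MCC-maximizing threshold over the midpoint grid.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus the sentinels 0 and 1 — MCC is constant between
    consecutive scores, so the midpoints cover every achievable confusion
    table. Ties are broken toward the smallest threshold.
    """
    y = np.asarray(labels, int)
    _check_labels(y)
    s = np.asarray(scores, float)
    uniq = np.unique(s)
    grid = [0.0]
    grid.extend(((uniq[:-1] + uniq[1:]) / 2.0).tolist())
    grid.append(1.0)
    best_t, best_m = 0.0, -np.inf
    for t in sorted(set(grid)):
        m = mcc_at_threshold(s, y, t)
        if m > best_m:
            best_t, best_m = t, m
    return float(best_t), float(best_m)


def scatter_pairs(
    a: FractionationResults,
    b: FractionationResults,
    annotate_above_thresholds: bool = True,
) -> pd.DataFrame:
    """Join two fractionations for a two-dimensional score scatter.

    One row per protein in both universes, with each complex's score and
    training label; ``above_both`` marks the proteins exceeding both
    MCC-optimal thresholds (the candidate rectangle of the 2-D plots).
    """
    common = a.scores.index.intersection(b.scores.index)
    if common.empty:
        raise ValidationError("fractionations share no proteins")
    out = pd.DataFrame(
        {
            "score_a": a.scores.loc[common],
            "score_b": b.scores.loc[common],
            "label_a": a.in_training.loc[common],
            "label_b": b.in_training.loc[common],
        }
    )
    if annotate_above_thresholds:
        out["above_both"] = (out["score_a"] > a.threshold) & (
            out["score_b"] > b.threshold
        )
    return out
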