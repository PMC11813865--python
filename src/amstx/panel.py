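"""Classifier panel construction: Gini-importance gene ranking, forward-
selected linear SVM panels, cross-cohort ROC/AUC, and Youden operating points.

The workflow mirrors the discovery/validation design: rank the replicated
biomarker pool by mean decrease in Gini impurity from a 10,000-tree random
forest trained on the discovery cohort, then grow panels gene by gene in rank
order, training a linear maximum-margin classifier (L2-regularized hinge
loss, inverse-class-frequency weights) on the discovery cohort and scoring
the held-out cohort; the best panel maximizes test AUC (smallest panel on
ties), with the operating threshold picked by the Youden index J = max(sens +
spec - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

log = logging.getLogger(__name__)

DEFAULT_N_TREES = 10_000


@dataclass(frozen=True)
class LabeledFeatures:
    """Log-CPM features restricted to a gene pool, with binary AMS labels."""

    features: pd.DataFrame  # samples x genes
    labels: pd.Series  # 1 = AMS+, 0 = AMS-
    cohort: str

    def __post_init__(self) -> None:
        if self.features.isna().to_numpy().any():
            raise ValueError("missing values in feature matrix")
        if not self.labels.index.equals(self.features.index):
            raise ValueError("labels and features index mismatch")


def diagnostic_labels(meta: pd.DataFrame) -> pd.Series:
    """Positives = HA samples of severe-AMS subjects; everything else negative.

    On the study's discovery cohort (18 paired subjects, 5 severe) this
    yields the published 5-positive / 31-negative training split.
    """
    pos = (meta["severe_ams"]) & (meta["timepoint"] == "HA")
    return pos.astype(int)


def predictive_labels(meta: pd.DataFrame) -> pd.Series:
    """SL samples labeled by the subject's eventual severity (others dropped)."""
    sl = meta[meta["timepoint"] == "SL"]
    return sl["severe_ams"].astype(int)


def build_features(
    logcpm: pd.DataFrame, meta: pd.DataFrame, pool: list[str], labels: pd.Series, cohort: str
) -> LabeledFeatures:
    """Assemble samples x pool features for the samples carrying a label."""
    samples = [s for s in labels.index if s in logcpm.columns]
    feats = logcpm.loc[pool, samples].T
    return LabeledFeatures(
        features=feats, labels=labels.loc[samples], cohort=cohort
    )


def gini_impurity(labels: np.ndarray | list) -> float:
    """Binary Gini impurity 1 - p+^2 - p-^2 of a label multiset."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty label set")
    p = np.mean(y == y[0])
    return float(1.0 - p**2 - (1.0 - p) ** 2)


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by descending Gini importance (lexicographic tie-break)."""

    genes: tuple[str, ...]
    importance: pd.Series
    n_trees: int
    seed: int


def gini_rank(
    train: LabeledFeatures, n_trees: int = DEFAULT_N_TREES, seed: int = 0
) -> GeneRanking:
    """Rank genes by mean decrease in Gini impurity over a random forest.

    Bootstrap sample per tree, sqrt(p) candidate features per split, trees
    grown to purity; reproducible for a fixed seed.
    """
    y = train.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 samples in each class to rank genes")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train.features.to_numpy(), y)
    imp = pd.Series(forest.feature_importances_, index=train.features.columns)
    order = sorted(imp.index, key=lambda g: (-imp[g], g))
    return GeneRanking(
        genes=tuple(order), importance=imp.loc[order], n_trees=n_trees, seed=seed
    )


@dataclass(frozen=True)
class LinearPanelClassifier:
    """Standardized linear max-margin scorer over a gene panel."""

    panel: tuple[str, ...]
    weights: np.ndarray
    bias: float
    mean: np.ndarray
    sd: np.ndarray

    def decision_scores(self, features: pd.DataFrame) -> pd.Series:
        X = (features[list(self.panel)].to_numpy() - self.mean) / self.sd
        return pd.Series(X @ self.weights + self.bias, index=features.index)


def train_linear_classifier(
    train: LabeledFeatures, panel: list[str], C: float = 1.0
) -> LinearPanelClassifier:
    """L2-regularized hinge-loss linear classifier with balanced class weights.

    Features are standardized by training mean/SD (zero-variance genes
    dropped with a warning); the bias is unregularized.
    """
    X = train.features[panel].to_numpy(dtype=float)
    y = train.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(panel, keep) if not k]
        warnings.warn(f"dropping zero-variance panel genes: {dropped}")
        panel = [g for g, k in zip(panel, keep) if k]
        X, mean, sd = X[:, keep], mean[keep], sd[keep]
        if X.shape[1] == 0:
            raise ValueError("all panel genes have zero training variance")
    Xs = (X - mean) / sd
    svm = SVC(kernel="linear", C=C, class_weight="balanced", tol=1e-6)
    svm.fit(Xs, y)
    return LinearPanelClassifier(
        panel=tuple(panel),
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        mean=mean,
        sd=sd,
    )


@dataclass(frozen=True)
class ROCCurve:
    """Full ROC with AUC and the Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def youden(self) -> tuple[float, float, float]:
        """(threshold, sensitivity, specificity) maximizing sens + spec - 1.

        Ties are broken toward higher sensitivity.
        """
        j = self.sensitivity + self.specificity - 1.0
        best = np.lexsort((self.sensitivity, j))[-1]
        return (
            float(self.thresholds[best]),
            float(self.sensitivity[best]),
            float(self.specificity[best]),
        )


def roc_auc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> ROCCurve:
    """ROC over all distinct score thresholds; AUC is the Mann-Whitney
    pair statistic (ties count one half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(roc_auc_score(y, s)),
    )


def youden_threshold(roc: ROCCurve) -> tuple[float, float, float]:
    return roc.youden()


@dataclass(frozen=True)
class PanelTrajectory:
    """Forward-selection record: one row per panel size k = 1..max_k.

    Columns: k, genes (comma-joined top-k), auc, youden_threshold,
    sensitivity, specificity. ``best`` holds the max-AUC row (smallest k on
    ties).
    """

    entries: pd.DataFrame
    best_k: int
    best_genes: tuple[str, ...]
    best_auc: float

    @property
    def best(self) -> pd.Series:
        return self.entries.loc[self.entries["k"] == self.best_k].iloc[0]


def forward_trajectory(
    ranking: GeneRanking,
    train: LabeledFeatures,
    test: LabeledFeatures,
    max_k: int | None = None,
    C: float = 1.0,
) -> PanelTrajectory:
    """Grow panels in rank order; evaluate each on the held-out cohort."""
    if len(np.unique(test.labels)) < 2:
        raise ValueError("test cohort labels are single-class")
    max_k = len(ranking.genes) if max_k is None else min(max_k, len(ranking.genes))
    rows = []
    for k in range(1, max_k + 1):
        panel = list(ranking.genes[:k])
        clf = train_linear_classifier(train, panel, C=C)
        scores = clf.decision_scores(test.features)
        roc = roc_auc(scores, test.labels)
        thr, sens, spec = roc.youden()
        rows.append(
            {
                "k": k,
                "genes": ",".join(panel),
                "auc": roc.auc,
                "youden_threshold": thr,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    entries = pd.DataFrame(rows)
    best_idx = int(entries["auc"].idxmax())  # idxmax takes the first (smallest k)
    best = entries.loc[best_idx]
    return PanelTrajectory(
        entries=entries,
        best_k=int(best["k"]),
        best_genes=tuple(best["genes"].split(",")),
        best_auc=float(best["auc"]),
    )
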