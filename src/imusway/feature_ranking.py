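"""Hybrid leave-one-subject-out feature scoring.

For every LOSO fold and every enabled technique, features are ranked on
the training trials only and top-k membership is recorded.  A feature's
per-technique score is the number of folds in which it entered the top k;
the fused final score is the sum across techniques, giving integer
counting identities:

    sum over features of one technique's counts = top_k * n_folds
    final score = sum of the technique counts

Cross-session scores are combined by summing per-session final scores
while retaining each session's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, IntegrityError, SchemaError

__all__ = [
    "TECHNIQUES",
    "RankingConfig",
    "FeatureScoreTable",
    "loso_folds",
    "rank_features",
    "score_session",
    "combine_sessions",
]

TECHNIQUES = ("anova_f", "mutual_info", "rf_importance", "svm_weight")


@dataclass
class RankingConfig:
    top_k: int = 15
    techniques: tuple[str, ...] = TECHNIQUES
    rf_trees: int = 200
    mi_neighbors: int = 3
    seed: int = 0
    standardize: bool = True
    svm_c: float = 1.0
    technique_weights: dict[str, float] | None = None

    def validate(self, n_features: int) -> None:
        if not 1 <= self.top_k <= n_features:
            raise ConfigurationError(
                f"top_k must lie in [1, {n_features}], got {self.top_k}"
            )
        if not self.techniques:
            raise ConfigurationError("at least one technique is required")
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise ConfigurationError(f"unknown techniques {sorted(unknown)}")


@dataclass
class FeatureScoreTable:
    """Per-feature top-k counts per technique plus the fused final score."""

    counts: pd.DataFrame          # index: feature, columns: techniques
    final_score: pd.Series        # fused integer score per feature
    session: str
    n_folds: int
    top_k: int

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def top_features(self, k: int) -> list[str]:
        order = self.final_score.to_frame("score")
        order["idx"] = np.arange(len(order))
        order = order.sort_values(["score", "idx"], ascending=[False, True])
        return list(order.index[:k])

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.columns = [f"count_{c}" for c in out.columns]
        out["final_score"] = self.final_score
        return out


def loso_folds(subject_ids) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds over per-row subject IDs.

    Returns one ``(held_out_subject, train_idx, test_idx)`` triple per
    subject, ordered by first appearance.  All trials of the held-out
    subject are excluded from the fold's training set.
    """
    subject_ids = np.asarray(subject_ids)
    subjects = list(pd.unique(subject_ids))
    if len(subjects) < 2:
        raise ConfigurationError("LOSO needs at least 2 subjects")
    folds = []
    for subj in subjects:
        test = np.flatnonzero(subject_ids == subj)
        train = np.flatnonzero(subject_ids != subj)
        folds.append((subj, train, test))
    return folds


def _scores_for_technique(
    X: np.ndarray, y: np.ndarray, technique: str, config: RankingConfig
) -> np.ndarray:
    if technique == "anova_f":
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat, _ = f_classif(X, y)
        return np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    if technique == "mutual_info":
        return mutual_info_classif(
            X, y, n_neighbors=config.mi_neighbors, random_state=config.seed
        )
    if technique == "rf_importance":
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=config.seed, n_jobs=1
        )
        rf.fit(X, y)
        return rf.feature_importances_
    if technique == "svm_weight":
        Xs = StandardScaler().fit_transform(X) if config.standardize else X
        # zero-variance columns scale to 0 and get |w| = 0
        svm = SVC(kernel="linear", C=config.svm_c)
        svm.fit(Xs, y)
        return np.abs(np.asarray(svm.coef_).ravel())
    raise ConfigurationError(f"unknown technique '{technique}'")


def rank_features(
    X, y, technique: str, config: RankingConfig | None = None
) -> np.ndarray:
    """Total order over feature indices, descending relevance.

    Ties (including zero-variance features scored 0) break by ascending
    feature index, so rankings are fully deterministic given the seed.
    """
    config = config or RankingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise IntegrityError("ranking needs at least 2 classes in training data")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise IntegrityError("ranking needs >= 2 samples per class")
    scores = _scores_for_technique(X, y, technique, config)
    # stable sort on -score keeps ascending-index tie order
    return np.argsort(-scores, kind="stable")


def _check_subject_groups(subjects: np.ndarray, y: np.ndarray) -> None:
    df = pd.DataFrame({"s": subjects, "y": y})
    spanning = df.groupby("s")["y"].nunique()
    bad = spanning[spanning > 1]
    if len(bad):
        raise IntegrityError(
            f"subject IDs span multiple groups: {list(bad.index)}"
        )


def score_session(
    features: pd.DataFrame,
    labels,
    subjects,
    config: RankingConfig | None = None,
    session: str = "",
) -> FeatureScoreTable:
    """Top-k counting over all LOSO folds and enabled techniques.

    ``features`` is a wide (trial x feature) table; ``labels`` and
    ``subjects`` are per-row.  Folds whose training data collapses to a
    single class are skipped (with the fold count adjusted).
    """
    config = config or RankingConfig()
    config.validate(features.shape[1])
    y = np.asarray(labels)
    subj = np.asarray(subjects)
    if not (len(y) == len(subj) == len(features)):
        raise ConfigurationError("features, labels and subjects disagree in length")
    _check_subject_groups(subj, y)
    X = features.to_numpy(dtype=float)
    names = list(features.columns)

    counts = pd.DataFrame(0, index=names, columns=list(config.techniques))
    n_folds = 0
    for _, train, _ in loso_folds(subj):
        if len(np.unique(y[train])) < 2:
            continue
        n_folds += 1
        for tech in config.techniques:
            order = rank_features(X[train], y[train], tech, config)
            top = order[: config.top_k]
            counts.iloc[top, counts.columns.get_loc(tech)] += 1

    weights = config.technique_weights or {}
    final = sum(
        counts[t] * weights.get(t, 1.0) for t in config.techniques
    )
    final = pd.Series(final, index=names, name="final_score")
    if not weights:
        final = final.astype(int)
    return FeatureScoreTable(
        counts=counts, final_score=final, session=session,
        n_folds=n_folds, top_k=config.top_k,
    )


def combine_sessions(tables: list[FeatureScoreTable]) -> pd.DataFrame:
    """Sum final scores across sessions, retaining per-session columns.

    Returns a frame indexed by feature with one ``score_<session>``
    column per table plus ``total``, sorted descending by total (ties by
    schema order).
    """
    if not tables:
        raise ConfigurationError("no score tables to combine")
    ref = tables[0].features
    for t in tables[1:]:
        if t.features != ref:
            diff = set(t.features) ^ set(ref)
            name = sorted(diff)[0] if diff else "(ordering)"
            raise SchemaError(f"feature schemas differ at '{name}'")
    out = pd.DataFrame(index=pd.Index(ref, name="feature"))
    for t in tables:
        label = t.session or f"session{len(out.columns)}"
        col = f"score_{label}"
        while col in out.columns:
            col += "_"
        out[col] = t.final_score
    out["total"] = out.sum(axis=1)
    out["_idx"] = np.arange(len(out))
    out = out.sort_values(["total", "_idx"], ascending=[False, True])
    return out.drop(columns="_idx")
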