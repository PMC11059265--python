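"""LOSO classification of the two groups from top-ranked sway features.

Per fold, the feature matrix is restricted to the selected features,
z-scored by training statistics, and a model is fit at a fixed seed; the
held-out subject's trials are all predicted.  Confusion counts are
aggregated over folds and reported as percentages rounded to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, EvaluationError
from .feature_ranking import RankingConfig, loso_folds, score_session

__all__ = [
    "MODELS",
    "EvalConfig",
    "EvalReport",
    "loso_classify",
    "majority_vote",
    "mmse_auc",
]

MODELS = ("svm", "random_forest", "majority_vote", "gradient_boost")

#: Base learners feeding the majority vote (odd count by construction).
VOTE_BASE_MODELS = ("svm", "random_forest", "gradient_boost")


@dataclass
class EvalConfig:
    model: str = "svm"
    n_features: int = 15
    positive_class: str = "MCI"
    seed: int = 0
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    rf_trees: int = 500
    gb_estimators: int = 100
    gb_learning_rate: float = 0.1
    gb_max_depth: int = 3
    mode: str = "nested"          # 'nested' | 'paper'
    per_subject_vote: bool = False
    ranking: RankingConfig = field(default_factory=RankingConfig)

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown model '{self.model}'")
        if self.mode not in ("nested", "paper"):
            raise ConfigurationError(f"mode must be 'nested' or 'paper', got '{self.mode}'")
        if self.n_features < 1:
            raise ConfigurationError(f"n_features must be >= 1, got {self.n_features}")


@dataclass
class EvalReport:
    session: str
    model: str
    tp: int
    fp: int
    tn: int
    fn: int
    predictions: pd.DataFrame     # per-prediction log: subject, truth, predicted

    @property
    def n_predictions(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _pct(num: float, den: float) -> float:
        return round(100.0 * num / den, 1) if den > 0 else float("nan")

    @property
    def accuracy(self) -> float:
        return self._pct(self.tp + self.tn, self.n_predictions)

    @property
    def precision(self) -> float:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._pct(self.tn, self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "session": self.session,
            "model": self.model,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def _make_model(name: str, config: EvalConfig):
    if name == "svm":
        return SVC(kernel=config.svm_kernel, C=config.svm_c,
                   random_state=config.seed)
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=config.seed, n_jobs=1
        )
    if name == "gradient_boost":
        return GradientBoostingClassifier(
            n_estimators=config.gb_estimators,
            learning_rate=config.gb_learning_rate,
            max_depth=config.gb_max_depth,
            random_state=config.seed,
        )
    raise ConfigurationError(f"unknown base model '{name}'")


def majority_vote(predictions: list[np.ndarray]) -> np.ndarray:
    """Per-sample modal label over an odd number of voters."""
    if len(predictions) < 2:
        raise ConfigurationError("majority vote needs at least 2 voters")
    if len(predictions) % 2 == 0:
        raise ConfigurationError(
            f"even voter count ({len(predictions)}) has no tie rule; use an odd count"
        )
    stacked = np.stack([np.asarray(p) for p in predictions])
    out = []
    for col in stacked.T:
        labels, counts = np.unique(col, return_counts=True)
        out.append(labels[np.argmax(counts)])
    return np.asarray(out)


def _fit_predict(name, config, Xtr, ytr, Xte) -> np.ndarray:
    if name == "majority_vote":
        votes = [
            _make_model(m, config).fit(Xtr, ytr).predict(Xte)
            for m in VOTE_BASE_MODELS
        ]
        return majority_vote(votes)
    return _make_model(name, config).fit(Xtr, ytr).predict(Xte)


def _fold_feature_list(features, y, subjects, train, config) -> list[str]:
    """Per-fold top features chosen without the held-out subject."""
    tbl = score_session(
        features.iloc[train], y[train], subjects[train], config.ranking
    )
    return tbl.top_features(config.n_features)


def loso_classify(
    features: pd.DataFrame,
    labels,
    subjects,
    top_features: list[str] | None = None,
    config: EvalConfig | None = None,
    session: str = "",
) -> EvalReport:
    """LOSO evaluation of one model on one session's feature table.

    In ``paper`` mode the single ``top_features`` list is used in every
    fold; in ``nested`` mode (default) the list is re-derived per fold
    from the fold's training subjects only, which avoids selection
    leakage.  Metrics are computed over per-trial predictions unless
    ``per_subject_vote`` aggregates each held-out subject's trials by
    majority first.
    """
    config = config or EvalConfig()
    config.validate()
    y = np.asarray(labels)
    subj = np.asarray(subjects)
    classes = np.unique(y)
    if config.positive_class not in classes:
        raise ConfigurationError(
            f"positive_class '{config.positive_class}' absent from labels"
        )
    if config.mode == "paper":
        if top_features is None:
            raise ConfigurationError("paper mode requires an explicit top_features list")
        missing = [f for f in top_features if f not in features.columns]
        if missing:
            raise ConfigurationError(f"top_features not in schema: {missing}")

    rows = []
    for held_out, train, test in loso_folds(subj):
        if len(np.unique(y[train])) < 2:
            raise EvaluationError(
                f"training fold for subject {held_out} has a single class"
            )
        if config.mode == "nested":
            fold_feats = _fold_feature_list(features, y, subj, train, config)
        else:
            fold_feats = top_features[: config.n_features]
        Xtr = features.iloc[train][fold_feats].to_numpy(dtype=float)
        Xte = features.iloc[test][fold_feats].to_numpy(dtype=float)
        scaler = StandardScaler().fit(Xtr)
        pred = _fit_predict(
            config.model, config, scaler.transform(Xtr), y[train],
            scaler.transform(Xte),
        )
        for idx, p in zip(test, pred):
            rows.append({"subject_id": subj[idx], "truth": y[idx], "predicted": p})

    log = pd.DataFrame(rows)
    if config.per_subject_vote:
        agg = []
        for sid, grp in log.groupby("subject_id", sort=False):
            labels_, counts_ = np.unique(grp["predicted"], return_counts=True)
            agg.append({
                "subject_id": sid,
                "truth": grp["truth"].iloc[0],
                "predicted": labels_[np.argmax(counts_)],
            })
        log = pd.DataFrame(agg)

    pos = config.positive_class
    truth_pos = log["truth"].to_numpy() == pos
    pred_pos = log["predicted"].to_numpy() == pos
    tp = int(np.sum(truth_pos & pred_pos))
    fp = int(np.sum(~truth_pos & pred_pos))
    tn = int(np.sum(~truth_pos & ~pred_pos))
    fn = int(np.sum(truth_pos & ~pred_pos))
    return EvalReport(
        session=session, model=config.model,
        tp=tp, fp=fp, tn=tn, fn=fn, predictions=log,
    )


def mmse_auc(mmse_scores, labels, positive_class: str = "MCI") -> float:
    """AUC of the rank rule "lower MMSE implies the positive class".

    Equivalent to the AUC of -MMSE as a score; ties are handled by
    midranks (identical scores for everyone give exactly 0.5).
    """
    scores = np.asarray(mmse_scores, dtype=float)
    y = np.asarray(labels)
    if len(scores) != len(y):
        raise ConfigurationError("scores and labels must align")
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUC undefined for single-class labels")
    return float(roc_auc_score(y == positive_class, -scores))
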