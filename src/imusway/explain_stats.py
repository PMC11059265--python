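"""Shapley attribution, ranking overlap, demographics ANOVA and group summaries.

Shapley values are computed for an arbitrary prediction function against a
background sample using interventional value functions
``v(S) = E_b[ f(x_S, b_{S^c}) ]``:

* ``exact`` — full coalition enumeration (tractable up to 12 features);
  satisfies efficiency/local accuracy to machine precision.
* ``monte_carlo`` — seeded permutation sampling with one background row
  per permutation; converges to the exact values as permutations grow.

The demographics comparison is a one-way fixed-effects ANOVA, available
both on raw values and on (n, mean, sd) summaries, with binary variables
encoded 0/1 before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import CapacityError, ConfigurationError, EvaluationError
from .feature_ranking import FeatureScoreTable

__all__ = [
    "AttributionSummary",
    "GroupSummary",
    "shapley_attribution",
    "rank_overlap",
    "group_anova",
    "group_anova_summary",
    "group_summary",
]

EXACT_MAX_FEATURES = 12


@dataclass
class AttributionSummary:
    """Per-sample, per-feature Shapley values for one fitted model."""

    values: np.ndarray            # (n_samples, n_features)
    base_value: float             # mean background prediction
    feature_names: list[str]
    model_id: str = ""
    session: str = ""
    method: str = ""

    @property
    def mean_abs(self) -> pd.Series:
        return pd.Series(
            np.mean(np.abs(self.values), axis=0),
            index=self.feature_names,
            name="mean_abs_shap",
        )

    def top_features(self, k: int) -> list[str]:
        s = self.mean_abs
        order = np.lexsort((np.arange(len(s)), -s.to_numpy()))
        return [self.feature_names[i] for i in order[:k]]


@dataclass
class GroupSummary:
    """Tukey boxplot statistics per feature per group with direction flags."""

    stats: pd.DataFrame           # (feature, group) -> median/q1/q3/whiskers/n
    direction: pd.Series          # per feature: 'MCI>CN' | 'MCI<CN' | 'none'


def _prediction_fn(model):
    if callable(model) and not hasattr(model, "predict"):
        return model
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, -1]
    if hasattr(model, "decision_function"):
        return lambda X: np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict"):
        return lambda X: np.asarray(model.predict(X), dtype=float)
    raise ConfigurationError("model exposes no prediction function")


def _shapley_exact(fn, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    n, p = X.shape
    nb = background.shape[0]
    if p > EXACT_MAX_FEATURES:
        raise CapacityError(
            f"exact enumeration supports <= {EXACT_MAX_FEATURES} features "
            f"(got {p}); use method='monte_carlo'"
        )
    subsets = []
    for size in range(p + 1):
        subsets.extend(combinations(range(p), size))
    index = {s: i for i, s in enumerate(subsets)}

    # v[s, i]: background-averaged prediction with subset s from sample i
    v = np.empty((len(subsets), n))
    for s_idx, s in enumerate(subsets):
        z = np.repeat(background, n, axis=0)          # (nb*n, p)
        if s:
            cols = list(s)
            tiled = np.tile(X[:, cols], (nb, 1))
            z[:, cols] = tiled
        preds = fn(z).reshape(nb, n)
        v[s_idx] = preds.mean(axis=0)

    w = {size: factorial(size) * factorial(p - size - 1) / factorial(p)
         for size in range(p)}
    phi = np.zeros((n, p))
    for s in subsets:
        if len(s) == p:
            continue
        s_set = set(s)
        for i in range(p):
            if i in s_set:
                continue
            s_with = tuple(sorted(s_set | {i}))
            phi[:, i] += w[len(s)] * (v[index[s_with]] - v[index[s]])
    return phi


def _shapley_monte_carlo(
    fn, X: np.ndarray, background: np.ndarray,
    n_permutations: int, seed, chunk: int | None = None,
) -> np.ndarray:
    n, p = X.shape
    if chunk is None:
        # cap the staged-matrix buffer at ~2^22 floats (32 MB)
        chunk = max(1, min(512, 2**22 // max(1, (p + 1) * n * p)))
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.stack([rng.permutation(p) for _ in range(m)])
        bg_rows = background[rng.integers(0, background.shape[0], size=m)]
        # stage t holds the first t features of the permutation from x
        stages = np.empty((m, p + 1, n, p))
        for j in range(m):
            z = np.repeat(bg_rows[j][None, :], n, axis=0)
            stages[j, 0] = z
            for t, feat in enumerate(perms[j]):
                z = z.copy()
                z[:, feat] = X[:, feat]
                stages[j, t + 1] = z
        preds = fn(stages.reshape(-1, p)).reshape(m, p + 1, n)
        deltas = np.diff(preds, axis=1)               # (m, p, n)
        for j in range(m):
            for t, feat in enumerate(perms[j]):
                phi[:, feat] += deltas[j, t]
        done += m
    return phi / n_permutations


def shapley_attribution(
    model,
    X,
    background,
    method: str = "auto",
    n_permutations: int = 2000,
    seed: int = 0,
    feature_names: list[str] | None = None,
    model_id: str = "",
    session: str = "",
) -> AttributionSummary:
    """Shapley attribution of ``model``'s predictions on ``X``.

    ``method``: 'exact' (coalition enumeration, <= 12 features),
    'monte_carlo' (seeded permutation sampling) or 'auto' (exact when
    tractable).  ``model`` may be a fitted classifier/regressor or a bare
    prediction callable.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(background, pd.DataFrame):
        background = background.to_numpy(dtype=float)
    else:
        background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ConfigurationError("background sample must be non-empty")
    if background.shape[1] != X.shape[1]:
        raise ConfigurationError("background and X feature counts differ")
    feature_names = feature_names or [f"f{i}" for i in range(X.shape[1])]

    fn = _prediction_fn(model)
    if method == "auto":
        method = "exact" if X.shape[1] <= EXACT_MAX_FEATURES else "monte_carlo"
    if method == "exact":
        phi = _shapley_exact(fn, X, background)
    elif method == "monte_carlo":
        phi = _shapley_monte_carlo(fn, X, background, n_permutations, seed)
    else:
        raise ConfigurationError(f"unknown method '{method}'")

    base = float(np.mean(fn(background)))
    return AttributionSummary(
        values=phi, base_value=base, feature_names=feature_names,
        model_id=model_id, session=session, method=method,
    )


def rank_overlap(
    attribution: AttributionSummary, scores: FeatureScoreTable, k: int
) -> dict:
    """Overlap between top-k by mean |Shapley| and top-k by final score."""
    names = attribution.feature_names
    if set(names) != set(scores.features):
        raise ConfigurationError("attribution and score table schemas differ")
    if not 1 <= k <= len(names):
        raise ConfigurationError(f"k must lie in [1, {len(names)}], got {k}")
    top_shap = set(attribution.top_features(k))
    top_score = set(scores.top_features(k))
    inter = top_shap & top_score
    union = top_shap | top_score
    membership = pd.DataFrame(
        {
            "in_shap_topk": [n in top_shap for n in names],
            "in_score_topk": [n in top_score for n in names],
        },
        index=names,
    )
    return {
        "k": k,
        "overlap": len(inter),
        "jaccard": len(inter) / len(union) if union else 0.0,
        "shared": sorted(inter),
        "membership": membership,
    }


def group_anova(values_a, values_b) -> tuple[float, float]:
    """One-way two-group ANOVA on raw values; returns (F, p).

    Zero within-group variance with equal means gives (0, 1) by
    convention; with unequal means, (inf, 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise EvaluationError("each group needs at least 2 values")
    return group_anova_summary(
        len(a), float(np.mean(a)), float(np.std(a, ddof=1)),
        len(b), float(np.mean(b)), float(np.std(b, ddof=1)),
    )


def group_anova_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """One-way two-group ANOVA reconstructed from (n, mean, sd) summaries.

    Between/within sums of squares are rebuilt from the summaries (sample
    sd, n-1 denominator); F = MSB/MSW with p from F(1, n1+n2-2).
    """
    if n1 < 2 or n2 < 2:
        raise EvaluationError("each group needs n >= 2")
    n = n1 + n2
    grand = (n1 * mean1 + n2 * mean2) / n
    ssb = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ssw = (n1 - 1) * sd1**2 + (n2 - 1) * sd2**2
    df_w = n - 2
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ssb / 1.0) / (ssw / df_w)
    p = float(spstats.f.sf(f_stat, 1, df_w))
    return float(f_stat), p


def demographics_table(
    subjects: pd.DataFrame,
    variables=("mmse", "age", "sex", "height_cm", "weight_kg", "education_yr"),
) -> pd.DataFrame:
    """Per-variable group means/SDs and two-group ANOVA p-values.

    Binary variables (sex) are 0/1-encoded (male = 1) before analysis.
    """
    rows = []
    groups = subjects.groupby("group")
    if len(groups) != 2:
        raise EvaluationError("demographics table needs exactly 2 groups")
    (ga, dfa), (gb, dfb) = sorted(groups, key=lambda kv: kv[0])
    for var in variables:
        a = dfa[var]
        b = dfb[var]
        if a.dtype == object:
            a = (a == "M").astype(float)
            b = (b == "M").astype(float)
        f_stat, p = group_anova(a.to_numpy(float), b.to_numpy(float))
        rows.append({
            "variable": var,
            f"mean_{ga}": float(np.mean(a)), f"sd_{ga}": float(np.std(a, ddof=1)),
            f"mean_{gb}": float(np.mean(b)), f"sd_{gb}": float(np.std(b, ddof=1)),
            "F": f_stat, "p_value": p,
        })
    return pd.DataFrame(rows)


def group_summary(
    features: pd.DataFrame, labels, positive: str = "MCI", negative: str = "CN"
) -> GroupSummary:
    """Tukey boxplot statistics per feature per group, plus per-feature
    median-direction flags."""
    y = np.asarray(labels)
    rows = []
    directions = {}
    for grp in (negative, positive):
        sub = features.loc[y == grp]
        if len(sub) == 0:
            raise EvaluationError(f"group '{grp}' is empty")
        for feat in features.columns:
            x = sub[feat].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            lo_candidates = x[x >= q1 - 1.5 * iqr]
            hi_candidates = x[x <= q3 + 1.5 * iqr]
            rows.append({
                "feature": feat, "group": grp, "n": len(x),
                "median": med, "q1": q1, "q3": q3,
                "whisker_lo": float(np.min(lo_candidates)),
                "whisker_hi": float(np.max(hi_candidates)),
            })
    stats = pd.DataFrame(rows).set_index(["feature", "group"])
    for feat in features.columns:
        m_pos = stats.loc[(feat, positive), "median"]
        m_neg = stats.loc[(feat, negative), "median"]
        if m_pos > m_neg:
            directions[feat] = f"{positive}>{negative}"
        elif m_pos < m_neg:
            directions[feat] = f"{positive}<{negative}"
        else:
            directions[feat] = "none"
    return GroupSummary(
        stats=stats, direction=pd.Series(directions, name="direction")
    )
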