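"""Response prediction: ROC analysis and backward-elimination logistic model.

Per-feature diagnostic performance is summarised by the empirical ROC
curve. The AUC is the Mann-Whitney pair-counting probability
P(score_pos > score_neg) + tie/2; its 95% CI uses the DeLong
structural-components variance. The reported cutoff maximises the Youden
index J = sensitivity + specificity - 1 (smallest threshold on ties), with
the decision direction (``>`` or ``<=``) oriented so AUC >= 0.5, matching
how diagnostic cutoffs are conventionally tabulated.

Feature combination follows the study design: features passing the
univariate gate enter a logistic regression; backward elimination removes
the least significant feature (largest Wald p > alpha, likelihood-ratio
variant behind a flag) until all retained features are significant. The
combined predictor is the fitted probability, scored with the same ROC
machinery. Paired AUCs on the same subjects are compared with the DeLong
test for correlated ROC curves. All performance is apparent (in-sample) —
no train/test split — mirroring the study design this pipeline emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ROCResult",
    "LogisticModel",
    "roc_analysis",
    "compare_auc_delong",
    "select_features_backward",
    "predict_probabilities",
    "roc_curve_points",
]


@dataclass(frozen=True)
class ROCResult:
    """Apparent ROC performance of one score."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    direction: str  # ">" or "<=": rule that predicts the positive class
    sensitivity: float  # percent
    specificity: float  # percent
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class LogisticModel:
    """Backward-eliminated logistic combination of texture features."""

    features: tuple[str, ...]
    params: dict[str, float]  # includes "intercept"; log-odds scale
    probabilities: np.ndarray
    trace: tuple[dict, ...]  # (step, removed, p_value) per elimination
    intercept_only: bool
    separation_warning: bool


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components (Sun & Xu midrank algorithm).

    Returns (auc, v10 per positive, v01 per negative)."""
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.size, neg.size
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    var10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    var01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return var10 / v10.size + var01 / v01.size


def roc_analysis(scores, labels, confidence: float = 0.95) -> ROCResult:
    """Empirical ROC of a score against a binary response label.

    The decision direction is ``>`` when higher scores indicate the
    positive class (raw AUC >= 0.5) and ``<=`` otherwise; the AUC is
    reported on the oriented scale so it is always >= 0.5. The cutoff is
    the Youden-optimal threshold among observed score values (smallest on
    ties) and the reported sensitivity/specificity are attained by
    re-applying that cutoff to the data.
    """
    scores = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    if scores.size != y.size:
        raise ValueError("scores and labels must align")
    auc_raw, v10, v01 = _delong_components(scores, y)
    direction = ">" if auc_raw >= 0.5 else "<="
    if direction == ">":
        auc = auc_raw
    else:
        auc = 1.0 - auc_raw
        v10, v01 = 1.0 - v10, 1.0 - v01
    se = float(np.sqrt(_auc_variance(v10, v01)))
    z = stats.norm.ppf(0.5 + confidence / 2)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)

    pos = scores[y]
    neg = scores[~y]
    best = None
    for t in np.unique(scores):
        if direction == ">":
            sens = (pos > t).mean()
            spec = (neg <= t).mean()
        else:
            sens = (pos <= t).mean()
            spec = (neg > t).mean()
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, cutoff, sens, spec = best
    return ROCResult(
        auc=float(auc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        cutoff=float(cutoff),
        direction=direction,
        sensitivity=float(100.0 * sens),
        specificity=float(100.0 * spec),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """FPR/TPR coordinates of the empirical ROC curve (for plotting)."""
    scores = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.concatenate([[0], np.cumsum(ys)])
    fps = np.concatenate([[0], np.cumsum(~ys)])
    return pd.DataFrame({"fpr": fps / fps[-1], "tpr": tps / tps[-1]})


def compare_auc_delong(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Paired DeLong test for two correlated ROC curves on the same subjects.

    Returns ``(auc_a, auc_b, difference, two-sided p)``. Identical scores
    give difference 0 and p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _check_labels(labels)
    if sa.size != sb.size or sa.size != y.size:
        raise ValueError("score vectors and labels must align")
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    diff = auc_a - auc_b
    var = _auc_variance(v10a - v10b, v01a - v01b)
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        zstat = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(zstat)))
    return float(auc_a), float(auc_b), float(diff), p


def _fit_logit(y: np.ndarray, exog):
    """Binomial GLM fit (IRLS with pseudo-inverse linear algebra, which
    tolerates the near-collinear feature sets texture parameters produce)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=100)


def _wald_pvalues(result) -> pd.Series:
    return result.pvalues.drop("const", errors="ignore")


def _lr_pvalues(result, X: pd.DataFrame, y, feats: list[str]) -> pd.Series:
    """Likelihood-ratio p-value for dropping each feature in turn."""
    out = {}
    for f in feats:
        reduced = [g for g in feats if g != f]
        exog = sm.add_constant(X[reduced], has_constant="add")
        red = _fit_logit(y, exog)
        lr = 2 * (result.llf - red.llf)
        out[f] = stats.chi2.sf(max(lr, 0.0), df=1)
    return pd.Series(out)


def select_features_backward(
    X: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    criterion: str = "wald",
) -> LogisticModel:
    """Backward-elimination logistic regression over candidate features.

    Starting from the full model, the feature with the largest
    p-value > ``alpha`` is removed (Wald by default, ``criterion="lr"``
    for likelihood-ratio) until every retained feature is significant or
    none remain — in which case the intercept-only model is returned and
    flagged. Quasi-complete separation is detected from non-convergence or
    exploding coefficients and reported as a warning naming the worst
    feature; the model is still returned.
    """
    if criterion not in ("wald", "lr"):
        raise ValueError("criterion must be 'wald' or 'lr'")
    y = _check_labels(labels).astype(float)
    if y.size < 10:
        warnings.warn(
            "fewer than 10 subjects: selection results are unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    feats = list(X.columns)
    trace: list[dict] = []
    separation = False
    step = 0
    while True:
        exog = sm.add_constant(X[feats], has_constant="add") if feats else np.ones((y.size, 1))
        result = _fit_logit(y, exog)
        if feats:
            coefs = result.params.drop("const", errors="ignore")
            eta = np.asarray(exog) @ np.asarray(result.params)
            if np.abs(eta).max() > 25:  # fitted probabilities pinned at 0/1
                worst = coefs.abs().idxmax()
                if not separation:
                    warnings.warn(
                        f"possible complete separation involving feature {worst!r}; "
                        "coefficients are unstable",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                separation = True
        if not feats:
            break
        pvals = (
            _wald_pvalues(result)
            if criterion == "wald"
            else _lr_pvalues(result, X, y, feats)
        )
        pvals = pvals.fillna(1.0)
        worst_feat = pvals.idxmax()
        if pvals[worst_feat] <= alpha:
            break
        step += 1
        trace.append(
            {"step": step, "removed": worst_feat, "p_value": float(pvals[worst_feat])}
        )
        feats.remove(worst_feat)

    if feats:
        params = {"intercept": float(result.params["const"])}
        params.update({f: float(result.params[f]) for f in feats})
        probs = np.asarray(result.predict())
    else:
        p0 = float(y.mean())
        p0 = min(max(p0, 1e-12), 1 - 1e-12)
        params = {"intercept": float(np.log(p0 / (1 - p0)))}
        probs = np.full(y.size, p0)
    return LogisticModel(
        features=tuple(feats),
        params=params,
        probabilities=probs,
        trace=tuple(trace),
        intercept_only=not feats,
        separation_warning=separation,
    )


def predict_probabilities(model: LogisticModel, X: pd.DataFrame | None = None) -> np.ndarray:
    """Inverse-logit of the model's linear predictor on new data.

    With ``X=None`` the in-sample fitted probabilities are returned.
    """
    if X is None:
        return model.probabilities
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    eta = np.full(len(X), model.params["intercept"], dtype=float)
    for f in model.features:
        eta += model.params[f] * X[f].to_numpy(dtype=float)
    return 1.0 / (1.0 + np.exp(-eta))
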