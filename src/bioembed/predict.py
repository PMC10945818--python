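"""Elastic-net prediction of early-life habitat quality from methylation.

The classifier asks whether the birth cohort (born before vs after the
home-range shift) can be read back out of adult methylation fractions.
Training uses leave-one-out cross-validation: for each held-out sample an
elastic net is fitted to all remaining samples, with the penalty strength
chosen by inner k-fold cross-validation, and the held-out sample's signed
linear predictor is recorded (positive = predicted born in the low-quality,
pre-shift habitat).  Accuracy is summarised by the ROC curve and its AUC
(the Mann-Whitney statistic).  For low-quality-born animals, ordinary
least squares of the prediction score on time since the habitat shift
tests whether the epigenetic signature of early life attenuates with
temporal distance from the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

LOW, HIGH = "low", "high"


def _prepare_features(
    fractions: np.ndarray, max_missing: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Drop sites missing in > max_missing of samples; keep the site mask.

    Remaining missing entries are left as NaN; imputation happens inside
    each training fold to avoid leakage.
    """
    frac = np.asarray(fractions, dtype=float)
    keep = np.isnan(frac).mean(axis=1) <= max_missing
    return frac[keep], keep


def loo_elastic_net(
    fractions: np.ndarray,
    labels: list[str] | np.ndarray,
    sample_ids: list[str] | None = None,
    mixing: float = 0.5,
    n_penalties: int = 50,
    inner_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out elastic-net habitat prediction.

    Parameters
    ----------
    fractions
        sites x samples matrix of methylation fractions (NaN = missing).
    labels
        Per-sample habitat-at-birth labels, "low" or "high".
    mixing
        Elastic-net mixing weight (1 = lasso, 0 = ridge).
    n_penalties
        Size of the log-spaced penalty grid searched by inner CV.
    seed
        Controls the inner CV fold assignment (the only randomness).

    Returns
    -------
    DataFrame with one row per sample: sample_id, true_label, score, fold.
    Scores are signed linear predictors; positive = predicted low-quality
    (pre-shift) birth.
    """
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if not classes <= {LOW, HIGH} or len(classes) < 2:
        raise ValueError("labels must contain both 'low' and 'high'")
    n = labels.size
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    y = np.where(labels == LOW, 1.0, -1.0)

    X_all, _ = _prepare_features(fractions)
    X_all = X_all.T  # samples x sites

    scores = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        Xtr, ytr = X_all[train], y[train]
        # fold-internal imputation and standardization (no leakage)
        col_mean = np.nanmean(Xtr, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        Xtr = np.where(np.isnan(Xtr), col_mean, Xtr)
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        if mixing > 1e-3:
            alphas = n_penalties  # size of the auto log-spaced penalty grid
        else:
            # pure ridge has no finite lasso-style alpha_max; build the
            # grid from the l1 alpha_max at a small nominal mixing
            amax = np.abs(Xtr.T @ ytr).max() / (len(ytr) * 0.01)
            alphas = np.geomspace(amax * 1e-4, amax, n_penalties)
        model = ElasticNetCV(
            l1_ratio=mixing,
            alphas=alphas,
            cv=cv,
            max_iter=1000,
            tol=1e-3,
        )
        model.fit(Xtr, ytr)
        xte = X_all[i]
        xte = np.where(np.isnan(xte), col_mean, xte)
        xte = (xte - mu) / sd
        # centered linear predictor: the intercept is the training-fold
        # class balance, whose leave-one-out fluctuation anti-correlates
        # with the held-out label and would bias a null model's ranking
        scores[i] = float(xte @ model.coef_)

    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "true_label": labels,
            "score": scores,
            "fold": np.arange(n),
        }
    )


def roc_auc(
    scores: np.ndarray, labels: list[str] | np.ndarray
) -> tuple[float, pd.DataFrame]:
    """AUC as the Mann-Whitney statistic (ties count 0.5) plus ROC points.

    "low" is the positive class.  ROC points are computed at every distinct
    score threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == LOW]
    neg = scores[labels != LOW]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # Mann-Whitney U via rank sums; ties get half credit
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    auc = float(u / (pos.size * neg.size))

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    pts = []
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        pts.append((t, fpr, tpr))
    curve = pd.DataFrame(pts, columns=["threshold", "fpr", "tpr"])
    return auc, curve


@dataclass
class AttenuationResult:
    """OLS slope of prediction score on a time variable."""

    variable: str
    slope: float
    se: float
    t: float
    p: float
    n: int


def _ols_slope(y: np.ndarray, x: np.ndarray, name: str) -> AttenuationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"regressor {name!r} is constant")
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    tstat = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(tstat), dof))
    return AttenuationResult(name, float(beta[1]), se, tstat, p, n)


def attenuation_test(
    predictions: pd.DataFrame,
    days_since_shift: np.ndarray,
    cumulative_days_low: np.ndarray,
    age: np.ndarray | None = None,
) -> dict[str, AttenuationResult]:
    """Temporal attenuation of the habitat signature.

    Restricted to low-quality-born samples: regresses the prediction score
    separately on (i) days since the habitat shift and (ii) cumulative days
    spent in low-quality habitat.  Optionally also runs the age-vs-habitat
    control regression.
    """
    scores = predictions["score"].to_numpy(dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 low-quality-born samples")
    out = {
        "days_since_shift": _ols_slope(scores, days_since_shift, "days_since_shift"),
        "cumulative_days_low": _ols_slope(
            scores, cumulative_days_low, "cumulative_days_low"
        ),
    }
    if age is not None:
        out["age"] = _ols_slope(scores, age, "age")
    return out
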