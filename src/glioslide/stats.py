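"""Inferential layer: permutation nulls, concordance, survival models,
classification summaries, and rank tests.

Permutation tests shuffle labels at the patient level and use the add-one
estimator p = (1 + #{null >= observed}) / (1 + n_perm), which is never
exactly zero and is super-uniform under the null.  Proportional-hazards
fitting and Kaplan-Meier curves delegate to lifelines; ROC/confusion
summaries delegate to scikit-learn.  Harrell's concordance index is
computed here directly from its pair definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int
    alternative: str = "greater"
    null_values: np.ndarray | None = None


def permutation_test(metric_fn, predictions, labels, n_perm: int = 999,
                     seed: int = 0, alternative: str = "greater",
                     keep_null: bool = False) -> PermutationResult:
    """Label-shuffling permutation test for a prediction metric.

    ``metric_fn(predictions, labels)`` must be a pure function; the null
    distribution is built by re-evaluating it on independently shuffled
    copies of ``labels``.  ``alternative="greater"`` suits accuracy-type
    metrics (observed should exceed the null), ``"less"`` suits error-type
    metrics such as MSE.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(metric_fn(predictions, labels))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = metric_fn(predictions, rng.permutation(labels))
    if alternative == "greater":
        extreme = int((null >= observed).sum())
    else:
        extreme = int((null <= observed).sum())
    return PermutationResult(
        observed=observed, null_mean=float(null.mean()),
        null_sd=float(null.std()), p_value=(1 + extreme) / (1 + n_perm),
        n_perm=n_perm, seed=seed, alternative=alternative,
        null_values=null if keep_null else None)


def harrell_c(times, events, scores) -> float:
    """Harrell's concordance index for right-censored data.

    Comparable pairs are (i, j) with t_i < t_j and an event at i; a pair is
    concordant when score_i > score_j, and tied scores count one half.
    Higher scores are interpreted as higher risk (shorter survival).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    s = np.asarray(scores, float)
    if not (len(t) == len(e) == len(s)):
        raise ValueError("length mismatch")
    # pair (i, j) comparable iff t_i < t_j and event at i
    comp = (t[:, None] < t[None, :]) & e[:, None]
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = (s[:, None] > s[None, :]) & comp
    ties = (s[:, None] == s[None, :]) & comp
    return (int(conc.sum()) + 0.5 * int(ties.sum())) / n_comp


def km_logrank(times, events, group):
    """Kaplan-Meier curves per group plus a two-group log-rank test.

    Returns ``(curves, statistic, p_value)`` where ``curves`` maps group
    label -> DataFrame with columns ``time`` and ``survival`` (the
    product-limit estimate, starting at S(0) = 1).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(group)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"expected 2 groups, got {len(labels)}")
    curves = {}
    for lab in labels:
        sel = g == lab
        if e[sel].sum() < 1:
            raise ValueError(f"group {lab!r} has no events")
        km = KaplanMeierFitter().fit(t[sel], e[sel])
        sf = km.survival_function_
        curves[lab] = pd.DataFrame({
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float)})
    a, b = labels
    res = logrank_test(t[g == a], t[g == b], e[g == a], e[g == b])
    return curves, float(res.test_statistic), float(res.p_value)


def cox_ph_fit(covariates: pd.DataFrame, times, events) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    Returns hazard ratios with 95% Wald confidence intervals and p-values.
    Supports univariable and multivariable tables (e.g. age, sex, treatment
    and a continuous risk score together).
    """
    X = pd.DataFrame(covariates).reset_index(drop=True)
    if (X.nunique() <= 1).any():
        bad = X.columns[X.nunique() <= 1].tolist()
        raise ValueError(f"constant covariates: {bad}")
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    if int(e.sum()) < X.shape[1]:
        raise ValueError("fewer events than covariates")
    df = X.copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    return pd.DataFrame({
        "covariate": s.index,
        "hr": s["exp(coef)"].to_numpy(),
        "hr_lo": s["exp(coef) lower 95%"].to_numpy(),
        "hr_hi": s["exp(coef) upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)


def classification_report(true_labels, score_matrix, classes=None):
    """One-vs-rest ROC AUCs, confusion matrix and accuracy.

    ``score_matrix`` has one column per class in ``classes`` order (default:
    sorted unique true labels).  The confusion matrix and accuracy use
    argmax calls.  A class absent from the truth gets AUC NaN and is listed
    under ``"undefined_auc"``.
    """
    y = np.asarray(true_labels)
    S = np.asarray(score_matrix, float)
    if classes is None:
        classes = sorted(np.unique(y).tolist())
    classes = list(classes)
    if len([c for c in classes if (y == c).any()]) < 2:
        raise ValueError("need at least 2 classes present in the truth")
    aucs, undefined = {}, []
    for ci, c in enumerate(classes):
        pos = (y == c).astype(int)
        if pos.min() == pos.max():
            aucs[c] = float("nan")
            undefined.append(c)
            continue
        fpr, tpr, _ = roc_curve(pos, S[:, ci])
        aucs[c] = float(roc_auc_score(pos, S[:, ci]))
    pred = np.asarray(classes, object)[S.argmax(axis=1)]
    cm = _sk_confusion(y, pred, labels=classes)
    return {
        "classes": classes,
        "auc": aucs,
        "undefined_auc": undefined,
        "confusion": cm,
        "accuracy": float((pred == y).mean()),
    }


def rank_tests(*samples, paired: bool = False):
    """Nonparametric location tests, two-sided.

    Two samples: Mann-Whitney U (unpaired) or Wilcoxon signed-rank
    (paired).  Three or more: Kruskal-Wallis.  Returns (statistic, p).
    """
    samples = [np.asarray(s, float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if len(samples) > 2:
        if paired:
            raise ValueError("paired comparison is defined for two samples")
        res = sps.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    a, b = samples
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        if np.all(a == b):
            raise ValueError("all paired differences are zero")
        res = sps.wilcoxon(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
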