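"""Diagnostic and prognostic evaluation of a hub-miRNA signature.

Given a candidate signature (e.g. the hub miRNAs of the modulation
network), this module quantifies:

* **diagnostic value** — cross-validated accuracy of a linear
  maximum-margin classifier (SVM) restricted to the signature's rows,
  referenced against a null of random same-size miRNA signatures;
* **structure** — PCA coordinates and hierarchical/k-means groupings of
  samples in signature space;
* **prognostic value** — a two-group k-means risk split with Kaplan–Meier
  curves, a log-rank test and proportional-hazards fits (group hazard
  ratio with Wald CI, plus per-miRNA univariate and joint multivariate
  coefficients);
* **differential expression** — per-feature fold change with a
  label-permutation p-value and Benjamini–Hochberg q.

The SVM protocol is fixed (linear kernel, C=1, stratified 5-fold CV) and
recorded in the returned metadata; published comparisons rarely state the
protocol, so fixing one is a prerequisite for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .io import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "ClassifierNullResult",
    "SurvivalResult",
    "classifier_accuracy",
    "random_signature_null",
    "pca_view",
    "cluster_samples",
    "survival_analysis",
    "differential_expression",
]

SVM_PROTOCOL = {"kernel": "linear", "C": 1.0, "cv": "stratified k-fold", "folds": 5}


@dataclass
class Signature:
    """An ordered list of unique miRNA identifiers."""

    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.mirna_ids = [str(m) for m in self.mirna_ids]
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("signature contains duplicate miRNA ids")
        if not self.mirna_ids:
            raise ValueError("signature is empty")

    def __len__(self) -> int:
        return len(self.mirna_ids)

    def resolve(self, expr: ExpressionMatrix) -> np.ndarray:
        """Samples × signature-features matrix from ``expr``."""
        missing = [m for m in self.mirna_ids if m not in expr]
        if missing:
            raise KeyError(f"signature miRNAs absent from matrix: {missing}")
        return expr.subset_features(self.mirna_ids).values.T


@dataclass
class ClassifierNullResult:
    """Signature classifier accuracy against a random-signature null."""

    signature_accuracy: float
    null_mean_accuracy: float
    null_accuracies: np.ndarray
    empirical_p: float
    protocol: dict = field(default_factory=lambda: dict(SVM_PROTOCOL))


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}: {classes}")
    return y


def classifier_accuracy(
    expr: ExpressionMatrix,
    labels,
    sig: Signature,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified cross-validated accuracy of a linear SVM on the signature rows."""
    y = _binary_labels(labels)
    if len(y) != expr.n_samples:
        raise ValueError("labels length must match sample count")
    X = sig.resolve(expr)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = SVC(kernel="linear", C=1.0)
    return float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())


def random_signature_null(
    expr: ExpressionMatrix,
    labels,
    k: int,
    n_lists: int,
    cv_folds: int = 5,
    seed: int = 0,
    sig: Optional[Signature] = None,
) -> ClassifierNullResult:
    """Accuracy null from ``n_lists`` uniform random k-subsets of all miRNA rows.

    The empirical p-value of the signature's accuracy uses the add-one rule
    p = (1 + #{null ≥ observed}) / (n_lists + 1) and can therefore never be
    exactly zero.
    """
    if n_lists < 1:
        raise ValueError("n_lists must be >= 1")
    if sig is None:
        raise ValueError("a signature to evaluate must be provided")
    if expr.n_features - len(sig) < k:
        raise ValueError(
            f"need at least k={k} non-signature rows, have "
            f"{expr.n_features - len(sig)}"
        )
    observed = classifier_accuracy(expr, labels, sig, cv_folds, seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_lists)
    all_ids = np.array(expr.feature_ids)
    for i in range(n_lists):
        random_sig = Signature(list(rng.choice(all_ids, size=k, replace=False)))
        null[i] = classifier_accuracy(expr, labels, random_sig, cv_folds, seed)
    empirical_p = (1 + int(np.sum(null >= observed))) / (n_lists + 1)
    return ClassifierNullResult(
        signature_accuracy=observed,
        null_mean_accuracy=float(null.mean()),
        null_accuracies=null,
        empirical_p=empirical_p,
    )


def pca_view(expr: ExpressionMatrix, sig: Signature):
    """Sample coordinates on the first three PCs of the signature-restricted,
    feature-centered matrix, plus explained variance ratios.

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so output is deterministic.
    """
    if len(sig) < 3:
        raise ValueError("need at least 3 signature features for a 3-component view")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    X = sig.resolve(expr)
    pca = PCA(n_components=3, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    for c in range(3):
        lead = np.argmax(np.abs(pca.components_[c]))
        if pca.components_[c, lead] < 0:
            pca.components_[c] *= -1.0
            coords[:, c] *= -1.0
    return coords, pca.explained_variance_ratio_


def cluster_samples(
    expr: ExpressionMatrix,
    sig: Signature,
    method: str = "kmeans",
    n_groups: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Group samples in signature space.

    ``hierarchical`` is average linkage on Euclidean distance cut into
    ``n_groups``; ``kmeans`` uses 50 restarts under a fixed seed.  Returns
    integer labels in 0..n_groups−1.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_groups > expr.n_samples:
        raise ValueError("n_groups cannot exceed the number of samples")
    X = sig.resolve(expr)
    if method == "kmeans":
        km = KMeans(n_clusters=n_groups, n_init=50, random_state=seed)
        return km.fit_predict(X).astype(int)
    if method == "hierarchical":
        Z = linkage(X, method="average", metric="euclidean")
        return (fcluster(Z, t=n_groups, criterion="maxclust") - 1).astype(int)
    raise ValueError("method must be 'kmeans' or 'hierarchical'")


@dataclass
class SurvivalResult:
    """Two-group risk stratification with KM, log-rank and Cox summaries.

    ``groups`` is 1 for the high-risk (low signature expression) group.
    """

    groups: np.ndarray
    km_curves: dict[int, pd.DataFrame]
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    cox_group_p: float
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    multivariate_converged: bool


def survival_analysis(
    expr: ExpressionMatrix,
    sig: Signature,
    meta: SampleMetadata,
    seed: int = 0,
) -> SurvivalResult:
    """Prognostic evaluation of a signature by two-group risk stratification.

    Samples are split by k-means (two groups, 50 restarts) on the signature
    rows; the group with the lower mean signature expression is labelled
    high-risk (group 1).  Reports Kaplan–Meier curves per group, the
    log-rank test, the group hazard ratio with Wald 95% CI from a Cox
    proportional-hazards fit, and univariate plus multivariate per-miRNA
    Cox coefficients.  A non-convergent multivariate fit is flagged, not
    fatal.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.exceptions import ConvergenceError
    from lifelines.statistics import logrank_test

    if not meta.has_survival:
        raise ValueError("metadata has no time_to_event/event_flag columns")
    if meta.sample_ids != expr.sample_ids:
        raise ValueError("metadata and expression samples must be aligned")
    time = meta.time_to_event
    event = meta.event_flag
    if int(event.sum()) < 10:
        raise ValueError(f"need at least 10 events, got {int(event.sum())}")

    X = sig.resolve(expr)
    raw = cluster_samples(expr, sig, method="kmeans", n_groups=2, seed=seed)
    # orient: group 1 = lower mean signature expression = high risk
    means = [X[raw == g].mean() for g in (0, 1)]
    groups = (raw == int(np.argmin(means))).astype(int)
    for g in (0, 1):
        in_g = groups == g
        if not in_g.any():
            raise ValueError("risk split produced an empty group")
        if np.max(time[in_g]) == 0:
            raise ValueError(
                f"degenerate survival input: all follow-up times in group {g} are 0"
            )

    km_curves = {}
    for g in (0, 1):
        kmf = KaplanMeierFitter()
        kmf.fit(time[groups == g], event[groups == g], label=f"group{g}")
        km_curves[g] = kmf.survival_function_

    lr = logrank_test(
        time[groups == 1], time[groups == 0], event[groups == 1], event[groups == 0]
    )

    df = pd.DataFrame({"time": time, "event": event.astype(int), "group": groups})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["group"]
    hazard_ratio = float(s["exp(coef)"])
    hr_ci = (float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"]))
    cox_group_p = float(s["p"])

    uni_rows = []
    for i, mirna in enumerate(sig.mirna_ids):
        dfi = pd.DataFrame({"time": time, "event": event.astype(int), "x": X[:, i]})
        fit = CoxPHFitter()
        try:
            fit.fit(dfi, duration_col="time", event_col="event")
            row = fit.summary.loc["x"]
            uni_rows.append(
                (mirna, float(row["coef"]), float(row["exp(coef)"]),
                 float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"]),
                 float(row["p"]), True)
            )
        except ConvergenceError:
            uni_rows.append((mirna, *([float("nan")] * 5), False))
    univariate = pd.DataFrame(
        uni_rows,
        columns=["mirna", "coef", "hr", "hr_lower95", "hr_upper95", "p", "converged"],
    )

    multi_df = pd.DataFrame(X, columns=sig.mirna_ids)
    multi_df["time"] = time
    multi_df["event"] = event.astype(int)
    multi_fit = CoxPHFitter(penalizer=0.0)
    converged = True
    try:
        multi_fit.fit(multi_df, duration_col="time", event_col="event")
        multivariate = multi_fit.summary.reset_index()[["covariate", "coef", "p"]]
    except ConvergenceError:
        converged = False
        logger.warning("multivariate Cox fit did not converge; coefficients NaN")
        multivariate = pd.DataFrame(
            {"covariate": sig.mirna_ids,
             "coef": np.nan,
             "p": np.nan}
        )

    return SurvivalResult(
        groups=groups,
        km_curves=km_curves,
        logrank_p=float(lr.p_value),
        hazard_ratio=hazard_ratio,
        hr_ci=hr_ci,
        cox_group_p=cox_group_p,
        univariate=univariate,
        multivariate=multivariate,
        multivariate_converged=converged,
    )


def differential_expression(
    expr: ExpressionMatrix,
    labels,
    case,
    control,
    log_scale: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature fold change (case/control) with permutation p and BH q.

    With ``log_scale=True`` inputs are treated as log2 expression and the
    fold change is 2^(Δmean); otherwise it is the ratio of class means,
    which requires positive means.  The p-value permutes class labels and
    compares |Δmean|; it obeys the add-one lower bound 1/(n_perm+1).
    """
    from statsmodels.stats.multitest import multipletests

    y = np.asarray(labels)
    case_idx = np.flatnonzero(y == case)
    ctrl_idx = np.flatnonzero(y == control)
    if len(case_idx) < 3 or len(ctrl_idx) < 3:
        raise ValueError("each class needs at least 3 samples")
    X = expr.values[:, np.concatenate([ctrl_idx, case_idx])]
    n_ctrl = len(ctrl_idx)
    n_tot = X.shape[1]

    mean_ctrl = X[:, :n_ctrl].mean(axis=1)
    mean_case = X[:, n_ctrl:].mean(axis=1)
    if log_scale:
        fold = 2.0 ** (mean_case - mean_ctrl)
    else:
        if np.any(mean_ctrl <= 0) or np.any(mean_case <= 0):
            raise ValueError(
                "nonpositive class means under ratio mode; pass log_scale=True "
                "for log-expression inputs"
            )
        fold = mean_case / mean_ctrl
    observed = np.abs(mean_case - mean_ctrl)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        Xp = X[:, perm]
        stat = np.abs(Xp[:, n_ctrl:].mean(axis=1) - Xp[:, :n_ctrl].mean(axis=1))
        exceed += stat >= observed
    p = (1 + exceed) / (n_perm + 1)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature": expr.feature_ids,
            "fold_change": fold,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "p": p,
            "q": q,
        }
    )
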