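"""Developmental staging of embryos from exponential-model features.

Embryos are classified into the three main early stages (cleavage,
syncytial blastoderm, cc14 cellularization) by linear discriminant analysis
on the four profile features (lambda1 apical, lambda1 basal, cab,
shallow_ratio).  Evaluation is by confusion matrix under resubstitution,
leave-one-out, or stratified k-fold; small samples make leave-one-out the
honest default.  Group differences are tested by label-permutation tests
(distribution-free, suited to small n); the mean-feature trajectory across
the nine age sub-groups traces the developmental dynamics at a finer
timescale.

Rows with a missing shallow_ratio are excluded from classification (never
imputed) and their count is logged.  Prediction ties are broken by the
fixed developmental label order cleavage < syncytial < cc14.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .expfit import FeatureVector
from .synthetic import MAIN_STAGES, SUBGROUPS

__all__ = [
    "StageClassifier",
    "ConfusionMatrix",
    "fit_lda",
    "predict_stage",
    "evaluate",
    "subgroup_trajectory",
    "test_group_difference",
    "STAGE_ORDER",
]

log = logging.getLogger(__name__)

#: Fixed developmental label order, also the prediction tie-break order.
STAGE_ORDER = list(MAIN_STAGES)


def _order_labels(labels: list[str]) -> list[str]:
    """Known stages in developmental order first, others alphabetically."""
    known = [s for s in STAGE_ORDER if s in labels]
    extra = sorted(set(labels) - set(STAGE_ORDER))
    return known + extra


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    if isinstance(features, pd.DataFrame):
        return features[list(FeatureVector.FEATURE_NAMES)].to_numpy(dtype=float)
    return np.array([fv.as_array() for fv in features], dtype=float)


@dataclass
class StageClassifier:
    """A fitted equal-covariance Gaussian (LDA) stage classifier."""

    labels: list[str]
    class_means: np.ndarray  # (k, p)
    pooled_cov: np.ndarray  # (p, p)
    priors: np.ndarray  # (k,)
    scalings: np.ndarray  # discriminant directions, (p, k-1)
    shrinkage_used: bool = False
    _lda: LinearDiscriminantAnalysis = field(repr=False, default=None)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def fit_lda(features, labels) -> StageClassifier:
    """Fit LDA with empirical class priors and pooled covariance.

    ``features`` may be an (n, 4) array, a features DataFrame, or a list of
    FeatureVector.  Rows containing NaN (typically a missing shallow_ratio)
    are dropped with a log message.  A numerically singular pooled
    covariance triggers a shrinkage (Ledoit-Wolf) refit, also logged.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=object)
    keep = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d rows with missing feature values", n_dropped)
    X, y = X[keep], y[keep]

    classes = _order_labels(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    p = X.shape[1]
    for cls in classes:
        if int((y == cls).sum()) <= p:
            raise ValueError(
                f"class {cls!r} needs more members than features ({p})"
            )

    lda = LinearDiscriminantAnalysis(solver="svd", store_covariance=True)
    lda.fit(X, y)
    cov = lda.covariance_
    shrunk = False
    # scale-invariant singularity check: LDA itself is affine-invariant, so
    # wildly different feature scales alone must not trigger shrinkage
    d = np.sqrt(np.clip(np.diag(cov), 0, None))
    d = np.where(d > 0, d, 1.0)
    corr = cov / np.outer(d, d)
    if not np.all(np.isfinite(corr)) or np.linalg.cond(corr) > 1e10:
        log.info("singular pooled covariance; refitting with shrinkage")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
        cov = getattr(lda, "covariance_", cov)
        shrunk = True

    # reorder per-class summaries into developmental order
    idx = [list(lda.classes_).index(cls) for cls in classes]
    counts = np.array([(y == cls).sum() for cls in classes], dtype=float)
    return StageClassifier(
        labels=classes,
        class_means=lda.means_[idx],
        pooled_cov=cov,
        priors=counts / counts.sum(),
        scalings=getattr(lda, "scalings_", np.empty((p, 0))),
        shrinkage_used=shrunk,
        _lda=lda,
    )


def predict_stage(clf: StageClassifier, features):
    """Predict stage labels and per-class discriminant scores.

    Accepts a single feature vector or an (n, 4) batch.  Returns
    ``(labels, scores)`` where ``scores`` are log-posterior-proportional
    discriminant values ordered as ``clf.labels``; the argmax (first on
    ties, i.e. earlier developmental stage) gives the label.  NaN features
    are rejected.
    """
    X = _as_matrix(features) if not isinstance(features, np.ndarray) else features
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("cannot predict from missing feature values")
    raw = clf._lda.decision_function(X)
    if raw.ndim == 1:  # binary case: sklearn returns one column
        raw = np.column_stack([-raw, raw])
    idx = [list(clf._lda.classes_).index(cls) for cls in clf.labels]
    scores = raw[:, idx]
    labels = np.array([clf.labels[i] for i in np.argmax(scores, axis=1)])
    if labels.size == 1:
        return labels[0], scores[0]
    return labels, scores


@dataclass
class ConfusionMatrix:
    """Confusion counts plus per-class correct fractions."""

    labels: list[str]
    counts: np.ndarray  # counts[true, predicted]
    scheme: str = "loo"
    permutation_p: float | None = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def per_class_correct(self) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, np.diag(self.counts) / totals, np.nan)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(self.n, 1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df.index.name = "true"
        df.columns.name = "predicted"
        return df


def _predictions(X, y, classes, scheme: str, rng=None):
    """Predicted label per sample under the evaluation scheme."""
    n = X.shape[0]
    pred = np.empty(n, dtype=object)
    if scheme == "resubstitution":
        clf = fit_lda(X, y)
        labels, _ = predict_stage(clf, X)
        return np.atleast_1d(labels)
    if scheme == "loo":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif scheme == "kfold":
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        folds = list(skf.split(X, y.astype(str)))
    else:
        raise ValueError("scheme must be loo, kfold or resubstitution")
    for train, test in folds:
        if len(set(y[train])) < len(classes):
            log.warning("a class is absent from a training fold; fold skipped")
            pred[test] = None
            continue
        try:
            clf = fit_lda(X[train], y[train])
        except ValueError:
            pred[test] = None
            continue
        labels, _ = predict_stage(clf, X[test])
        pred[test] = np.atleast_1d(labels)
    return pred


def evaluate(
    features,
    labels,
    scheme: str = "loo",
    n_perm: int = 0,
    seed: int = 0,
) -> ConfusionMatrix:
    """Confusion matrix of stage prediction under a validation scheme.

    With ``n_perm > 0`` a permutation p-value for overall accuracy above
    chance is attached: labels are shuffled ``n_perm`` times and the same
    scheme re-run; p = (1 + #{perm accuracy >= observed}) / (n_perm + 1).
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=object)
    keep = np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    classes = _order_labels(sorted(set(y)))

    pred = _predictions(X, y, classes, scheme)
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p_ in zip(y, pred):
        if p_ is not None:
            counts[classes.index(t), classes.index(p_)] += 1
    cm = ConfusionMatrix(labels=classes, counts=counts, scheme=scheme)

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        obs = cm.accuracy
        hits = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            pp = _predictions(X, yp, classes, scheme)
            acc = np.mean([a == b for a, b in zip(yp, pp) if b is not None])
            if acc >= obs:
                hits += 1
        cm.permutation_p = (1 + hits) / (n_perm + 1)
    return cm


def subgroup_trajectory(features, subgroups) -> pd.DataFrame:
    """Mean feature vector per age sub-group, in developmental order.

    Empty sub-groups are omitted with a log message.  Returns a DataFrame
    indexed by sub-group with one column per feature plus the group size.
    """
    X = _as_matrix(features)
    g = np.asarray(subgroups, dtype=object)
    rows = []
    for name in SUBGROUPS:
        sel = g == name
        if not sel.any():
            log.info("sub-group %s empty; omitted from trajectory", name)
            continue
        means = np.nanmean(X[sel], axis=0)
        rows.append({"subgroup": name, "n": int(sel.sum()),
                     **dict(zip(FeatureVector.FEATURE_NAMES, means))})
    extra = sorted(set(g) - set(SUBGROUPS))
    for name in extra:
        sel = g == name
        means = np.nanmean(X[sel], axis=0)
        rows.append({"subgroup": name, "n": int(sel.sum()),
                     **dict(zip(FeatureVector.FEATURE_NAMES, means))})
    return pd.DataFrame(rows).set_index("subgroup")


def _between_group_stat(X: np.ndarray, y: np.ndarray, groups) -> np.ndarray:
    """Per-feature sum over groups of n_g * (standardized mean shift)^2."""
    grand = np.nanmean(X, axis=0)
    pooled = np.nanvar(X, axis=0, ddof=1)
    stat = np.zeros(X.shape[1])
    for gname in groups:
        sel = y == gname
        if not sel.any():
            continue
        diff = np.nanmean(X[sel], axis=0) - grand
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = np.where(pooled > 0, diff**2 / pooled, 0.0)
        stat += sel.sum() * z2
    return stat


def test_group_difference(
    features,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation test for feature-mean differences between groups.

    The statistic is, per feature, the between-group sum of squared
    standardized mean differences (weighted by group size); the omnibus
    statistic sums it over features.  p-values are
    (1 + #{perm >= observed}) / (n_perm + 1) under label shuffling.
    Identical groups therefore give p ~ 1, never 0.
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a coarse p-value resolution", stacklevel=2)
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=object)
    groups = _order_labels(sorted(set(y)))
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    obs = _between_group_stat(X, y, groups)
    obs_omni = obs.sum()
    rng = np.random.default_rng(seed)
    hits = np.zeros(X.shape[1])
    hits_omni = 0
    for _ in range(n_perm):
        stat = _between_group_stat(X, rng.permutation(y), groups)
        hits += stat >= obs - 1e-12
        hits_omni += stat.sum() >= obs_omni - 1e-12
    p = (1 + hits) / (n_perm + 1)
    out = pd.Series(p, index=list(FeatureVector.FEATURE_NAMES)[: X.shape[1]])
    out["omnibus"] = (1 + hits_omni) / (n_perm + 1)
    return out
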