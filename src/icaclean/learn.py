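"""Feature selection and classification.

The selection chain mirrors how the component classifier is built: features
are standardized; a Linear Programming Machine (an L1-regularized
soft-margin linear classifier solved as a linear program, which yields
sparse weights) is trained in repeated stratified cross-validation to rank
features by their mean normalized absolute weight; the number of top-ranked
features is the smallest whose cross-validation error is within one standard
error of the minimum; and the final classifier is a regularized Linear
Discriminant Analysis whose pooled covariance is shrunk toward a scaled
identity with the analytic (Ledoit-Wolf) shrinkage intensity.

The classification error used throughout is the mean 0/1 loss of the sign
predictions (conventionally reported as a percentage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import StratifiedKFold

from .core_io import TrainedModel

DEFAULT_C = 0.1
DEFAULT_FOLDS = 10
DEFAULT_REPEATS = 5
RELEVANCE_THRESHOLD = 0.1   # |mean(w_i / ||w||_1)| above this counts a feature


@dataclass
class LabeledFeatureSet:
    """Components x features matrix with +-1 labels (+1 = artifact)."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing values")
        if set(np.unique(self.labels)) - {-1.0, 1.0}:
            raise ValueError("labels must be +-1")
        if self.features.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("features, labels and feature_names are inconsistent")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, labels: np.ndarray
                   ) -> "LabeledFeatureSet":
        return cls(features=frame.to_numpy(), labels=labels,
                   feature_names=list(frame.columns))

    def select(self, names: list[str]) -> "LabeledFeatureSet":
        idx = [self.feature_names.index(n) for n in names]
        return LabeledFeatureSet(self.features[:, idx], self.labels, list(names))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def fit_standardizer(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and standard deviation of the training data."""
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    bad = np.where(sigma <= 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance feature(s) at column(s) {bad.tolist()}")
    return mu, sigma


def apply_standardizer(features: np.ndarray, mu: np.ndarray,
                       sigma: np.ndarray) -> np.ndarray:
    return (np.asarray(features, dtype=float) - mu) / sigma


# ---------------------------------------------------------------------------
# Linear Programming Machine
# ---------------------------------------------------------------------------

def train_lpm(x: np.ndarray, y: np.ndarray, C: float = DEFAULT_C
              ) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact LP optimum of the L1 soft-margin problem.

    minimize  (1/n) * sum_i xi_i + C * ||w||_1
    s.t.      y_i (w . x_i + b) >= 1 - xi_i,   xi >= 0

    solved with the weight split into nonnegative parts.  C is the sparsity
    knob: larger C zeroes more features.  Returns (w, b, slacks).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = x.shape
    # variables: w+ (d), w- (d), b+ , b-, xi (n)
    cost = np.concatenate([np.full(2 * d, C), [0.0, 0.0], np.full(n, 1.0 / n)])
    yx = y[:, None] * x
    a_ub = np.hstack([-yx, yx, -y[:, None], y[:, None], -np.eye(n)])
    b_ub = -np.ones(n)
    res = linprog(cost, A_ub=a_ub, b_ub=b_ub,
                  bounds=[(0, None)] * (2 * d + 2) + [(0, None)] * n,
                  method="highs")
    if not res.success:
        raise RuntimeError(f"LPM linear program failed: {res.message}")
    sol = res.x
    w = sol[:d] - sol[d:2 * d]
    b = sol[2 * d] - sol[2 * d + 1]
    slacks = sol[2 * d + 2:]
    return w, float(b), slacks


def zero_one_error(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean 0/1 loss of sign predictions (ties count as +1)."""
    pred = np.where(np.asarray(scores) >= 0, 1.0, -1.0)
    return float(np.mean(pred != np.asarray(labels)))


# ---------------------------------------------------------------------------
# Cross-validation machinery
# ---------------------------------------------------------------------------

def _cv_splits(labels: np.ndarray, folds: int, repeats: int, seed: int):
    """Stratified folds, repeated with distinct shuffles; deterministic."""
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError(
            f"cannot build {folds} stratified folds: smallest class has "
            f"{counts.min()} members"
        )
    states = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    for state in states:
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(state))
        yield from skf.split(np.zeros(len(labels)), labels)


def _fold_lpm(fset: LabeledFeatureSet, train, test, C: float
              ) -> tuple[np.ndarray, float]:
    """Train LPM on one fold; return normalized weights and test error."""
    mu, sigma = fit_standardizer(fset.features[train])
    xtr = apply_standardizer(fset.features[train], mu, sigma)
    xte = apply_standardizer(fset.features[test], mu, sigma)
    w, b, _ = train_lpm(xtr, fset.labels[train], C)
    norm = np.sum(np.abs(w))
    w_norm = w / norm if norm > 0 else w
    err = zero_one_error(xte @ w + b, fset.labels[test])
    return w_norm, err


def select_C(fset: LabeledFeatureSet, candidates: list[float],
             folds: int = DEFAULT_FOLDS, repeats: int = DEFAULT_REPEATS,
             seed: int = 0) -> float:
    """One-standard-error sparsity heuristic for the LPM hyperparameter.

    Among candidates whose cross-validation error is within one standard
    error of the minimum, pick the one using the fewest relevant features
    (|mean normalized weight| > 0.1).
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    errors, ses, n_relevant = [], [], []
    for C in candidates:
        ws, errs = [], []
        for train, test in _cv_splits(fset.labels, folds, repeats, seed):
            w_norm, err = _fold_lpm(fset, train, test, C)
            ws.append(w_norm)
            errs.append(err)
        errs = np.array(errs)
        errors.append(errs.mean())
        ses.append(errs.std(ddof=1) / np.sqrt(len(errs)))
        score = np.abs(np.mean(ws, axis=0))
        n_relevant.append(int(np.sum(score > RELEVANCE_THRESHOLD)))
    errors = np.array(errors)
    i_min = int(np.argmin(errors))
    admissible = np.where(errors <= errors[i_min] + ses[i_min])[0]
    best = min(admissible, key=lambda i: (n_relevant[i], errors[i], i))
    return float(candidates[best])


@dataclass
class RankingResult:
    """Feature ranking by mean normalized absolute LPM weight."""

    feature_names: list[str]
    scores: np.ndarray                      # |mean(w_i / ||w||_1)| per feature
    order: np.ndarray                       # indices, descending score
    cv_sizes: np.ndarray | None = None
    cv_error_mean: np.ndarray | None = None
    cv_error_se: np.ndarray | None = None
    chosen_size: int | None = None

    @property
    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]


def rank_features_cv(fset: LabeledFeatureSet, C: float = DEFAULT_C,
                     folds: int = DEFAULT_FOLDS,
                     repeats: int = DEFAULT_REPEATS,
                     seed: int = 0) -> RankingResult:
    """Rank features by |E(w_i / ||w||_1)| over repeated stratified CV.

    Ties are broken by canonical feature order.
    """
    ws = [
        _fold_lpm(fset, train, test, C)[0]
        for train, test in _cv_splits(fset.labels, folds, repeats, seed)
    ]
    scores = np.abs(np.mean(ws, axis=0))
    order = np.lexsort((np.arange(len(scores)), -scores))
    return RankingResult(feature_names=list(fset.feature_names),
                         scores=scores, order=order)


def choose_feature_count(ranking: RankingResult, fset: LabeledFeatureSet,
                         classifier_kind: str = "rlda",
                         C: float = DEFAULT_C,
                         folds: int = DEFAULT_FOLDS,
                         repeats: int = DEFAULT_REPEATS,
                         seed: int = 0) -> int:
    """Smallest feature count within one SE of the minimal CV error.

    For every rank position r the classifier is cross-validated on the top-r
    features; the chosen size is the smallest whose mean error deviates less
    than one standard error (of the minimum) from the minimal error.  The
    full error-vs-size curve is stored on ``ranking``.
    """
    d = len(ranking.feature_names)
    splits = list(_cv_splits(fset.labels, folds, repeats, seed))
    means, ses = [], []
    for r in range(1, d + 1):
        cols = ranking.order[:r]
        sub = LabeledFeatureSet(fset.features[:, cols], fset.labels,
                                [fset.feature_names[i] for i in cols])
        errs = []
        for train, test in splits:
            mu, sigma = fit_standardizer(sub.features[train])
            xtr = apply_standardizer(sub.features[train], mu, sigma)
            xte = apply_standardizer(sub.features[test], mu, sigma)
            if classifier_kind == "rlda":
                w, b, _ = train_rlda(xtr, sub.labels[train])
            elif classifier_kind == "lpm":
                w, b, _ = train_lpm(xtr, sub.labels[train], C)
            else:
                raise ValueError(f"unknown classifier kind {classifier_kind!r}")
            errs.append(zero_one_error(xte @ w + b, sub.labels[test]))
        errs = np.array(errs)
        means.append(errs.mean())
        ses.append(errs.std(ddof=1) / np.sqrt(len(errs)))
    means = np.array(means)
    ses = np.array(ses)
    i_min = int(np.argmin(means))
    chosen = int(np.where(means <= means[i_min] + ses[i_min])[0][0]) + 1
    ranking.cv_sizes = np.arange(1, d + 1)
    ranking.cv_error_mean = means
    ranking.cv_error_se = ses
    ranking.chosen_size = chosen
    return chosen


# ---------------------------------------------------------------------------
# Regularized LDA
# ---------------------------------------------------------------------------

def train_rlda(x: np.ndarray, y: np.ndarray,
               shrinkage: float | None = None
               ) -> tuple[np.ndarray, float, float]:
    """LDA with the pooled covariance shrunk toward nu * I.

    ``shrinkage=None`` uses the analytic Ledoit-Wolf intensity (nu is the
    mean eigenvalue of the empirical pooled covariance); passing a value in
    [0, 1] forces it.  Returns (w, b, gamma); the bias places the decision
    boundary midway between the projected class means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("train_rlda needs exactly two classes")
    mu_pos = x[y > 0].mean(axis=0)
    mu_neg = x[y < 0].mean(axis=0)
    centered = x.copy()
    centered[y > 0] -= mu_pos
    centered[y < 0] -= mu_neg
    n, d = x.shape
    emp = centered.T @ centered / n
    nu = np.trace(emp) / d
    if shrinkage is None:
        _, gamma = ledoit_wolf(centered, assume_centered=True)
    else:
        gamma = float(shrinkage)
    cov = (1.0 - gamma) * emp + gamma * nu * np.eye(d)
    w = np.linalg.solve(cov, mu_pos - mu_neg)
    b = -0.5 * float(w @ (mu_pos + mu_neg))
    return w, b, float(gamma)


# ---------------------------------------------------------------------------
# Prediction and full training
# ---------------------------------------------------------------------------

def predict(model: TrainedModel, features: pd.DataFrame | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Scores and +-1 labels (+1 = artifact) for a feature table."""
    if isinstance(features, pd.DataFrame):
        missing = [n for n in model.feature_names if n not in features.columns]
        if missing:
            raise ValueError(f"feature table is missing {missing}")
        x = features[model.feature_names].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.shape[1] != len(model.feature_names):
            raise ValueError("feature matrix width != model feature count")
    scores = apply_standardizer(x, model.mu, model.sigma) @ model.w + model.b
    return scores, np.where(scores >= 0, 1.0, -1.0)


def artifact_probability(scores: np.ndarray) -> np.ndarray:
    """Logistic squashing of the linear score (a convention, not a paper
    quantity): a surrogate for the probability of being an artifact."""
    return 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=float)))


def train_component_classifier(fset: LabeledFeatureSet,
                               classifier_kind: str = "rlda",
                               C: float = DEFAULT_C,
                               folds: int = DEFAULT_FOLDS,
                               repeats: int = DEFAULT_REPEATS,
                               seed: int = 0,
                               select_features: bool = True) -> TrainedModel:
    """Full training chain: rank features, pick the count, fit the model."""
    if select_features:
        ranking = rank_features_cv(fset, C, folds, repeats, seed)
        size = choose_feature_count(ranking, fset, classifier_kind, C,
                                    folds, repeats, seed)
        names = ranking.ranked_names[:size]
        sub = fset.select(names)
    else:
        names = list(fset.feature_names)
        sub = fset
    mu, sigma = fit_standardizer(sub.features)
    xs = apply_standardizer(sub.features, mu, sigma)
    if classifier_kind == "rlda":
        w, b, gamma = train_rlda(xs, sub.labels)
        meta = {"shrinkage": gamma}
    elif classifier_kind == "lpm":
        w, b, _ = train_lpm(xs, sub.labels, C)
        meta = {"C": C}
    else:
        raise ValueError(f"unknown classifier kind {classifier_kind!r}")
    meta["n_train"] = len(sub.labels)
    return TrainedModel(feature_names=names, mu=mu, sigma=sigma, w=w, b=b,
                        classifier_kind=classifier_kind, metadata=meta)
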