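"""QSPR modeling: cross-validated kernel regression, consensus averaging,
Gaussian outlier filtering and a stratified-bagging decomposition classifier.

The regression learner is an RBF-kernel support-vector machine (the
LibSVM-style parameters C, γ and ε), validated by fivefold cross
validation: each fold's model is trained on 4/5 of the rows and predicts
the held-out 20 %, so every row receives exactly one out-of-fold
prediction; the final model is refit on all rows.

Consensus predictions combine several member models (typically trained on
different descriptor sets) by a simple average, an RMSE-weighted average,
or a linear stack fitted on the members' out-of-fold predictions; the
standard deviation of member predictions serves as the distance-to-model
(CONSENSUS-STD), an applicability-domain measure.

Outlier filtering assumes residuals are N(0, σ) with σ equal to the model
RMSE: for a chosen two-sided tail probability p, residuals beyond
z(p)·σ are outliers, N·p are expected by chance, and the observed/expected
ratio is the signal-to-noise ratio (SNR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm
from sklearn.base import clone
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from .features import SparseDescriptorMatrix

__all__ = [
    "SVMParams",
    "CVResult",
    "ConsensusModel",
    "OutlierReport",
    "BaggingResult",
    "rmse",
    "balanced_accuracy",
    "fivefold_cv",
    "grid_search",
    "build_consensus",
    "consensus_predict",
    "consensus_cv",
    "filter_outliers",
    "expected_outliers",
    "stratified_bagging_classify",
]


@dataclass(frozen=True)
class SVMParams:
    """RBF-kernel SVM regression parameters (LibSVM convention)."""

    C: float = 256.0
    gamma: float = 1.0
    epsilon: float = 16.0

    def __post_init__(self):
        if not (self.C > 0 and self.gamma > 0 and self.epsilon >= 0):
            raise ValueError("C and gamma must be positive, epsilon >= 0")

    def make_estimator(self) -> SVR:
        return SVR(kernel="rbf", C=self.C, gamma=self.gamma,
                   epsilon=self.epsilon)


@dataclass
class CVResult:
    fold_assignment: np.ndarray
    oof_predictions: np.ndarray
    rmse: float
    rmse_se: float
    final_model: object
    params: Optional[SVMParams] = None


@dataclass
class ConsensusModel:
    members: List[Tuple[object, float]]  # (fitted model handle, CV RMSE)
    strategy: str  # "simple" | "weighted" | "mlra"
    stack_coefficients: Optional[np.ndarray] = None
    stack_intercept: float = 0.0


@dataclass
class OutlierReport:
    sigma: float
    p: float
    z_threshold: float
    threshold_c: float
    expected_count: float
    observed_count: int
    snr: float
    outlier_rows: np.ndarray


@dataclass
class BaggingResult:
    models: List[object]
    bag_indices: List[np.ndarray]
    classes: Tuple[object, object]  # (majority, minority)
    oob_probability: np.ndarray  # probability of the minority class
    oob_prediction: np.ndarray
    balanced_accuracy: float


def _as_matrix(X):
    if isinstance(X, SparseDescriptorMatrix):
        return X.matrix
    if sp.issparse(X):
        return X
    return np.asarray(X, dtype=float)


def rmse(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    yt, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


def balanced_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Mean of per-class recalls (= (sensitivity + specificity)/2 for two
    classes)."""
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    recalls = [np.mean(yp[yt == c] == c) for c in np.unique(yt)]
    return float(np.mean(recalls))


def fivefold_cv(
    X,
    y: Sequence[float],
    params: Optional[SVMParams] = None,
    seed: int = 0,
    model_factory: Optional[Callable[[], object]] = None,
    n_folds: int = 5,
) -> CVResult:
    """Fivefold cross validation of a kernel regression model.

    Fold membership is a uniform random permutation controlled by ``seed``.
    Returns out-of-fold predictions for every row, the CV RMSE with a
    standard error from the fold-to-fold spread, and a final model fit on
    all rows.
    """
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = yv.shape[0]
    if n < 2 * n_folds:
        raise ValueError(f"too few rows for {n_folds} folds")
    if model_factory is None:
        if params is None:
            raise ValueError("provide SVMParams or a model factory")
        model_factory = params.make_estimator

    folds = np.empty(n, dtype=int)
    oof = np.empty(n, dtype=float)
    fold_rmses = []
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k, (train, test) in enumerate(splitter.split(np.arange(n))):
        model = clone(model_factory())
        model.fit(Xm[train], yv[train])
        pred = model.predict(Xm[test])
        folds[test] = k
        oof[test] = pred
        fold_rmses.append(rmse(yv[test], pred))
    final = clone(model_factory())
    final.fit(Xm, yv)
    return CVResult(
        fold_assignment=folds,
        oof_predictions=oof,
        rmse=rmse(yv, oof),
        rmse_se=float(np.std(fold_rmses, ddof=1) / np.sqrt(n_folds)),
        final_model=final,
        params=params,
    )


def grid_search(
    X,
    y: Sequence[float],
    grid: Sequence[SVMParams],
    fraction: float = 1.0,
    seed: int = 0,
) -> SVMParams:
    """Select (C, γ, ε) by cross validation on a random data fraction.

    Every triple of the user-supplied grid is scored by fivefold CV on the
    same random subset of rows; the argmin-RMSE triple wins, ties resolving
    to the smallest C, then γ, then ε.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = yv.shape[0]
    if fraction < 1.0:
        rng = np.random.default_rng(seed)
        m = max(10, int(round(fraction * n)))
        rows = rng.choice(n, size=min(m, n), replace=False)
        Xm, yv = Xm[rows], yv[rows]

    scored = []
    for params in grid:
        result = fivefold_cv(Xm, yv, params=params, seed=seed)
        scored.append((result.rmse, params.C, params.gamma, params.epsilon,
                       params))
    scored.sort(key=lambda t: t[:4])
    return scored[0][4]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def build_consensus(
    member_results: Sequence[CVResult],
    y: Optional[Sequence[float]] = None,
    strategy: str = "simple",
) -> ConsensusModel:
    """Assemble a consensus model from cross-validated members.

    The ``mlra`` strategy fits a multiple linear regression on the members'
    out-of-fold predictions (requires ``y``); ``simple`` and ``weighted``
    need only the member RMSEs.
    """
    if not member_results:
        raise ValueError("need at least one member model")
    members = [(r.final_model, r.rmse) for r in member_results]
    stack_coef, stack_int = None, 0.0
    if strategy == "mlra":
        if y is None:
            raise ValueError("mlra stacking requires the training target")
        P = np.column_stack([r.oof_predictions for r in member_results])
        reg = LinearRegression().fit(P, np.asarray(y, float))
        stack_coef, stack_int = reg.coef_.copy(), float(reg.intercept_)
    elif strategy not in ("simple", "weighted"):
        raise ValueError(f"unknown strategy {strategy!r}")
    return ConsensusModel(members=members, strategy=strategy,
                          stack_coefficients=stack_coef,
                          stack_intercept=stack_int)


def consensus_predict(
    member_predictions: Sequence[np.ndarray],
    strategy: str = "simple",
    member_rmses: Optional[Sequence[float]] = None,
    stack_coefficients: Optional[np.ndarray] = None,
    stack_intercept: float = 0.0,
    printed_normalization: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Combine member predictions; returns (prediction, distance-to-model).

    * ``simple``  — unweighted mean.
    * ``weighted`` — Σ wᵢyᵢ / Σ wᵢ with wᵢ = 1/RMSEᵢ, which reduces to the
      simple average when all member RMSEs are equal.  The alternative
      normalization by sqrt(Σ wᵢ²) is available via
      ``printed_normalization`` but lacks that reduction property.
    * ``mlra``    — linear stack with the supplied coefficients.

    The distance-to-model is the standard deviation of the member
    predictions for each input (CONSENSUS-STD); it is 0 for one member.
    """
    P = np.asarray(member_predictions, dtype=float)
    if P.ndim == 1:  # one scalar prediction per member
        P = P[:, None]
    n_members = P.shape[0]
    if n_members == 0:
        raise ValueError("need at least one member prediction")
    if strategy == "simple":
        pred = P.mean(axis=0)
    elif strategy == "weighted":
        if member_rmses is None:
            raise ValueError("weighted consensus requires member RMSEs")
        w = 1.0 / np.asarray(member_rmses, dtype=float)
        if printed_normalization:
            pred = (w[:, None] * P).sum(axis=0) / np.sqrt(np.sum(w ** 2))
        else:
            pred = (w[:, None] * P).sum(axis=0) / w.sum()
    elif strategy == "mlra":
        if stack_coefficients is None:
            raise ValueError("mlra consensus requires stack coefficients")
        pred = stack_intercept + np.asarray(stack_coefficients) @ P
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if n_members == 1:
        distance = np.zeros(P.shape[1])
    else:
        distance = P.std(axis=0, ddof=1)
    return pred, distance


def consensus_cv(
    feature_sets: Sequence,
    y: Sequence[float],
    params: Optional[SVMParams] = None,
    seed: int = 0,
    strategy: str = "simple",
    model_factory: Optional[Callable[[], object]] = None,
) -> Tuple[ConsensusModel, List[CVResult], np.ndarray, float]:
    """Train one member per descriptor set with shared folds and combine.

    All members use the same seed, hence identical fold assignments, so the
    member out-of-fold predictions align row-wise and the consensus
    out-of-fold RMSE is a valid cross-validated estimate.  Returns the
    consensus model, the member CV results, the consensus out-of-fold
    predictions and their RMSE.
    """
    results = [fivefold_cv(X, y, params=params, seed=seed,
                           model_factory=model_factory)
               for X in feature_sets]
    model = build_consensus(results, y=y, strategy=strategy)
    preds = [r.oof_predictions for r in results]
    oof, _ = consensus_predict(
        preds, strategy=strategy,
        member_rmses=[r.rmse for r in results],
        stack_coefficients=model.stack_coefficients,
        stack_intercept=model.stack_intercept,
    )
    return model, results, oof, rmse(y, oof)


# ---------------------------------------------------------------------------
# Gaussian outlier filtering
# ---------------------------------------------------------------------------

def expected_outliers(n: int, p: float) -> float:
    """Number of residuals beyond the two-sided p-tail expected by chance."""
    return n * p


def filter_outliers(
    residuals: Sequence[float], sigma: float, p: float
) -> OutlierReport:
    """Flag residuals incompatible with the Gaussian error null N(0, σ).

    ``p`` is the two-sided tail probability: the threshold z solves
    2·(1 − Φ(z)) = p, residuals with |r| > z·σ are outliers, N·p of them
    are expected by chance, and SNR = observed/expected.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < p < 0.5:
        raise ValueError("p must be in (0, 0.5)")
    r = np.asarray(residuals, dtype=float)
    z = float(norm.isf(p / 2.0))
    threshold = z * sigma
    rows = np.flatnonzero(np.abs(r) > threshold)
    expected = expected_outliers(r.size, p)
    observed = int(rows.size)
    return OutlierReport(
        sigma=float(sigma), p=float(p), z_threshold=z, threshold_c=threshold,
        expected_count=expected, observed_count=observed,
        snr=observed / expected if expected > 0 else float("inf"),
        outlier_rows=rows,
    )


# ---------------------------------------------------------------------------
# Stratified bagging for the decompose-vs-melt classifier
# ---------------------------------------------------------------------------

def _default_learners(seed: int) -> List[object]:
    # kernel learner + decision tree: diverse members for the consensus vote
    return [SVC(kernel="rbf", gamma="scale", C=1.0),
            DecisionTreeClassifier(random_state=seed)]


def stratified_bagging_classify(
    X,
    labels: Sequence,
    n_models: int = 64,
    base_learners: Optional[Sequence[object]] = None,
    seed: int = 0,
) -> BaggingResult:
    """Stratified-bagging classifier for heavily imbalanced binary labels.

    Each of the ``n_models`` bags resamples the minority class with
    replacement to its own size and subsamples the majority class (without
    replacement) to the same size, so every bag holds 2×minority rows with
    equal class counts.  A row's prediction averages the votes of the bags
    whose training set excluded it (out-of-bag); rows present in every bag
    fall back to the all-bags average.  Balanced accuracy is the mean of
    the per-class recalls of the out-of-bag predictions.
    """
    Xm = _as_matrix(X)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() == 0:
        raise ValueError("need two non-empty classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    m = min_idx.size

    rng = np.random.default_rng(seed)
    learners = list(base_learners) if base_learners else _default_learners(seed)

    models: List[object] = []
    bags: List[np.ndarray] = []
    votes = np.zeros(y.size, dtype=float)
    n_votes = np.zeros(y.size, dtype=int)
    all_votes = np.zeros(y.size, dtype=float)
    for b in range(n_models):
        take_min = rng.choice(min_idx, size=m, replace=True)
        take_maj = rng.choice(maj_idx, size=m, replace=False)
        bag = np.concatenate([take_min, take_maj])
        model = clone(learners[b % len(learners)])
        if "random_state" in model.get_params():
            model.set_params(random_state=int(rng.integers(2 ** 31 - 1)))
        model.fit(Xm[bag], y[bag] == minority)
        vote = model.predict(Xm).astype(float)  # 1 = minority class
        in_bag = np.zeros(y.size, dtype=bool)
        in_bag[bag] = True
        votes[~in_bag] += vote[~in_bag]
        n_votes[~in_bag] += 1
        all_votes += vote
        models.append(model)
        bags.append(bag)

    prob = np.where(n_votes > 0, votes / np.maximum(n_votes, 1),
                    all_votes / n_models)
    pred = np.where(prob >= 0.5, minority, majority)
    return BaggingResult(
        models=models,
        bag_indices=bags,
        classes=(majority, minority),
        oob_probability=prob,
        oob_prediction=pred,
        balanced_accuracy=balanced_accuracy(y, pred),
    )
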