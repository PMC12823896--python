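"""Sparse logistic screening model: L1 fit, CV, calibration, thresholding.

The classifier minimizes

    J(w, b) = C * sum_i log(1 + exp(-y~_i (w . x_i + b))) + ||w||_1

with labels y~ in {-1, +1} and an unpenalized intercept — the "inverse
regularization" convention, so larger C means a weaker penalty. The solver
is proximal gradient (ISTA with Nesterov acceleration and adaptive restart):
a gradient step on the smooth loss followed by soft-thresholding of the
weights, which produces exact zeros and hence feature selection.

C is chosen by stratified K-fold cross-validation maximizing the mean
held-out AUC of raw scores; ties break toward the smaller C (stronger
sparsity). Raw scores are then calibrated to probabilities with Platt
scaling (two-parameter sigmoid, maximum likelihood with smoothed targets),
and a decision threshold is fixed on the development set as the largest
probability cutoff whose sensitivity meets the floor — the sensitivity-first
operating point for a screening tool where false negatives are the costly
error.

Features are z-scored with training-set statistics before fitting so that
coefficient magnitudes are comparable across features; development and test
data reuse the training statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import (
    ConfigError,
    DegenerateLabelsError,
    InputError,
    ShapeError,
)
from .features import FEATURE_NAMES

logger = logging.getLogger("lingscreen")

#: Default C grid: 10^-2 .. 10^2 in multiplicative steps of 10^0.2.
#: The step is chosen so the grid contains 10^-0.2 = 0.6310.
DEFAULT_C_GRID = tuple(float(10.0 ** e) for e in np.round(np.arange(-2.0, 2.0 + 1e-9, 0.2), 10))

DEFAULT_TARGET_SENSITIVITY = 0.92


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Per-feature (mean, sd) z-scoring fitted on the training split."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.scale) <= 0):
            raise ConfigError("standardizer scale must be positive")

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        # A constant column carries no information; leave it centered only.
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    @classmethod
    def identity(cls, n_features: int) -> "Standardizer":
        return cls(mean=np.zeros(n_features), scale=np.ones(n_features))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """Fitted sparse logistic weights in canonical feature order."""

    weights: np.ndarray
    intercept: float
    C: float
    standardizer: Standardizer
    feature_names: tuple[str, ...] = FEATURE_NAMES
    n_iter: int = 0

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        """Decision scores w . z(x) + b on (unstandardized) feature rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.shape[0]:
            raise ShapeError(
                f"expected {self.weights.shape[0]} feature columns, got {X.shape[1]}"
            )
        return self.standardizer.transform(X) @ self.weights + self.intercept

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass
class CvResult:
    """Cross-validation record: the grid, per-fold AUCs, and the winner."""

    grid: np.ndarray
    fold_aucs: np.ndarray  # K x |grid|
    mean_aucs: np.ndarray
    C_star: float
    K: int
    seed: int

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ConfigError("cross-validation needs K >= 2")
        best = float(np.max(self.mean_aucs))
        at_star = float(self.mean_aucs[int(np.argmin(np.abs(self.grid - self.C_star)))])
        if not np.isclose(at_star, best, atol=1e-12):
            raise ConfigError("C_star does not attain the maximal mean AUC")


@dataclass
class CalibratedModel:
    """Sparse logistic model + Platt sigmoid + fixed decision threshold.

    Calibrated probability of depression for score s is
    p = 1 / (1 + exp(platt_A * s + platt_B)); with platt_A < 0 the
    probability increases with the raw score. A transcript is flagged when
    p >= threshold (inclusive).
    """

    base: LogisticModel
    platt_A: float
    platt_B: float
    threshold: float
    target_sensitivity: float = DEFAULT_TARGET_SENSITIVITY

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ConfigError(f"threshold {self.threshold} outside (0, 1)")

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        return platt_probability(self.base.raw_scores(X), self.platt_A, self.platt_B)

    # -- serialization (bit-exact float round trip via JSON repr) ----------

    def to_json(self, extra: Optional[dict] = None) -> str:
        payload = {
            "feature_names": list(self.base.feature_names),
            "weights": self.base.weights.tolist(),
            "intercept": self.base.intercept,
            "C": self.base.C,
            "standardizer": {
                "mean": self.base.standardizer.mean.tolist(),
                "scale": self.base.standardizer.scale.tolist(),
            },
            "platt_A": self.platt_A,
            "platt_B": self.platt_B,
            "threshold": self.threshold,
            "target_sensitivity": self.target_sensitivity,
        }
        if extra:
            payload.update(extra)
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CalibratedModel":
        obj = json.loads(text)
        base = LogisticModel(
            weights=np.array(obj["weights"], dtype=float),
            intercept=float(obj["intercept"]),
            C=float(obj["C"]),
            standardizer=Standardizer(
                mean=np.array(obj["standardizer"]["mean"], dtype=float),
                scale=np.array(obj["standardizer"]["scale"], dtype=float),
            ),
            feature_names=tuple(obj["feature_names"]),
        )
        return cls(
            base=base,
            platt_A=float(obj["platt_A"]),
            platt_B=float(obj["platt_B"]),
            threshold=float(obj["threshold"]),
            target_sensitivity=float(obj["target_sensitivity"]),
        )

    def save(self, path: str | Path, extra: Optional[dict] = None) -> None:
        Path(path).write_text(self.to_json(extra), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CalibratedModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


# --------------------------------------------------------------------------
# L1 logistic fit (proximal gradient with acceleration)
# --------------------------------------------------------------------------


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ShapeError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ShapeError("X and y lengths differ")
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite values in X")
    classes = set(np.unique(y).tolist())
    if not classes <= {0, 1}:
        raise InputError(f"labels must be binary 0/1, got {sorted(classes)}")
    if len(classes) < 2:
        raise DegenerateLabelsError("both classes are required")
    return X, y.astype(int)


def _log1pexp(z: np.ndarray) -> np.ndarray:
    """log(1 + exp(z)) without overflow."""
    out = np.empty_like(z, dtype=float)
    pos = z > 0
    out[pos] = z[pos] + np.log1p(np.exp(-z[pos]))
    out[~pos] = np.log1p(np.exp(z[~pos]))
    return out


def l1_logistic_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float
) -> float:
    """J(w, b) = C * sum log(1 + exp(-y~ (Xw + b))) + ||w||_1, y~ in {-1,+1}."""
    yt = 2.0 * np.asarray(y) - 1.0
    margins = yt * (np.asarray(X) @ np.asarray(w) + b)
    return float(C * np.sum(_log1pexp(-margins)) + np.sum(np.abs(w)))


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    warm_start: Optional[tuple[np.ndarray, float]] = None,
) -> LogisticModel:
    """Fit the L1-penalized logistic regression by accelerated proximal gradient.

    ``X`` is taken as-is (standardize beforehand; the returned model carries
    an identity standardizer — the pipeline swaps in the real one).
    Converged when the largest absolute parameter change over one proximal
    step falls below ``tol``, or after ``max_iter`` iterations. Exact zeros
    in the weights are produced by the soft-thresholding step.
    """
    if C <= 0:
        raise ConfigError("C must be positive")
    X, y = _check_Xy(X, y)
    n, p = X.shape
    yt = 2.0 * y - 1.0

    # Lipschitz constant of the smooth part: C/4 * lambda_max([X 1]^T [X 1]).
    aug = np.hstack([X, np.ones((n, 1))])
    smax = np.linalg.svd(aug, compute_uv=False)[0]
    L = C * smax * smax / 4.0
    step = 1.0 / L

    if warm_start is not None:
        w = np.asarray(warm_start[0], dtype=float).copy()
        b = float(warm_start[1])
    else:
        w = np.zeros(p)
        b = 0.0
    w_prev, b_prev = w.copy(), b
    t_mom = 1.0
    zw, zb = w.copy(), b  # extrapolated point
    obj_prev = l1_logistic_objective(w, b, X, y, C)
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        margins = yt * (X @ zw + zb)
        # d/dz of C*log1pexp(-z) = -C*sigmoid(-z)
        sig = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))
        coef = -C * yt * sig
        grad_w = X.T @ coef
        grad_b = float(np.sum(coef))
        w_new = zw - step * grad_w
        # soft-threshold the weights; the intercept is unpenalized
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step, 0.0)
        b_new = zb - step * grad_b

        delta = max(float(np.max(np.abs(w_new - w))), abs(b_new - b))

        # adaptive restart: drop momentum if the objective went up
        obj_new = l1_logistic_objective(w_new, b_new, X, y, C)
        if obj_new > obj_prev + 1e-15:
            zw, zb = w.copy(), b
            t_mom = 1.0
            obj_prev = l1_logistic_objective(w, b, X, y, C)
            continue
        obj_prev = obj_new

        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom)) / 2.0
        beta = (t_mom - 1.0) / t_next
        zw = w_new + beta * (w_new - w)
        zb = b_new + beta * (b_new - b)
        t_mom = t_next
        w_prev, b_prev = w, b
        w, b = w_new, b_new
        if delta < tol:
            break
    del w_prev, b_prev

    return LogisticModel(
        weights=w,
        intercept=float(b),
        C=float(C),
        standardizer=Standardizer.identity(p),
        n_iter=n_iter,
    )


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


def stratified_kfold(y: np.ndarray, K: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns K arrays of test indices."""
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(K)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < K:
            raise ConfigError(
                f"class {cls} has {idx.size} samples, fewer than K={K} folds; "
                "use a smaller K"
            )
        idx = idx[rng.permutation(idx.size)]
        for j, i in enumerate(idx):
            folds[j % K].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def cv_select_C(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] = DEFAULT_C_GRID,
    K: int = 5,
    seed: int = 0,
) -> CvResult:
    """Select C by maximizing mean held-out AUC over stratified K folds.

    Fold AUCs are computed on raw (pre-calibration) scores — calibration is
    a monotone transform fitted later and cannot change AUC. Exact ties in
    mean AUC break toward the smaller C, preferring the sparser model. Fits
    along the grid are warm-started from the previous C for speed.
    """
    from .evaluation import roc_auc

    X, y = _check_Xy(X, y)
    grid_arr = np.asarray(sorted(grid), dtype=float)
    if grid_arr.size == 0:
        raise ConfigError("C grid is empty")
    folds = stratified_kfold(y, K, seed)
    fold_aucs = np.zeros((K, grid_arr.size))
    for k, test_idx in enumerate(folds):
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        X_tr, y_tr = X[mask], y[mask]
        X_te, y_te = X[test_idx], y[test_idx]
        warm: Optional[tuple[np.ndarray, float]] = None
        for g, C in enumerate(grid_arr):
            m = fit_l1_logistic(X_tr, y_tr, C, warm_start=warm)
            warm = (m.weights, m.intercept)
            fold_aucs[k, g] = roc_auc(m.raw_scores(X_te), y_te)
    mean_aucs = fold_aucs.mean(axis=0)
    best = np.max(mean_aucs)
    # smallest C among the exact argmax set
    C_star = float(grid_arr[np.flatnonzero(np.isclose(mean_aucs, best, atol=1e-12))[0]])
    return CvResult(
        grid=grid_arr,
        fold_aucs=fold_aucs,
        mean_aucs=mean_aucs,
        C_star=C_star,
        K=K,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Platt calibration
# --------------------------------------------------------------------------


def platt_probability(scores: np.ndarray, A: float, B: float) -> np.ndarray:
    z = A * np.asarray(scores, dtype=float) + B
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def platt_nll(A: float, B: float, scores: np.ndarray, targets: np.ndarray) -> float:
    """Negative log-likelihood of the Platt sigmoid against smoothed targets."""
    z = A * np.asarray(scores, dtype=float) + B
    # -[t*log(p) + (1-t)*log(1-p)] with p = sigmoid(-z), stably:
    # log(p) = -log1pexp(z), log(1-p) = -log1pexp(-z)
    return float(np.sum(targets * _log1pexp(z) + (1.0 - targets) * _log1pexp(-z)))


def platt_calibrate(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Platt parameters (A, B) with smoothed targets.

    Targets are t+ = (N+ + 1)/(N+ + 2) for positives and t- = 1/(N- + 2)
    for negatives, the standard smoothing that keeps the fit away from
    degenerate 0/1 probabilities. With scores positively associated with
    the positive class the fitted A is negative, so the calibrated
    probability rises with the score.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("Platt calibration requires both classes")
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    targets = np.where(y == 1, t_pos, t_neg)

    def fun(ab: np.ndarray) -> float:
        return platt_nll(ab[0], ab[1], scores, targets)

    def grad(ab: np.ndarray) -> np.ndarray:
        z = ab[0] * scores + ab[1]
        p = 1.0 / (1.0 + np.exp(np.clip(-z, -500, 500)))  # sigmoid(z)
        r = p - (1.0 - targets)  # d NLL / d z
        return np.array([np.sum(r * scores), np.sum(r)])

    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(fun, x0, jac=grad, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    A, B = float(res.x[0]), float(res.x[1])
    return A, B


# --------------------------------------------------------------------------
# Threshold selection and prediction
# --------------------------------------------------------------------------


def select_threshold(
    probs: np.ndarray, y: np.ndarray, min_sensitivity: float = DEFAULT_TARGET_SENSITIVITY
) -> float:
    """Largest threshold whose development-set sensitivity meets the floor.

    Candidates are the distinct observed probabilities plus 0; flags use the
    inclusive rule (prob >= threshold). Feasibility is guaranteed: at the
    minimum positive probability every positive is flagged (sensitivity 1).
    Among candidates with equal sensitivity, the largest threshold flags the
    fewest negatives, i.e. maximizes specificity.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    if not 0 < min_sensitivity <= 1:
        raise ConfigError("min_sensitivity must be in (0, 1]")
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise DegenerateLabelsError("threshold selection requires at least one positive")
    candidates = np.unique(np.concatenate([probs, [0.0]]))[::-1]  # descending
    pos_probs = probs[y == 1]
    for tau in candidates:
        sens = float(np.mean(pos_probs >= tau))
        if sens >= min_sensitivity:
            return float(tau)
    return 0.0  # unreachable: tau = 0 flags everything


def predict_risk(model: CalibratedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated probabilities and inclusive-threshold risk flags."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_features = model.base.weights.shape[0]
    if X.shape[1] != n_features:
        raise ShapeError(f"expected {n_features} feature columns, got {X.shape[1]}")
    probs = model.probabilities(X)
    flags = (probs >= model.threshold).astype(int)
    return probs, flags


# --------------------------------------------------------------------------
# Published coefficients
# --------------------------------------------------------------------------

#: Coefficients published for a four-feature DAIC-WOZ screening model, in
#: canonical feature order. Context/format fixture only: the corpus behind
#: them is access-restricted, so they serve interpretation and I/O tests,
#: not metric reproduction.
PUBLISHED_COEFFICIENTS = {
    "neg_words_r": 0.458,
    "emb_1": 0.295,
    "sent_neg": 0.275,
    "avg_dep_dist": -0.124,
}


def load_published_model(
    coefficients: dict[str, float], intercept: Optional[float] = None
) -> LogisticModel:
    """Build a LogisticModel from a named coefficient table.

    All four canonical feature names must be present. A missing intercept
    defaults to 0 with a logged warning (published tables often omit it).
    """
    unknown = set(coefficients) - set(FEATURE_NAMES)
    if unknown:
        raise ConfigError(f"unknown feature names: {sorted(unknown)}")
    missing = set(FEATURE_NAMES) - set(coefficients)
    if missing:
        raise ConfigError(f"missing feature names: {sorted(missing)}")
    if intercept is None:
        logger.warning("no intercept supplied with coefficient table; defaulting to 0")
        intercept = 0.0
    weights = np.array([float(coefficients[name]) for name in FEATURE_NAMES])
    return LogisticModel(
        weights=weights,
        intercept=float(intercept),
        C=float("nan"),
        standardizer=Standardizer.identity(len(FEATURE_NAMES)),
    )
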