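"""RBF-kernel support-vector classification with Grey-Wolf-tuned (C, gamma).

The kernel is the Gaussian ``K(x, x_j) = exp(-||x - x_j||^2 / (2 sigma^2))``.
The tunable width parameter is expressed as ``gamma = 1 / sigma`` (the
inverse of the kernel standard deviation); the effective exponent
coefficient actually used in the kernel is ``gamma_eff = 1 / (2 sigma^2) =
gamma**2 / 2``.  The soft-margin weight ``C`` bounds the dual coefficients
(``0 <= a_i <= C``).

Hyperparameters are searched on the box ``C in [1, 50]``, ``gamma in
[1, 30]`` by the Grey Wolf Optimizer, whose cost is the mean
misclassification rate over stratified k-fold cross-validation; the search
is repeated several times from independent seeds and the best repetition
(ties broken toward smaller C, i.e. the simpler model) is kept.

Features are standardised to zero mean / unit variance using training-fold
statistics before the kernel is applied: an RBF on raw high-dimensional CNN
features is fragile to per-feature scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from ._exceptions import ValidationError
from .evaluation import stratified_kfold
from .gwo import GWOConfig, GWOResult, minimize

__all__ = [
    "KernelParams",
    "SVMModel",
    "TuneResult",
    "rbf_kernel",
    "rbf_gram",
    "fit_svm",
    "predict",
    "cv_error",
    "tune_hyperparameters",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class KernelParams:
    """Soft-margin weight and kernel width.

    ``gamma`` is the inverse kernel standard deviation (1/sigma); ``sigma``
    and the kernel exponent coefficient ``gamma_eff = 1/(2 sigma^2)`` are
    derived from it.
    """

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError("C and gamma must be positive")

    @property
    def sigma(self) -> float:
        return 1.0 / self.gamma

    @property
    def gamma_eff(self) -> float:
        return self.gamma**2 / 2.0


def rbf_kernel(x: np.ndarray, x_j: np.ndarray, params: KernelParams) -> float:
    """Gaussian kernel value ``exp(-||x - x_j||^2 / (2 sigma^2))``."""
    x = np.asarray(x, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x.shape != x_j.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {x_j.shape}")
    d2 = float(np.sum((x - x_j) ** 2))
    return float(np.exp(-d2 * params.gamma_eff))


def rbf_gram(X: np.ndarray, Y: np.ndarray, params: KernelParams) -> np.ndarray:
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return np.exp(-params.gamma_eff * d2)


@dataclass
class SVMModel:
    """A fitted soft-margin RBF classifier in its dual representation."""

    support_vectors: np.ndarray  # (n_sv, d), standardised space
    dual_coef: np.ndarray  # a_i * y_i, signed
    bias: float
    params: KernelParams
    feature_mean: np.ndarray
    feature_scale: np.ndarray


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # z-score each feature, then scale by sqrt(d) so a standardised row has
    # expected unit norm: squared distances between samples are then O(1)
    # regardless of the feature dimension, which makes the gamma search box
    # meaningful for both 2-D toy data and 1536-dim CNN features.
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    scale = scale * math.sqrt(X.shape[1])
    return mean, scale


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    params: KernelParams,
    standardize: bool = True,
    tol: float = 1e-3,
) -> SVMModel:
    """Solve the C-SVC dual on the RBF Gram matrix.

    The returned model stores the support vectors, the signed dual
    coefficients ``a_i y_i`` (bounded by the box constraint ``0 <= a_i <=
    C`` and summing to zero), the bias, and the feature standardisation
    fitted on the training rows.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be 2-D with one label per row")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 training samples")
    labels = np.unique(y)
    if labels.size != 2 or not set(labels).issubset({-1, 1}):
        raise ValidationError(
            f"need both classes with labels in {{-1, +1}}, got {labels.tolist()}"
        )
    if standardize:
        mean, scale = _standardize_fit(X)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    svc = SVC(C=params.C, kernel="rbf", gamma=params.gamma_eff, tol=tol)
    svc.fit(Xs, y)
    return SVMModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        params=params,
        feature_mean=mean,
        feature_scale=scale,
    )


def predict(model: SVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values ``sum_i a_i y_i K(x_i, x) + b``.

    The decision is evaluated directly from the stored support vectors, so
    predictions depend only on the model file contents.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValidationError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.support_vectors.shape[1]})"
        )
    Xs = (X - model.feature_mean) / model.feature_scale
    K = rbf_gram(Xs, model.support_vectors, model.params)
    decision = K @ model.dual_coef + model.bias
    labels = np.where(decision >= 0, 1, -1)
    return labels, decision


def cv_error(
    X: np.ndarray,
    y: np.ndarray,
    params: KernelParams,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean misclassification rate over stratified k-fold cross-validation.

    Standardisation is fitted on each training split only.  Deterministic
    given (data, params, folds, seed)."""
    y = np.asarray(y)
    assignments = stratified_kfold(y, k=folds, seed=seed)
    errors = []
    for fold in range(folds):
        test = assignments == fold
        model = fit_svm(X[~test], y[~test], params)
        pred, _ = predict(model, X[test])
        errors.append(float(np.mean(pred != y[test])))
    return float(np.mean(errors))


@dataclass(frozen=True)
class TuneResult:
    best_params: KernelParams
    cv_error: float
    #: one GWOResult per repetition of the optimisation
    repetitions: tuple[GWOResult, ...]
    mean_cv_error: float
    seed: int


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    c_range: tuple[float, float] = (1.0, 50.0),
    g_range: tuple[float, float] = (1.0, 30.0),
    gwo_cfg: GWOConfig | None = None,
    repetitions: int = 5,
    seed: int = 0,
) -> TuneResult:
    """Search (C, gamma) with the Grey Wolf Optimizer.

    The objective is the stratified k-fold CV classification error; the
    fold assignment is fixed once per call so the cost is a deterministic
    function of the candidate parameters.  The optimisation is repeated
    ``repetitions`` times from distinct seeds; the repetition with the
    lowest error wins, ties broken toward smaller C.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] < folds:
        raise ValidationError(f"need at least {folds} samples for {folds}-fold CV")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValidationError("every class needs >= folds members (stratification)")
    if gwo_cfg is None:
        gwo_cfg = GWOConfig(bounds=(c_range, g_range), n_restarts=1, seed=seed)
    else:
        gwo_cfg = GWOConfig(
            bounds=(c_range, g_range),
            pop_size=gwo_cfg.pop_size,
            n_iters=gwo_cfg.n_iters,
            n_restarts=gwo_cfg.n_restarts,
            a_init=gwo_cfg.a_init,
            seed=seed,
            enable_mutation=gwo_cfg.enable_mutation,
            mutation_prob=gwo_cfg.mutation_prob,
            mutation_scale=gwo_cfg.mutation_scale,
        )
    cache: dict[tuple[float, float], float] = {}

    def objective(position: np.ndarray) -> float:
        key = (round(float(position[0]), 12), round(float(position[1]), 12))
        if key not in cache:
            params = KernelParams(C=key[0], gamma=key[1])
            cache[key] = cv_error(X, y, params, folds=folds, seed=seed)
        return cache[key]

    rep_seeds = np.random.SeedSequence(seed).generate_state(repetitions)
    results: list[GWOResult] = []
    for rep_seed in rep_seeds:
        cfg = GWOConfig(
            bounds=gwo_cfg.bounds,
            pop_size=gwo_cfg.pop_size,
            n_iters=gwo_cfg.n_iters,
            n_restarts=gwo_cfg.n_restarts,
            a_init=gwo_cfg.a_init,
            seed=int(rep_seed % 2**31),
            enable_mutation=gwo_cfg.enable_mutation,
            mutation_prob=gwo_cfg.mutation_prob,
            mutation_scale=gwo_cfg.mutation_scale,
        )
        results.append(minimize(objective, cfg))
    winner = min(results, key=lambda r: (r.best_fitness, r.best_position[0]))
    best = KernelParams(
        C=float(winner.best_position[0]), gamma=float(winner.best_position[1])
    )
    return TuneResult(
        best_params=best,
        cv_error=float(winner.best_fitness),
        repetitions=tuple(results),
        mean_cv_error=float(np.mean([r.best_fitness for r in results])),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model persistence: text header + array payload
# ---------------------------------------------------------------------------


def save_model(model: SVMModel, path_prefix: str) -> None:
    header = {
        "C": model.params.C,
        "gamma": model.params.gamma,
        "sigma": model.params.sigma,
        "bias": model.bias,
        "n_support": int(model.support_vectors.shape[0]),
        "n_features": int(model.support_vectors.shape[1]),
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(header, fh, indent=1)
    np.savez_compressed(
        path_prefix + ".npz",
        support_vectors=model.support_vectors,
        dual_coef=model.dual_coef,
        feature_mean=model.feature_mean,
        feature_scale=model.feature_scale,
    )


def load_model(path_prefix: str) -> SVMModel:
    with open(path_prefix + ".json") as fh:
        header = json.load(fh)
    with np.load(path_prefix + ".npz") as data:
        return SVMModel(
            support_vectors=data["support_vectors"],
            dual_coef=data["dual_coef"],
            bias=float(header["bias"]),
            params=KernelParams(C=header["C"], gamma=header["gamma"]),
            feature_mean=data["feature_mean"],
            feature_scale=data["feature_scale"],
        )
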