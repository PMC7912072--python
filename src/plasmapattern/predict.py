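"""BMI prediction from binary protein profiles.

The estimator is an L1-penalized (LASSO) linear regression of BMI on 0/1
presence features, with the penalty weight chosen by repeated k-fold
cross-validation (10 runs of 10-fold by default, minimum mean error,
ties toward the sparser model). Feature selection is stabilised by
subsample intersection: 10 iterations each fit on a random 90% of the
samples, and the consensus panel keeps only proteins selected in every
iteration ("10 out of 10"). The final model is refit on all samples
restricted to the consensus panel with its own cross-validated penalty.

Performance is summarised as the median absolute error (MAE, kg/m^2)
between true and predicted BMI, under two protocols: ``holdout_pooled``
(each iteration's model predicts its ~10% held-out samples; all pairs are
pooled) and ``refit_insample`` (the final consensus model's in-sample
residuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._lasso import lasso_gram_python, lasso_path_gram
from .errors import DataError

_TOL = 1e-7
_MAX_SWEEPS = 100_000


@dataclass
class LassoModel:
    """Fitted L1-penalized linear model on the original 0/1 feature scale."""

    intercept: float
    coefficients: dict[str, float]
    lam: float
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def nonzero(self) -> list[str]:
        return [k for k, v in self.coefficients.items() if v != 0.0]

    def predict(self, X: np.ndarray, feature_ids: Sequence[str] | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = list(self.coefficients)
        beta = np.array([self.coefficients.get(f, 0.0) for f in feature_ids])
        return self.intercept + X @ beta


@dataclass
class CvResult:
    """Cross-validation curve over a descending lambda grid."""

    lambda_grid: np.ndarray
    mean_cv_error: np.ndarray
    lambda_min: float
    folds: int
    repeats: int

    @property
    def lambda_min_index(self) -> int:
        return int(np.argmin(self.mean_cv_error))


@dataclass
class StabilityResult:
    """Outcome of subsample-intersection stability selection."""

    iterations: int
    subsample_fraction: float
    per_iteration_selected: list[set[str]]
    consensus: set[str]
    final_model: LassoModel
    mae: float  # headline: pooled-holdout MAE (kg/m^2); NaN if no holdout
    mae_holdout: float
    mae_insample: float
    baseline_mae_holdout: float
    seed: int
    consensus_empty: bool = False
    selection_frequency: dict[str, float] = field(default_factory=dict)


def _as_float_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be a 2-D matrix")
    return X


def _standardize(X: np.ndarray, standardize: bool = True):
    """Center columns; scale by population SD when ``standardize``.

    Zero-variance columns get scale 0 and are excluded from the penalized
    fit (their coefficients stay 0).
    """
    center = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, matching the (1/2n) loss convention
    scale = sd.copy() if standardize else np.ones_like(sd)
    scale[sd == 0] = 0.0
    Xs = np.zeros_like(X)
    ok = scale > 0
    Xs[:, ok] = (X[:, ok] - center[ok]) / scale[ok]
    return Xs, center, scale


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    ratio: float = 0.01,
    standardize: bool = True,
) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max to lambda_max*ratio.

    lambda_max = max_j |x~_j'(y - ybar)|/n over standardized columns is the
    smallest penalty with an all-zero solution. A signal-free problem
    (lambda_max = 0) degenerates to the single-point grid [0.0].
    """
    if n_lambda < 2:
        raise DataError("n_lambda must be >= 2")
    X = _as_float_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, _, _ = _standardize(X, standardize)
    n = len(y)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n) if X.size else 0.0
    if lam_max == 0.0:
        warnings.warn("no signal (lambda_max = 0); degenerate single-point path",
                      stacklevel=2)
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _gram(Xs: np.ndarray, y: np.ndarray):
    n = len(y)
    G = (Xs.T @ Xs) / n
    c = Xs.T @ (y - y.mean()) / n
    return np.ascontiguousarray(G), np.ascontiguousarray(c)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_ids: Sequence[str] | None = None,
    standardize: bool = True,
    debug: bool = False,
) -> LassoModel:
    """Solve (1/2n)||y - b0 - X beta||^2 + lam*|beta|_1 by coordinate descent.

    Features are centred and (by default) scaled by their population SD for
    the solve; returned coefficients are back-transformed to the original
    0/1 scale. Zero-variance columns are dropped with a warning, and a
    constant response yields the intercept-only model. ``debug=True`` runs
    a slow reference solver that asserts the objective is non-increasing
    across sweeps.
    """
    X = _as_float_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise DataError("X and y have different numbers of samples")
    if len(y) < 2:
        raise DataError("need at least two samples")
    if lam < 0:
        raise DataError("lambda must be nonnegative")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    feature_ids = list(feature_ids)
    Xs, center, scale = _standardize(X, standardize)
    dropped = [f for f, s in zip(feature_ids, scale) if s == 0.0]
    if dropped:
        warnings.warn(f"zero-variance column(s) dropped from the fit: {dropped}",
                      stacklevel=2)
    if np.all(y == y[0]):
        return LassoModel(
            intercept=float(y[0]),
            coefficients={f: 0.0 for f in feature_ids},
            lam=lam,
            standardization={f: (float(c), float(s)) for f, c, s in zip(feature_ids, center, scale)},
        )
    G, c = _gram(Xs, y)
    if debug:
        objectives: list[float] = []
        beta_std = lasso_gram_python(
            G, c, lam, tol=_TOL, track_objective=objectives.append
        )
        drops = np.diff(objectives)
        if np.any(drops > 1e-10):
            raise AssertionError("coordinate-descent objective increased across sweeps")
    else:
        beta_std = lasso_path_gram(G, c, np.array([lam]), _TOL, _MAX_SWEEPS)[0]
    ok = scale > 0
    beta = np.zeros(X.shape[1])
    beta[ok] = beta_std[ok] / scale[ok]
    intercept = float(y.mean() - center @ beta)
    return LassoModel(
        intercept=intercept,
        coefficients={f: float(b) for f, b in zip(feature_ids, beta)},
        lam=lam,
        standardization={f: (float(cc), float(s)) for f, cc, s in zip(feature_ids, center, scale)},
    )


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    metric: str = "mse",
    n_lambda: int = 100,
    ratio: float = 0.01,
    standardize: bool = True,
) -> CvResult:
    """Repeated k-fold cross-validation of the penalty weight.

    Each repeat draws a fresh random fold assignment; per lambda the
    out-of-fold error (squared by default, ``metric="mae"`` for absolute)
    is averaged over all folds and repeats. The minimising lambda is
    returned, ties broken toward the larger (sparser) value.
    """
    X = _as_float_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise DataError(f"need at least {folds} samples for {folds}-fold CV")
    if metric not in {"mse", "mae"}:
        raise DataError(f"unknown CV metric {metric!r}")
    grid = lambda_grid(X, y, n_lambda=n_lambda, ratio=ratio, standardize=standardize)
    rng = np.random.default_rng(seed)
    errors = np.zeros(len(grid))
    n_eval = 0
    for _ in range(repeats):
        perm = rng.permutation(n)
        for fold_idx in np.array_split(perm, folds):
            if len(fold_idx) < 2:
                raise DataError("a CV fold has fewer than 2 samples")
            train = np.setdiff1d(perm, fold_idx, assume_unique=True)
            Xtr, ytr = X[train], y[train]
            Xs, center, scale = _standardize(Xtr, standardize)
            G, c = _gram(Xs, ytr)
            betas = lasso_path_gram(G, c, grid, _TOL, _MAX_SWEEPS)
            ok = scale > 0
            Xval = np.zeros((len(fold_idx), X.shape[1]))
            Xval[:, ok] = (X[fold_idx][:, ok] - center[ok]) / scale[ok]
            pred = ytr.mean() + Xval @ betas.T  # (n_val, n_lambda)
            resid = pred - y[fold_idx][:, None]
            fold_err = (
                (resid ** 2).mean(axis=0) if metric == "mse" else np.abs(resid).mean(axis=0)
            )
            errors += fold_err
            n_eval += 1
    errors /= n_eval
    lam_min = float(grid[int(np.argmin(errors))])  # grid descending: first = largest
    return CvResult(
        lambda_grid=grid,
        mean_cv_error=errors,
        lambda_min=lam_min,
        folds=folds,
        repeats=repeats,
    )


def median_absolute_error(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """median(|y_true - y_pred|); even lengths use the mean of the two
    central order statistics (numpy convention)."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise DataError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size < 1:
        raise DataError("need at least one pair")
    return float(np.median(np.abs(yt - yp)))


def stability_select(
    X: np.ndarray,
    y: np.ndarray,
    iterations: int = 10,
    fraction: float = 0.9,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    feature_ids: Sequence[str] | None = None,
    metric: str = "mse",
    n_lambda: int = 100,
    ratio: float = 0.01,
    standardize: bool = True,
    final: str = "cv",
) -> StabilityResult:
    """Subsample-intersection stability selection with a consensus refit.

    Each iteration draws floor(fraction*n) samples without replacement,
    selects lambda by repeated CV on the subsample, fits the LASSO there,
    and records the nonzero proteins. The consensus keeps proteins selected
    in *every* iteration; the final model refits on all samples restricted
    to the consensus panel with a fresh CV-selected penalty (``final="ols"``
    for an unpenalized refit). An empty consensus yields a flagged
    intercept-only final model. Fully reproducible from the seed.
    """
    X = _as_float_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    feature_ids = list(feature_ids)
    n_sub = int(np.floor(fraction * n))
    if n_sub < folds:
        raise DataError(f"subsample size {n_sub} smaller than fold count {folds}")
    if final not in {"cv", "ols"}:
        raise DataError(f"unknown final-model mode {final!r}")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(iterations + 1)
    selected: list[set[str]] = []
    holdout_true: list[float] = []
    holdout_pred: list[float] = []
    baseline_pred: list[float] = []
    for it in range(iterations):
        child = children[it]
        rng = np.random.default_rng(child)
        sub = np.sort(rng.choice(n, size=n_sub, replace=False))
        cv_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cv_select_lambda(
                X[sub], y[sub], folds=folds, repeats=repeats, seed=cv_seed,
                metric=metric, n_lambda=n_lambda, ratio=ratio, standardize=standardize,
            )
            model = lasso_fit(X[sub], y[sub], cv.lambda_min, feature_ids,
                              standardize=standardize)
        selected.append(set(model.nonzero()))
        held = np.setdiff1d(np.arange(n), sub, assume_unique=True)
        if held.size:
            holdout_true.extend(y[held])
            holdout_pred.extend(model.predict(X[held], feature_ids))
            baseline_pred.extend(np.full(held.size, y[sub].mean()))

    consensus: set[str] = set(feature_ids)
    for s in selected:
        consensus &= s
    freq = {
        f: sum(f in s for s in selected) / iterations
        for f in feature_ids
        if any(f in s for s in selected)
    }

    consensus_empty = len(consensus) == 0
    final_seed = int(children[-1].generate_state(1)[0] & 0x7FFFFFFF)
    if consensus_empty:
        warnings.warn("empty consensus; final model is intercept-only", stacklevel=2)
        final_model = LassoModel(intercept=float(y.mean()), coefficients={}, lam=0.0)
        insample_pred = np.full(n, y.mean())
    else:
        cons_order = [f for f in feature_ids if f in consensus]
        idx = [feature_ids.index(f) for f in cons_order]
        Xc = X[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if final == "cv":
                cv = cv_select_lambda(
                    Xc, y, folds=folds, repeats=repeats, seed=final_seed,
                    metric=metric, n_lambda=n_lambda, ratio=ratio,
                    standardize=standardize,
                )
                final_model = lasso_fit(Xc, y, cv.lambda_min, cons_order,
                                        standardize=standardize)
            else:
                final_model = lasso_fit(Xc, y, 0.0, cons_order, standardize=standardize)
        insample_pred = final_model.predict(Xc, cons_order)

    mae_insample = median_absolute_error(y, insample_pred)
    if holdout_true:
        mae_holdout = median_absolute_error(holdout_true, holdout_pred)
        baseline_mae = median_absolute_error(holdout_true, baseline_pred)
    else:
        mae_holdout = float("nan")
        baseline_mae = float("nan")
    return StabilityResult(
        iterations=iterations,
        subsample_fraction=fraction,
        per_iteration_selected=selected,
        consensus=consensus,
        final_model=final_model,
        mae=mae_holdout,
        mae_holdout=mae_holdout,
        mae_insample=mae_insample,
        baseline_mae_holdout=baseline_mae,
        seed=seed,
        consensus_empty=consensus_empty,
        selection_frequency=freq,
    )


def evaluate_mae(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "holdout_pooled",
    **stability_kwargs,
) -> float:
    """MAE of the stability-selected predictor under a named protocol.

    ``holdout_pooled`` (default) pools each iteration's ~10% held-out
    predictions; ``refit_insample`` scores the final consensus model on the
    full sample.
    """
    if method not in {"holdout_pooled", "refit_insample"}:
        raise DataError(f"unknown evaluation method {method!r}")
    result = stability_select(X, y, **stability_kwargs)
    return result.mae_holdout if method == "holdout_pooled" else result.mae_insample
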