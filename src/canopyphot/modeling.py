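"""Trait estimation models: dataset splitting, univariate index regression,
LASSO variable selection with cross-validated λ, PLSR with cross-validated
component count, VIP scores, and evaluation metrics.

Conventions
-----------
* LASSO uses the objective (1/(2n))·‖y − Xβ‖² + λ‖β‖₁ on internally
  standardized columns; the λ path is geometric from λ_max = max|Xᵀy|/n down
  four decades, and the CV winner breaks ties toward the larger λ (sparser
  model).
* PLSR is NIPALS (scikit-learn's PLSRegression) on centered/scaled data;
  the component count minimizes 10-fold CV RMSE, ties toward fewer
  components.
* bias = mean(predicted − observed); rRMSE = 100·RMSE/mean(observed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "EvalReport",
    "TrainedTraitModel",
    "UnivariateModel",
    "split_dataset",
    "univariate_fit",
    "lasso_coefficients",
    "lasso_select",
    "fit_plsr",
    "vip_scores",
    "evaluate",
    "save_model_json",
    "load_model_json",
]


@dataclass
class EvalReport:
    """Agreement metrics between predicted and observed trait values."""

    r2: float
    r: float
    rmse: float
    bias: float
    rrmse_percent: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UnivariateModel:
    """Simple linear model trait = slope·index + intercept."""

    index: str
    slope: float
    intercept: float
    trait: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    @property
    def selected_indices(self) -> list[str]:
        return [self.index]


@dataclass
class TrainedTraitModel:
    """A fitted LASSO→PLSR trait model.

    Prediction is linear once trained: y = y_mean + Σ_j coef_j·(x_j − x_mean_j)/x_std_j
    over the LASSO-selected indices. Weights/loadings and VIP scores are
    retained for inspection.
    """

    trait: str
    selected_indices: list[str]
    lasso_lambda: float
    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    coef: np.ndarray  # on standardized X
    x_weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    vip: np.ndarray  # (p,)
    cv_rmse: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        p = len(self.selected_indices)
        if self.n_components > p:
            raise ValueError("n_components exceeds number of selected indices")
        if len(self.vip) != p:
            raise ValueError("vip length must equal number of selected indices")

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.selected_indices].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean) / self.x_std
        return self.y_mean + Xs @ self.coef

    @property
    def important_indices(self) -> list[str]:
        """Indices flagged influential by the VIP > 1 rule."""
        return [n for n, v in zip(self.selected_indices, self.vip) if v > 1.0]


def split_dataset(samples, ratio: float = 2.0 / 3.0, seed: int = 0):
    """Seeded random split into calibration/validation of sizes
    round(N·ratio) / remainder (default 2:1)."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_cal = int(round(n * ratio))
    n_cal = min(max(n_cal, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    cal_idx, val_idx = np.sort(perm[:n_cal]), np.sort(perm[n_cal:])
    if isinstance(samples, pd.DataFrame):
        return samples.iloc[cal_idx], samples.iloc[val_idx]
    samples = list(samples)
    return [samples[i] for i in cal_idx], [samples[i] for i in val_idx]


def evaluate(predicted, observed) -> EvalReport:
    """R², |r|, RMSE, bias and rRMSE (%) between prediction and observation.

    r2 = 1 − Σ(o−p)²/Σ(o−ō)²; bias = mean(p−o); rRMSE = 100·RMSE/ō.
    Zero variance in the observations makes R² (and r) undefined → NaN.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    bias = float(np.mean(p - o))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        r2 = float("nan")
        r = float("nan")
    else:
        r2 = 1.0 - float(np.sum((o - p) ** 2)) / ss_tot
        r = float(abs(stats.pearsonr(p, o)[0])) if np.std(p) > 0 else float("nan")
    rrmse = 100.0 * rmse / float(o.mean()) if o.mean() != 0 else float("nan")
    return EvalReport(r2=r2, r=r, rmse=rmse, bias=bias, rrmse_percent=rrmse, n=n)


def univariate_fit(index_values, trait):
    """Ordinary least squares line trait = slope·index + intercept."""
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    model = UnivariateModel(index="", slope=float(res.slope), intercept=float(res.intercept))
    report = evaluate(model.predict(x), y)
    return model.slope, model.intercept, report


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    if np.any(std == 0):
        raise ValueError("constant column in X; drop it before modeling")
    return (X - mean) / std, mean, std


def lasso_coefficients(
    X: np.ndarray, y: np.ndarray, lam: float, standardize: bool = True
) -> np.ndarray:
    """LASSO coefficients at one penalty λ for (1/(2n))·RSS + λ‖β‖₁.

    With ``standardize=False`` the columns are used as-is (y still centered),
    which makes the closed-form soft-threshold solution exact on orthonormal
    designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if standardize:
        X, _, _ = _standardize(X)
    model = Lasso(alpha=lam, fit_intercept=True, tol=1e-12, max_iter=100000)
    model.fit(X, y)
    return model.coef_


def lasso_select(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    decades: float = 4.0,
):
    """LASSO variable selection with a cross-validated penalty.

    Standardizes columns, builds a geometric λ path from λ_max (the smallest
    penalty zeroing every coefficient) down ``decades`` decades, picks the
    λ minimizing mean CV MSE over seeded ``folds``-fold partitions (ties →
    larger λ), and returns (selected column names, λ*). Rows with NaN are
    the caller's responsibility to drop.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if n <= folds:
        raise ValueError("need more samples than folds")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("X contains non-finite values")
    if np.std(ya) == 0:
        raise ValueError("constant response")
    Xs, _, _ = _standardize(Xa)
    yc = ya - ya.mean()
    lam_max = np.max(np.abs(Xs.T @ yc)) / n
    path = np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambdas)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_mse = np.zeros((folds, n_lambdas))
    # the deep end of the path (λ_max·1e-4) converges slowly on strongly
    # correlated index banks and is essentially never the CV winner; the
    # coordinate-descent convergence warning there is expected noise
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for f, (tr, te) in enumerate(kf.split(Xs)):
            model = Lasso(
                alpha=path[0], fit_intercept=True, tol=1e-8, max_iter=50000, warm_start=True
            )
            for j, lam in enumerate(path):
                model.set_params(alpha=lam)
                model.fit(Xs[tr], ya[tr])
                pred = model.predict(Xs[te])
                cv_mse[f, j] = np.mean((pred - ya[te]) ** 2)
    mean_mse = cv_mse.mean(axis=0)
    # ties toward the sparser model = larger λ = smaller path index
    best_j = int(np.argmin(mean_mse))
    lam_star = float(path[best_j])

    final = Lasso(alpha=lam_star, fit_intercept=True, tol=1e-10, max_iter=100000)
    final.fit(Xs, ya)
    selected = [names[j] for j in np.flatnonzero(np.abs(final.coef_) > 0)]
    return selected, lam_star


def _vip_from_pls(pls: PLSRegression) -> np.ndarray:
    """VIP_j = sqrt(p·Σ_a SS_a·(w_ja/‖w_a‖)² / Σ_a SS_a), with SS_a the
    y-variance explained by component a (q_a²·‖t_a‖²)."""
    W = pls.x_weights_  # (p, a)
    T = pls.x_scores_  # (n, a)
    Q = pls.y_loadings_  # (1, a)
    p, a = W.shape
    ss = (Q[0] ** 2) * np.sum(T**2, axis=0)  # (a,)
    w_norm2 = np.sum(W**2, axis=0)
    contrib = (W**2) / w_norm2[None, :]
    return np.sqrt(p * (contrib @ ss) / ss.sum())


def fit_plsr(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 0,
    trait: str = "",
    n_components: int | None = None,
) -> TrainedTraitModel:
    """PLS regression on centered/scaled data with a CV-chosen component count.

    Components are searched over 1..min(p, n−1) by ``folds``-fold CV RMSE
    (ties toward the smaller count). Passing ``n_components`` skips the CV.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if p == 0:
        raise ValueError("no predictors selected")
    if n <= folds and n_components is None:
        raise ValueError("need more samples than folds")
    Xs, x_mean, x_std = _standardize(Xa)

    max_a = min(p, n - 1)
    cv_rmse = np.array([])
    if n_components is None:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(Xs))
        max_a_cv = min(max_a, min(len(tr) - 1 for tr, _ in splits))
        rmses = []
        for a in range(1, max_a_cv + 1):
            sq = []
            for tr, te in splits:
                pls = PLSRegression(n_components=a, scale=False)
                pls.fit(Xs[tr], ya[tr])
                pred = pls.predict(Xs[te]).ravel()
                sq.append(np.sum((pred - ya[te]) ** 2))
            rmses.append(np.sqrt(np.sum(sq) / n))
        cv_rmse = np.asarray(rmses)
        n_components = int(np.argmin(cv_rmse)) + 1  # argmin takes first = smallest a on ties
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}]")

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, ya)
    coef = np.asarray(pls.coef_).reshape(-1)
    if coef.size != p:  # sklearn >=1.1 stores (n_targets, p)
        coef = np.asarray(pls.coef_).reshape(p)
    vip = _vip_from_pls(pls)
    return TrainedTraitModel(
        trait=trait,
        selected_indices=names,
        lasso_lambda=float("nan"),
        n_components=n_components,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=float(ya.mean()),
        coef=coef,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_[0],
        vip=vip,
        cv_rmse=cv_rmse,
    )


def vip_scores(model: TrainedTraitModel) -> pd.Series:
    """Per-index VIP scores of a fitted model (VIP > 1 flags importance)."""
    if not isinstance(model, TrainedTraitModel) or model.vip.size == 0:
        raise ValueError("model is not fitted")
    return pd.Series(model.vip, index=model.selected_indices, name="vip")


# ---------------------------------------------------------------------------
# Model persistence


def save_model_json(model, path) -> None:
    if isinstance(model, UnivariateModel):
        payload = {"kind": "univariate", **asdict(model)}
    elif isinstance(model, TrainedTraitModel):
        payload = {"kind": "plsr", **asdict(model)}
        for key in ("x_mean", "x_std", "coef", "x_weights", "x_loadings", "y_loadings", "vip", "cv_rmse"):
            payload[key] = np.asarray(payload[key]).tolist()
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model_json(path):
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.pop("kind")
    if kind == "univariate":
        return UnivariateModel(**payload)
    if kind == "plsr":
        for key in ("x_mean", "x_std", "coef", "x_weights", "x_loadings", "y_loadings", "vip", "cv_rmse"):
            payload[key] = np.asarray(payload[key], dtype=float)
        return TrainedTraitModel(**payload)
    raise ValueError(f"unknown model kind {kind!r}")
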