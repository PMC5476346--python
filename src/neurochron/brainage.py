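"""Kernel Gaussian-process regression of chronological age on brain structure.

Age is regressed on a (normalised) linear kernel over concatenated GM+WM
feature vectors.  With ``K~ = K / mean(diag K)`` the covariance is
``C = s_f^2 K~ + s_n^2 I``; the two variance hyperparameters are set by
maximising the Gaussian-process log marginal likelihood of the centred
ages, and the predictive mean for a test subject with cross-kernel row
``k*`` is ``mu + s_f^2 (k* / kernel_norm) . alpha`` with dual weights
``alpha = C^{-1} (y - mu)``.

Model accuracy is summarised by Pearson's r, R^2 (= r^2), mean absolute
error and root mean squared error over 10-fold cross-validated
predictions, with significance from a label-permutation test.  The
brain-predicted age difference (brain-PAD) of a subject is
``predicted age - chronological age``: positive means an
"older-appearing" brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .features import KernelMatrix

__all__ = [
    "GPRModel",
    "AccuracyReport",
    "fit_gpr",
    "predict",
    "assign_folds",
    "crossval_predict",
    "performance",
    "permutation_test",
]

_JITTER = 1e-8  # added to the diagonal of the normalised covariance


@dataclass
class GPRModel:
    """A fitted GP age-regression model in dual (weight-vector) form."""

    dual_weights: np.ndarray
    train_mean_age: float
    signal_var: float
    noise_var: float
    kernel_norm: float
    train_ids: list[str]

    def __post_init__(self):
        if self.signal_var <= 0 or self.noise_var < 0:
            raise ValueError("signal_var must be > 0 and noise_var >= 0")
        if not np.all(np.isfinite(self.dual_weights)):
            raise ValueError("dual weights must be finite")


@dataclass(frozen=True)
class AccuracyReport:
    """Cross-validated age-prediction accuracy metrics."""

    pearson_r: float
    r_squared: float
    mae_years: float
    rmse_years: float
    n: int


def _check_psd(eigvals: np.ndarray, trace: float, n: int) -> None:
    if eigvals.min() < -1e-8 * max(trace / n, 1e-30):
        raise ValueError("kernel is not positive semidefinite")


def _optimize_hypers(eigvals: np.ndarray, y_rot: np.ndarray) -> tuple[float, float]:
    """Maximise the log marginal likelihood in (log s_f^2, log s_n^2).

    Works in the eigenbasis of the normalised kernel, where the covariance
    is diagonal: d_i = s_f^2 lam_i + s_n^2 + jitter.  The surface is badly
    conditioned when one kernel eigenvalue dominates (raw probability maps
    have a large DC component), so a single descent start can stall in a
    noise-only optimum; a fixed coarse grid scan (cheap in the eigenbasis)
    followed by an L-BFGS polish from the best cell is deterministic and
    robust.
    """
    n = y_rot.size
    var_y = max(float(np.var(y_rot)), 1e-12)

    def neg_lml_and_grad(theta):
        sf2, sn2 = np.exp(theta)
        d = sf2 * eigvals + sn2 + _JITTER
        if np.any(d <= 0):
            return np.inf, np.zeros(2)
        q = y_rot**2 / d
        nll = 0.5 * (q.sum() + np.log(d).sum() + n * np.log(2 * np.pi))
        # d(nll)/d(log sf2) etc., chain rule through d
        g_sf = 0.5 * np.sum((1.0 / d - q / d) * sf2 * eigvals)
        g_sn = 0.5 * np.sum((1.0 / d - q / d) * sn2)
        return nll, np.array([g_sf, g_sn])

    log_vy = np.log(var_y)
    x0 = np.array([0.0, 0.5 * log_vy])
    best = (neg_lml_and_grad(x0)[0], x0)
    for lf in np.linspace(-10.0, 14.0, 13):
        for ln in np.linspace(log_vy - 10.0, log_vy + 3.0, 9):
            x = np.array([lf, ln])
            val = neg_lml_and_grad(x)[0]
            if val < best[0]:
                best = (val, x)
    res = minimize(neg_lml_and_grad, best[1], jac=True, method="L-BFGS-B",
                   bounds=[(-20.0, 20.0), (-25.0, 20.0)])
    sf2, sn2 = np.exp(res.x)
    return float(sf2), float(sn2)


def fit_gpr(K_train: KernelMatrix | np.ndarray, ages: np.ndarray,
            signal_var: float | None = None,
            noise_var: float | None = None,
            train_ids: list[str] | None = None) -> GPRModel:
    """Fit the GP age model on a training kernel.

    Hyperparameters are optimised from the marginal likelihood unless both
    ``signal_var`` and ``noise_var`` are supplied.
    """
    if isinstance(K_train, KernelMatrix):
        ids = train_ids or K_train.subject_ids
        K = K_train.values
    else:
        K = np.asarray(K_train, dtype=float)
        ids = train_ids or [f"s{i:04d}" for i in range(K.shape[0])]
    ages = np.asarray(ages, dtype=float)
    n = K.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training subjects")
    if ages.shape != (n,):
        raise ValueError("ages length must match the kernel")

    kernel_norm = float(np.mean(np.diag(K)))
    if kernel_norm <= 0:
        raise ValueError("kernel diagonal mean must be positive")
    Kn = K / kernel_norm
    eigvals, eigvecs = np.linalg.eigh(Kn)
    _check_psd(eigvals, float(np.trace(Kn)), n)
    eigvals = np.clip(eigvals, 0.0, None)

    mu = float(np.mean(ages))
    yc = ages - mu
    y_rot = eigvecs.T @ yc

    if signal_var is None or noise_var is None:
        signal_var, noise_var = _optimize_hypers(eigvals, y_rot)
    d = signal_var * eigvals + noise_var + _JITTER
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise np.linalg.LinAlgError(
            "singular covariance at the optimum; add jitter or noise variance"
        )
    alpha = eigvecs @ (y_rot / d)
    return GPRModel(alpha, mu, signal_var, noise_var, kernel_norm, list(ids))


def predict(model: GPRModel, K_cross: np.ndarray,
            subject_ids: list[str] | None = None,
            ages: np.ndarray | None = None) -> pd.DataFrame:
    """Predict ages for test subjects from their cross-kernel rows.

    ``K_cross`` is (n_test, n_train), columns ordered as ``model.train_ids``.
    Returns a table with ``brain_predicted_age`` and, when chronological
    ages are given, ``brain_pad = brain_predicted_age - age_years``.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != model.dual_weights.size:
        raise ValueError("cross-kernel columns must match the training subjects")
    pred = model.train_mean_age + model.signal_var * (
        K_cross / model.kernel_norm
    ) @ model.dual_weights
    out = pd.DataFrame({
        "subject_id": subject_ids if subject_ids is not None
        else [f"t{i:04d}" for i in range(pred.size)],
        "brain_predicted_age": pred,
    })
    if ages is not None:
        out.insert(1, "age_years", np.asarray(ages, dtype=float))
        out["brain_pad"] = out["brain_predicted_age"] - out["age_years"]
    return out


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random fold labels: shuffle indices with the seed, deal round-robin.

    Fold sizes differ by at most one.  Assignment depends only on (n, k,
    seed), never on the ages, so held-out labels cannot leak into it.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


class _FoldCache:
    """Per-fold eigendecompositions of a kernel, reusable across label sets.

    Lets cross-validated predictions be recomputed for many label vectors
    (as in the permutation test) without refactorising the kernel.
    """

    def __init__(self, K: np.ndarray, folds: np.ndarray):
        self.folds = folds
        self.k = int(folds.max()) + 1
        self.parts = []
        for f in range(self.k):
            te = np.flatnonzero(folds == f)
            tr = np.flatnonzero(folds != f)
            norm = float(np.mean(np.diag(K)[tr]))
            Kn = K[np.ix_(tr, tr)] / norm
            eigvals, eigvecs = np.linalg.eigh(Kn)
            eigvals = np.clip(eigvals, 0.0, None)
            Kc = K[np.ix_(te, tr)] / norm
            self.parts.append((tr, te, eigvals, eigvecs, Kc))

    def cv_predict(self, y: np.ndarray, optimize: bool = True,
                   hypers: tuple[float, float] | None = None) -> np.ndarray:
        pred = np.empty_like(y, dtype=float)
        for tr, te, eigvals, eigvecs, Kc in self.parts:
            mu = float(np.mean(y[tr]))
            y_rot = eigvecs.T @ (y[tr] - mu)
            if optimize or hypers is None:
                sf2, sn2 = _optimize_hypers(eigvals, y_rot)
            else:
                sf2, sn2 = hypers
            d = sf2 * eigvals + sn2 + _JITTER
            alpha = eigvecs @ (y_rot / d)
            pred[te] = mu + sf2 * (Kc @ alpha)
        return pred


def crossval_predict(K: KernelMatrix | np.ndarray, ages: np.ndarray,
                     k: int = 10, seed: int = 0, optimize: bool = True,
                     hypers: tuple[float, float] | None = None,
                     subject_ids: list[str] | None = None) -> pd.DataFrame:
    """K-fold cross-validated age predictions.

    Each subject's prediction comes from a model fitted without its fold.
    With ``optimize=False`` and ``hypers`` given, the supplied
    (signal_var, noise_var) are reused in every fold.
    """
    if isinstance(K, KernelMatrix):
        ids = subject_ids or K.subject_ids
        K = K.values
    else:
        K = np.asarray(K, dtype=float)
        ids = subject_ids or [f"s{i:04d}" for i in range(K.shape[0])]
    ages = np.asarray(ages, dtype=float)
    n = K.shape[0]
    folds = assign_folds(n, k, seed)
    cache = _FoldCache(K, folds)
    pred = cache.cv_predict(ages, optimize=optimize, hypers=hypers)
    return pd.DataFrame({
        "subject_id": ids,
        "age_years": ages,
        "brain_predicted_age": pred,
        "brain_pad": pred - ages,
        "fold": folds,
    })


def performance(ages: np.ndarray, predictions: np.ndarray) -> AccuracyReport:
    """Pearson r, R^2 (= r^2), MAE and RMSE of age predictions."""
    ages = np.asarray(ages, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if ages.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.var(ages) == 0 or np.var(predictions) == 0:
        raise ValueError("Pearson r undefined: zero variance")
    r = float(pearsonr(ages, predictions).statistic)
    err = predictions - ages
    return AccuracyReport(
        pearson_r=r,
        r_squared=r * r,
        mae_years=float(np.mean(np.abs(err))),
        rmse_years=float(np.sqrt(np.mean(err**2))),
        n=ages.size,
    )


def permutation_test(K: KernelMatrix | np.ndarray, ages: np.ndarray,
                     n_perm: int = 1000, k: int = 10, seed: int = 0,
                     optimize: bool = True,
                     hypers: tuple[float, float] | None = None) -> dict:
    """Label-permutation significance of the cross-validated accuracy.

    Age labels are permuted ``n_perm`` times, the cross-validated Pearson
    r recomputed each time (re-optimising the hyperparameters unless
    ``optimize=False``), and the p-value is
    ``(1 + #[r_perm >= r_obs]) / (n_perm + 1)``, so the smallest
    attainable p is ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(K, KernelMatrix):
        K = K.values
    K = np.asarray(K, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = K.shape[0]
    folds = assign_folds(n, k, seed)
    cache = _FoldCache(K, folds)

    def cv_r(y):
        pred = cache.cv_predict(y, optimize=optimize, hypers=hypers)
        return float(pearsonr(y, pred).statistic)

    r_obs = cv_r(ages)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        r_perm[i] = cv_r(ages[rng.permutation(n)])
    p = (1 + int(np.sum(r_perm >= r_obs))) / (n_perm + 1)
    return {"r_observed": r_obs, "r_permuted": r_perm, "p_value": p,
            "n_perm": n_perm}
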