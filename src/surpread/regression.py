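"""Gaussian linear regression with closed-form train/held-out log-likelihood.

Fits are ordinary least squares; the error variance attached to a fit is
the training maximum-likelihood estimate RSS/n, so the held-out
log-likelihood of new data is a pure function of the training fit:
``Σ log N(y_i | x_i β̂, σ̂²_train)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GaussianFit:
    """OLS coefficients plus the training MLE residual variance."""

    coef: np.ndarray
    sigma2: float  # training MLE residual variance RSS/n
    columns: tuple[str, ...] = ()
    n_train: int = 0

    @property
    def train_loglik(self) -> float:
        # -n/2 (log 2πσ² + 1) since RSS = n σ² at the MLE
        n = self.n_train
        return -0.5 * n * (np.log(2 * np.pi * self.sigma2) + 1.0)


def fit_gaussian_linear(
    X: np.ndarray, y: np.ndarray, columns: tuple[str, ...] = ()
) -> GaussianFit:
    """Fit y = Xβ + ε by OLS with MLE error variance.

    Raises on rank deficiency (naming the offending columns when labels
    are supplied) and when n ≤ p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns involved in the collinearity via QR pivoting
        _, R, piv = _qr_pivot(X)
        bad = sorted(piv[rank:])
        names = [columns[j] if columns else str(j) for j in bad]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid / n)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny  # perfectly interpolated data
    return GaussianFit(coef=beta, sigma2=sigma2, columns=tuple(columns), n_train=n)


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def gaussian_loglik(y: np.ndarray, mu: np.ndarray, sigma2: float) -> float:
    """Σ log N(y_i | mu_i, sigma2)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(
        -0.5 * np.sum(np.log(2 * np.pi * sigma2) + (y - mu) ** 2 / sigma2)
    )


def heldout_loglik(fit: GaussianFit, X: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood of held-out data under the training fit
    (training coefficients and training σ²)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(fit.coef):
        raise ValueError(
            f"design has {X.shape[1]} columns but fit expects {len(fit.coef)}"
        )
    return gaussian_loglik(y, X @ fit.coef, fit.sigma2)
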