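"""Penalized-spline additive models (Gaussian response).

Smooth terms use cubic B-spline bases on equally spaced knots with a
second-order difference penalty on the coefficients (P-splines).  With
uniform knots the penalty null space corresponds exactly to constant and
linear functions of the covariate, so an infinitely penalized smooth
*is* the linear fit.  Each smooth is reparameterized to separate that
null space from the penalized range space:

* the constant is absorbed by the model intercept,
* the linear part enters as an explicit unpenalized column,
* the penalized part is transformed so its penalty is the identity.

Tensor-product smooths for two-way interactions are built as row-wise
Kronecker products of the marginal bases, with one difference penalty
per margin; their joint null space (bilinear functions) is likewise
split out as unpenalized columns.

Smoothing parameters are chosen by minimizing either a profiled REML
criterion (default) or GCV over log-smoothing-parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, eigh

from .regression import gaussian_loglik

_NULL_TOL = 1e-9


class GamConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------- terms


@dataclass
class LinearTerm:
    var: str


@dataclass
class SmoothTerm:
    """Univariate penalized cubic spline smooth."""

    var: str
    basis_dim: int = 10
    x_range: tuple[float, float] | None = None


@dataclass
class TensorTerm:
    """Two-way tensor-product smooth (one penalty per margin)."""

    var1: str
    var2: str
    basis_dim: tuple[int, int] = (5, 5)
    x_range: tuple | None = None  # ((lo1, hi1), (lo2, hi2))


Term = LinearTerm | SmoothTerm | TensorTerm


# ------------------------------------------------------- basis building


def _uniform_knots(lo: float, hi: float, ndim: int) -> np.ndarray:
    """Uniform cubic B-spline knots giving ``ndim`` basis functions whose
    full-support domain is [lo, hi]."""
    if ndim < 4:
        raise ValueError("basis_dim must be >= 4")
    h = (hi - lo) / (ndim - 3)
    return lo + h * (np.arange(ndim + 4) - 3.0)


def bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(
        np.asarray(x, dtype=float), knots, 3, extrapolate=True
    ).toarray()


def difference_penalty(ndim: int, order: int = 2) -> np.ndarray:
    """Positive semi-definite penalty DᵀD from order-``order`` coefficient
    differences; its null space holds polynomial coefficient sequences of
    degree < order (constant and linear for order 2)."""
    D = np.diff(np.eye(ndim), n=order, axis=0)
    return D.T @ D


def build_spline_basis(x: np.ndarray, basis_dim: int = 10,
                       x_range: tuple[float, float] | None = None):
    """Cubic B-spline basis with second-order difference penalty.

    Returns ``(basis, penalty, knots)``.  The penalty is symmetric PSD
    and its null space spans constant and linear functions of ``x``.
    Raises when ``x`` has fewer than ``basis_dim`` distinct values.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < basis_dim:
        raise ValueError(
            f"need at least basis_dim={basis_dim} distinct values, "
            f"got {len(np.unique(x))}"
        )
    lo = min(x.min(), x_range[0]) if x_range else x.min()
    hi = max(x.max(), x_range[1]) if x_range else x.max()
    knots = _uniform_knots(lo, hi, basis_dim)
    return bspline_design(x, knots), difference_penalty(basis_dim), knots


def tensor_design(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product of two marginal bases."""
    n = B1.shape[0]
    return (B1[:, :, None] * B2[:, None, :]).reshape(n, -1)


# --------------------------------------------------- fitted term blocks


@dataclass
class _Block:
    """A term's contribution to the design: unpenalized columns plus an
    optional penalized block with its penalty matrices."""

    term: Term
    unpen: np.ndarray  # (n, m)
    pen: np.ndarray | None  # (n, q) or None
    penalties: list  # list of (q, q) arrays, or ["ident"] markers
    transform: dict  # whatever predict() needs to rebuild columns


def _center(x, mean):
    return np.asarray(x, dtype=float) - mean


def _build_block(term: Term, data: pd.DataFrame) -> _Block:
    if isinstance(term, LinearTerm):
        x = data[term.var].to_numpy(float)
        m = x.mean()
        return _Block(term, _center(x, m)[:, None], None, [],
                      {"mean": m})

    if isinstance(term, SmoothTerm):
        x = data[term.var].to_numpy(float)
        B, P, knots = build_spline_basis(x, term.basis_dim, term.x_range)
        w, U = eigh(P)
        null = w < _NULL_TOL * w[-1]
        Upos, wpos = U[:, ~null], w[~null]
        Tpen = Upos / np.sqrt(wpos)  # coefficient-space transform
        m = x.mean()
        return _Block(
            term,
            _center(x, m)[:, None],
            B @ Tpen,
            ["ident"],
            {"knots": knots, "Tpen": Tpen, "mean": m},
        )

    if isinstance(term, TensorTerm):
        x1 = data[term.var1].to_numpy(float)
        x2 = data[term.var2].to_numpy(float)
        r1, r2 = (term.x_range or (None, None))
        d1, d2 = term.basis_dim
        B1, P1, k1 = build_spline_basis(x1, d1, r1)
        B2, P2, k2 = build_spline_basis(x2, d2, r2)
        T = tensor_design(B1, B2)
        S1 = np.kron(P1, np.eye(d2))
        S2 = np.kron(np.eye(d1), P2)
        w, U = eigh(S1 + S2)
        null = w < _NULL_TOL * w[-1]
        Upos, wpos = U[:, ~null], w[~null]
        scale = 1.0 / np.sqrt(wpos)
        Tpen = Upos * scale
        S1p = Tpen.T @ S1 @ Tpen
        S2p = Tpen.T @ S2 @ Tpen
        m1, m2 = x1.mean(), x2.mean()
        xc, zc = _center(x1, m1), _center(x2, m2)
        unpen = np.column_stack([xc, zc, xc * zc])
        return _Block(term, unpen, T @ Tpen, [S1p, S2p],
                      {"knots": (k1, k2), "Tpen": Tpen, "means": (m1, m2)})

    raise TypeError(f"unknown term type: {term!r}")


def _block_columns(block: _Block, data: pd.DataFrame,
                   drop_pen: bool) -> np.ndarray:
    """Rebuild a block's design columns for new data."""
    t, tr = block.term, block.transform
    if isinstance(t, LinearTerm):
        return _center(data[t.var].to_numpy(float), tr["mean"])[:, None]
    if isinstance(t, SmoothTerm):
        x = data[t.var].to_numpy(float)
        cols = [_center(x, tr["mean"])[:, None]]
        if not drop_pen:
            cols.append(bspline_design(x, tr["knots"]) @ tr["Tpen"])
        return np.hstack(cols)
    x1 = data[t.var1].to_numpy(float)
    x2 = data[t.var2].to_numpy(float)
    m1, m2 = tr["means"]
    xc, zc = _center(x1, m1), _center(x2, m2)
    cols = [np.column_stack([xc, zc, xc * zc])]
    if not drop_pen:
        k1, k2 = tr["knots"]
        T = tensor_design(bspline_design(x1, k1), bspline_design(x2, k2))
        cols.append(T @ tr["Tpen"])
    return np.hstack(cols)


# -------------------------------------------------------------- fitting


@dataclass
class GamFit:
    """A fitted penalized additive model."""

    terms: list[Term]
    blocks: list[_Block]
    coef: np.ndarray
    lambdas: np.ndarray
    edf: float
    sigma2: float  # MLE residual variance on the training data
    n_train: int
    response: str
    method: str
    train_means: pd.Series
    drop_pen: bool = False
    criterion_value: float = np.nan

    @property
    def train_loglik(self) -> float:
        return -0.5 * self.n_train * (np.log(2 * np.pi * self.sigma2) + 1.0)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(data), 1))]
        cols += [_block_columns(b, data, self.drop_pen) for b in self.blocks]
        return np.hstack(cols)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.design(data) @ self.coef

    def heldout_loglik(self, data: pd.DataFrame, response: str | None = None) -> float:
        y = data[response or self.response].to_numpy(float)
        return gaussian_loglik(y, self.predict(data), self.sigma2)


def _assemble(blocks: list[_Block], n: int, drop_pen: bool):
    """Stack blocks into a design matrix, recording penalized slices."""
    cols = [np.ones((n, 1))]
    pen_entries = []  # (slice, penalty matrix or "ident")
    offset = 1
    for b in blocks:
        cols.append(b.unpen)
        offset += b.unpen.shape[1]
        if b.pen is not None and not drop_pen:
            q = b.pen.shape[1]
            cols.append(b.pen)
            for S in b.penalties:
                pen_entries.append((slice(offset, offset + q), S))
            offset += q
    return np.hstack(cols), pen_entries


def fit_gam(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[Term],
    method: str = "reml",
    lambdas: Sequence[float] | float | None = None,
    start_rho: np.ndarray | None = None,
    maxfev: int = 400,
) -> GamFit:
    """Fit a penalized Gaussian additive model.

    Parameters
    ----------
    data, response
        Training frame and the response column name.
    terms
        Model terms (linear, smooth, tensor); an intercept is always
        included.
    method
        ``"reml"`` (profiled restricted likelihood, default) or
        ``"gcv"`` for smoothing-parameter selection.
    lambdas
        Fixed smoothing parameter(s) bypassing selection.  A scalar is
        broadcast to every penalty; ``np.inf`` collapses all smooths to
        their null space (linear/bilinear fits).
    start_rho
        Warm start for the log-smoothing-parameter search.
    """
    y = data[response].to_numpy(float)
    n = len(y)
    blocks = [_build_block(t, data) for t in terms]

    drop_pen = False
    if lambdas is not None and np.all(np.isinf(np.atleast_1d(lambdas))):
        drop_pen = True
    X, pen_entries = _assemble(blocks, n, drop_pen)
    n_pen = len(pen_entries)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need n > total basis dimension, got n={n}, p={p}")
    # unpenalized column count (penalized slices repeat for tensor terms)
    pen_cols = set()
    for sl, _ in pen_entries:
        pen_cols.update(range(sl.start, sl.stop))
    M = p - len(pen_cols)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def penalized_solve(lam: np.ndarray, jitter: bool = False):
        A = XtX.copy()
        for (sl, S), l in zip(pen_entries, lam):
            if isinstance(S, str):  # identity penalty
                A[sl, sl] += l * np.eye(sl.stop - sl.start)
            else:
                A[sl, sl] += l * S
        eps = 0.0
        for _ in range(6):
            try:
                c, low = cho_factor(A + eps * np.eye(p), lower=True)
                break
            except np.linalg.LinAlgError:
                if not jitter:
                    raise
                eps = max(eps * 100.0, 1e-10 * np.mean(np.diag(A)))
        else:
            raise GamConvergenceError("penalized normal equations not positive definite")
        beta = cho_solve((c, low), Xty)
        logdet_A = 2.0 * np.sum(np.log(np.diag(c)))
        return beta, (c, low), logdet_A

    def logdet_S(lam: np.ndarray) -> float:
        # grouped per block: identity blocks contribute q log λ; tensor
        # blocks need the eigenvalues of λ1 S1' + λ2 S2'
        total = 0.0
        i = 0
        for b in blocks:
            if b.pen is None or drop_pen:
                continue
            q = b.pen.shape[1]
            if b.penalties == ["ident"]:
                total += q * np.log(lam[i])
                i += 1
            else:
                S = sum(l * Sj for l, Sj in zip(lam[i : i + len(b.penalties)], b.penalties))
                w = np.linalg.eigvalsh(S)
                # w > 0 in exact arithmetic (the joint null space was removed);
                # guard against eigvalsh round-off at extreme lambdas
                w = np.maximum(w, 1e-14 * max(w[-1], np.min(lam[i : i + len(b.penalties)])))
                total += float(np.sum(np.log(w)))
                i += len(b.penalties)
        return total

    def criterion(rho: np.ndarray) -> float:
        lam = np.exp(np.clip(rho, -20.0, 28.0))
        try:
            beta, chol, logdet_A = penalized_solve(lam)
        except np.linalg.LinAlgError:
            return np.inf  # infeasible corner of the lambda space
        if method == "reml":
            rss_p = max(yty - beta @ Xty, np.finfo(float).tiny)
            return (n - M) * np.log(rss_p) + logdet_A - logdet_S(lam)
        # GCV
        resid = y - X @ beta
        rss = float(resid @ resid)
        edf = float(np.trace(cho_solve(chol, XtX)))
        return n * rss / max(n - edf, 1e-8) ** 2

    if n_pen == 0 or drop_pen:
        lam = np.array([])
        beta, chol, _ = penalized_solve(lam, jitter=True)
        crit = np.nan
    elif lambdas is not None:
        lam = np.broadcast_to(np.atleast_1d(np.asarray(lambdas, float)), (n_pen,)).copy()
        beta, chol, _ = penalized_solve(lam, jitter=True)
        crit = np.nan
    else:
        rho0 = np.full(n_pen, 2.0) if start_rho is None else np.asarray(start_rho, float)
        res = optimize.minimize(
            criterion, rho0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 0.05, "fatol": 1e-6},
        )
        if not np.isfinite(res.fun):
            raise GamConvergenceError(
                f"smoothing-parameter search failed: {res.message}\n{res}"
            )
        lam = np.exp(np.clip(res.x, -20.0, 28.0))
        beta, chol, _ = penalized_solve(lam, jitter=True)
        crit = float(res.fun)

    resid = y - X @ beta
    sigma2 = float(resid @ resid / n)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    edf = float(np.trace(cho_solve(chol, XtX)))
    return GamFit(
        terms=list(terms),
        blocks=blocks,
        coef=beta,
        lambdas=lam,
        edf=edf,
        sigma2=sigma2,
        n_train=n,
        response=response,
        method=method,
        train_means=data.mean(numeric_only=True),
        drop_pen=drop_pen,
        criterion_value=crit,
    )


def n_penalties(terms: Sequence[Term]) -> int:
    out = 0
    for t in terms:
        if isinstance(t, SmoothTerm):
            out += 1
        elif isinstance(t, TensorTerm):
            out += 2
    return out
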