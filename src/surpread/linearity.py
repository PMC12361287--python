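"""Linearity test of the surprisal → reading-time linking function.

Three additive models are compared on participant-averaged gaze
durations under a shared k-fold split:

baseline
    tensor-product smooths of (Zipf frequency × word length) for the
    current and the previous word — the non-contextual controls;
linear
    baseline + linear surprisal + linear previous-word surprisal;
nonlinear
    baseline + penalized smooths of surprisal and previous-word
    surprisal.

Per fold, the held-out log-likelihood improvements of the linear and
nonlinear models over the baseline are recorded; a paired sign-flip
permutation test asks whether the two improvement series differ beyond
what exchangeability allows.  If the true linking function is linear the
smooths buy nothing and the test should not reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import make_folds
from .gam import GamFit, LinearTerm, SmoothTerm, TensorTerm, Term, fit_gam, n_penalties


@dataclass
class LinearityResult:
    """Fold-wise ΔLL of linear and nonlinear models vs the shared baseline."""

    delta_ll_linear: np.ndarray  # per fold, held-out totals
    delta_ll_nonlinear: np.ndarray
    n_test: np.ndarray
    mean_difference: float  # mean over folds of (nonlinear − linear) per item
    permutation_p: float
    n_perm: int
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def delta_ll_linear_per_item(self) -> np.ndarray:
        return self.delta_ll_linear / self.n_test

    @property
    def delta_ll_nonlinear_per_item(self) -> np.ndarray:
        return self.delta_ll_nonlinear / self.n_test

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("delta_ll_linear", "delta_ll_nonlinear", "n_test"):
            d[key] = [float(v) for v in d[key]]
        return d


def paired_permutation_test(
    d_lin: Sequence[float],
    d_non: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided paired sign-flip permutation p for mean(d_non − d_lin).

    Under the null the two improvement series are exchangeable within
    each pair, so each paired difference has a symmetric sign.  The
    returned p carries the +1 correction: p = (1 + #{|T*| ≥ |T|})/(N+1),
    hence p ∈ [1/(N+1), 1].
    """
    d_lin = np.asarray(d_lin, dtype=float)
    d_non = np.asarray(d_non, dtype=float)
    if d_lin.shape != d_non.shape:
        raise ValueError("paired difference vectors must have equal length")
    if d_lin.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = d_non - d_lin
    T = abs(diff.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diff.size))
    # sorting makes the Monte-Carlo draw invariant to the fold order
    # (signs are i.i.d., so this changes nothing in distribution)
    T_star = np.abs((signs * np.sort(diff)).mean(axis=1))
    return float((1 + np.sum(T_star >= T - 1e-15)) / (n_perm + 1))


def linearity_model_terms(
    tensor_dim: tuple[int, int] = (5, 5),
    smooth_dim: int = 10,
    surprisal_range: tuple[float, float] | None = (0.0, 20.0),
) -> dict[str, list[Term]]:
    """Term lists of the three competing models."""
    base: list[Term] = [
        TensorTerm("zipf_freq", "length_chars", basis_dim=tensor_dim),
        TensorTerm("prev_zipf", "prev_length", basis_dim=tensor_dim),
    ]
    return {
        "baseline": base,
        "linear": base + [LinearTerm("surprisal"), LinearTerm("prev_surprisal")],
        "nonlinear": base
        + [
            SmoothTerm("surprisal", basis_dim=smooth_dim, x_range=surprisal_range),
            SmoothTerm("prev_surprisal", basis_dim=smooth_dim, x_range=surprisal_range),
        ],
    }


def cv_linearity(
    items: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_perm: int = 1000,
    response: str = "mean_gd_ms",
    tensor_dim: tuple[int, int] = (5, 5),
    smooth_dim: int = 10,
    method: str = "reml",
    maxfev_full: int = 300,
    maxfev_fold: int = 80,
    metadata: dict | None = None,
) -> LinearityResult:
    """Cross-validated linear-vs-nonlinear comparison on item-level data.

    ``items`` must carry the response plus ``zipf_freq, length_chars,
    prev_zipf, prev_length, surprisal, prev_surprisal`` (the output of
    :func:`surpread.corpus.average_item_gd` on a spillover-joined
    table).  The three models are fitted on identical folds; smoothing
    parameters are selected per fold, warm-started from a full-data fit.
    """
    data = items.reset_index(drop=True)
    models = linearity_model_terms(tensor_dim, smooth_dim)

    # full-data fits provide warm starts for the per-fold λ searches
    warm: dict[str, np.ndarray | None] = {}
    for name, terms in models.items():
        if n_penalties(terms):
            fit = fit_gam(data, response, terms, method=method, maxfev=maxfev_full)
            warm[name] = np.log(fit.lambdas)
        else:
            warm[name] = None

    folds = make_folds(len(data), k, seed)
    all_idx = np.arange(len(data))
    d_lin, d_non, n_test = [], [], []
    for test_idx in folds:
        train = data.iloc[np.setdiff1d(all_idx, test_idx)]
        test = data.iloc[test_idx]
        ll = {}
        for name, terms in models.items():
            fit = fit_gam(
                train, response, terms, method=method,
                start_rho=warm[name], maxfev=maxfev_fold,
            )
            ll[name] = fit.heldout_loglik(test)
        d_lin.append(ll["linear"] - ll["baseline"])
        d_non.append(ll["nonlinear"] - ll["baseline"])
        n_test.append(len(test_idx))

    d_lin = np.asarray(d_lin)
    d_non = np.asarray(d_non)
    n_test = np.asarray(n_test, dtype=float)
    p = paired_permutation_test(d_lin / n_test, d_non / n_test,
                                n_perm=n_perm, seed=seed)
    return LinearityResult(
        delta_ll_linear=d_lin,
        delta_ll_nonlinear=d_non,
        n_test=n_test,
        mean_difference=float(np.mean(d_non / n_test - d_lin / n_test)),
        permutation_p=p,
        n_perm=n_perm,
        seed=seed,
        metadata=dict(metadata or {}, k=k, method=method, n_items=len(data)),
    )


def predict_slowdown_curve(
    fit: GamFit,
    grid: np.ndarray | int = 101,
    reference: pd.Series | None = None,
    surprisal_var: str = "surprisal",
    label: str | None = None,
    grid_range: tuple[float, float] = (0.0, 20.0),
) -> pd.DataFrame:
    """Predicted reading time over a surprisal grid at reference covariates.

    The grid spans [0, 20] by default; all other covariates are held at
    the training means (or a supplied reference row).  Returns a frame
    with columns ``surprisal``, ``prediction``, ``model``.
    """
    if not any(
        getattr(t, "var", None) == surprisal_var for t in fit.terms
    ):
        raise ValueError(f"fit contains no term in '{surprisal_var}'")
    if isinstance(grid, int):
        grid = np.linspace(grid_range[0], grid_range[1], grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < grid_range[0] - 1e-12 or grid.max() > grid_range[1] + 1e-12:
        raise ValueError(f"grid must lie within {grid_range}")
    ref = reference if reference is not None else fit.train_means
    newdata = pd.DataFrame({surprisal_var: grid})
    for col in ref.index:
        if col != surprisal_var:
            newdata[col] = ref[col]
    return pd.DataFrame(
        {
            "surprisal": grid,
            "prediction": fit.predict(newdata),
            "model": label or ("nonlinear" if any(isinstance(t, SmoothTerm) for t in fit.terms) else "linear"),
        }
    )
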