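"""Cross-validated Δlog-likelihood evaluation of surprisal's predictive power.

For each fold of a k-fold split, a baseline regression (word length,
Zipf frequency, sentence position, previous-word length and frequency)
and a full regression (baseline plus surprisal of the current and
previous word) are fitted on the other k−1 folds; the gain in held-out
log-likelihood from the surprisal terms, per word, is the psychometric
predictive power of a surprisal source.  Fold-level p-values are
combined over folds with Fisher's method.

Fold p-value sources
--------------------
``fold_exact`` (default)
    Likelihood-ratio test of the two nested models computed *within*
    each held-out fold, using the exact finite-sample null of the
    Gaussian likelihood-ratio statistic (the F distribution).  Folds are
    disjoint, so the p-values are independent and uniform under the
    null — the only construction under which Fisher's combination is
    calibrated.
``heldout``
    2 × (held-out ΔLL) of the training fits referred to χ²_df, clamped
    to p = 1 for negative improvements.  Strongly conservative under the
    null (the statistic is not χ² distributed); provided for
    comparability.
``train``
    Classical likelihood-ratio test on the k−1 training folds.  Fold
    statistics share 90% of their data, so Fisher combination is
    anticonservative; provided for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regression import fit_gaussian_linear, heldout_loglik

BASELINE_PREDICTORS = ("length_chars", "zipf_freq", "word_pos", "prev_length", "prev_zipf")
SURPRISAL_PREDICTORS = ("surprisal", "prev_surprisal")
MEASURE_COLUMN = {"ffd": "ffd_ms", "gd": "gd_ms", "trt": "trt_ms"}


@dataclass
class RegressionSpec:
    """Predictor sets for the baseline and full reading-time regressions."""

    response: str = "gd"
    baseline: tuple[str, ...] = BASELINE_PREDICTORS
    surprisal_terms: tuple[str, ...] = SURPRISAL_PREDICTORS
    log_response: bool = False

    @property
    def response_column(self) -> str:
        return MEASURE_COLUMN.get(self.response, self.response)

    @property
    def df(self) -> int:
        return len(self.surprisal_terms)


@dataclass
class FoldResult:
    fold_id: int
    n_test: int
    delta_ll_total: float
    delta_ll_per_word: float
    p_fold: float


@dataclass
class EvalResult:
    """Aggregated cross-validated Δlog-likelihood for one
    (corpus, measure, surprisal source) cell."""

    mean_delta_ll_per_word: float
    se: float
    fisher_p: float
    folds: list[FoldResult]
    metadata: dict = field(default_factory=dict)

    @property
    def per_1000(self) -> float:
        return 1000.0 * self.mean_delta_ll_per_word

    def to_dict(self) -> dict:
        return {
            "mean_delta_ll_per_word": self.mean_delta_ll_per_word,
            "delta_ll_per_1000_words": self.per_1000,
            "se": self.se,
            "fisher_p": self.fisher_p,
            "folds": [asdict(f) for f in self.folds],
            "metadata": self.metadata,
        }


def lrt_p(delta_ll: float, df: int = 2) -> float:
    """Upper-tail χ²_df p-value of a log-likelihood improvement.

    The statistic is 2·ΔLL; negative improvements clamp to p = 1.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if delta_ll <= 0:
        return 1.0
    return float(stats.chi2.sf(2.0 * delta_ll, df))


def fisher_combine(ps: Sequence[float]) -> float:
    """Fisher's combined probability: X = −2 Σ ln p ~ χ²_{2k}."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    X = -2.0 * np.sum(np.log(ps))
    return float(stats.chi2.sf(X, 2 * ps.size))


def _design(table: pd.DataFrame, predictors: Sequence[str]):
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(float) for c in predictors]
    )
    return X, ("intercept",) + tuple(predictors)


def _fold_exact_p(table_test: pd.DataFrame, spec: RegressionSpec, y_test) -> float:
    """Exact Gaussian LRT (F test) of the surprisal terms within a fold."""
    Xb, _ = _design(table_test, spec.baseline)
    Xf, _ = _design(table_test, list(spec.baseline) + list(spec.surprisal_terms))
    n, pf = Xf.shape
    rb = y_test - Xb @ np.linalg.lstsq(Xb, y_test, rcond=None)[0]
    rf = y_test - Xf @ np.linalg.lstsq(Xf, y_test, rcond=None)[0]
    rss_b, rss_f = rb @ rb, rf @ rf
    df1, df2 = spec.df, n - pf
    if df2 <= 0:
        raise ValueError(f"fold too small for exact test: n={n}, p={pf}")
    F = ((rss_b - rss_f) / df1) / (rss_f / df2)
    return float(stats.f.sf(F, df1, df2))


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Partition row indices 0..n−1 into k near-equal folds by a seeded
    uniform shuffle."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


def cv_delta_loglik(
    table: pd.DataFrame,
    spec: RegressionSpec | None = None,
    k: int = 10,
    seed: int = 0,
    p_source: str = "fold_exact",
    metadata: dict | None = None,
) -> EvalResult:
    """k-fold cross-validated Δlog-likelihood of the surprisal terms.

    Parameters
    ----------
    table
        Analysis table (one response row per participant × word) with
        the response column and all predictors of ``spec``.
    spec
        Predictor specification; defaults to the gaze-duration spec with
        the standard baseline controls.
    k, seed
        Number of folds and shuffle seed.
    p_source
        Fold p-value construction; see module docstring.

    Returns
    -------
    EvalResult
        Per-fold and aggregated ΔLL per word, SE over folds, and the
        Fisher-combined p-value.
    """
    spec = spec or RegressionSpec()
    if p_source not in ("fold_exact", "heldout", "train"):
        raise ValueError(f"unknown p_source: {p_source}")
    data = table.reset_index(drop=True)
    y = data[spec.response_column].to_numpy(float)
    if spec.log_response:
        y = np.log(y)
    Xb, cols_b = _design(data, spec.baseline)
    Xf, cols_f = _design(data, list(spec.baseline) + list(spec.surprisal_terms))

    folds = make_folds(len(data), k, seed)
    results: list[FoldResult] = []
    all_idx = np.arange(len(data))
    for fold_id, test_idx in enumerate(folds, start=1):
        train = np.setdiff1d(all_idx, test_idx, assume_unique=False)
        fit_b = fit_gaussian_linear(Xb[train], y[train], cols_b)
        fit_f = fit_gaussian_linear(Xf[train], y[train], cols_f)
        dll = heldout_loglik(fit_f, Xf[test_idx], y[test_idx]) - heldout_loglik(
            fit_b, Xb[test_idx], y[test_idx]
        )
        if p_source == "fold_exact":
            p = _fold_exact_p(data.iloc[test_idx], spec, y[test_idx])
        elif p_source == "heldout":
            p = lrt_p(dll, spec.df)
        else:  # train
            p = lrt_p(fit_f.train_loglik - fit_b.train_loglik, spec.df)
        results.append(
            FoldResult(
                fold_id=fold_id,
                n_test=len(test_idx),
                delta_ll_total=float(dll),
                delta_ll_per_word=float(dll / len(test_idx)),
                p_fold=p,
            )
        )
    per_word = np.array([f.delta_ll_per_word for f in results])
    return EvalResult(
        mean_delta_ll_per_word=float(per_word.mean()),
        se=float(per_word.std(ddof=1) / np.sqrt(k)),
        fisher_p=fisher_combine([f.p_fold for f in results]),
        folds=results,
        metadata=dict(metadata or {}, k=k, seed=seed, p_source=p_source,
                      response=spec.response, n_rows=len(data)),
    )


@dataclass
class ScalingResult:
    """Meta-regression of predictive-power gain on model size."""

    slope_per_100M: float
    se: float
    t: float
    p: float
    formula: str
    n_cells: int


def scaling_regression(
    results: Sequence[EvalResult] | pd.DataFrame,
    gain_scale: float = 1000.0,
) -> ScalingResult:
    """Regress ΔLogLik gain on model size (per 100 million parameters).

    Each input cell is one (corpus, measure, model) evaluation.  The
    regression includes main effects of corpus and eye-tracking measure
    and interactions of model size with corpus and with model family;
    the reported slope is the main effect of size.  A negative slope is
    the inverse scaling trend: surprisal from larger models predicting
    reading times worse.

    Parameters
    ----------
    results
        EvalResults whose metadata carries ``corpus``, ``measure``,
        ``family`` and ``n_params`` (parameter count), or an equivalent
        DataFrame with columns ``gain, corpus, measure, family, size_100M``.
    gain_scale
        Multiplier applied to ΔLL per word before regression (default:
        per 1,000 words).
    """
    import statsmodels.formula.api as smf

    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            {
                "gain": [gain_scale * r.mean_delta_ll_per_word for r in results],
                "corpus": [r.metadata.get("corpus", "corpus") for r in results],
                "measure": [r.metadata.get("measure", r.metadata.get("response", "gd"))
                            for r in results],
                "family": [r.metadata.get("family", "family") for r in results],
                "size_100M": [r.metadata.get("n_params", np.nan) / 1e8 for r in results],
            }
        )
    if df["size_100M"].isna().any():
        raise ValueError("every result needs an n_params metadata entry")
    if df["size_100M"].nunique() < 2:
        raise ValueError("need at least 2 distinct model sizes")

    terms = ["size_100M"]
    for factor in ("corpus", "measure"):
        if df[factor].nunique() > 1:
            terms.append(f"C({factor})")
    for factor in ("corpus", "family"):
        if df[factor].nunique() > 1:
            terms.append(f"size_100M:C({factor})")
    formula = "gain ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    return ScalingResult(
        slope_per_100M=float(fit.params["size_100M"]),
        se=float(fit.bse["size_100M"]),
        t=float(fit.tvalues["size_100M"]),
        p=float(fit.pvalues["size_100M"]),
        formula=formula,
        n_cells=len(df),
    )
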