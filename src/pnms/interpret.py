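"""Structural interpretation of the pNMS via an additive model.

Predicts the per-patient PET asymmetry index (the scalar expression of
the pNMS) from five structural features — total intracranial volume,
ipsilateral hippocampal and amygdalar volumes, and the volumetric
asymmetry indices of both structures — with a Gaussian additive model,
then interprets the fit with exact Shapley values, partial dependence
curves, repeated k-fold cross-validation, and the actual-vs-predicted
Pearson correlation.

The additive model is unpenalized: one 3-knot restricted-cubic-spline
smooth per feature (the same basis as the outcome regressions), fitted
by least squares. At the cohort sizes involved (tens of subjects, five
features) this is the smallest model class that is a genuine GAM yet
exactly reproducible, with no smoothing-parameter search.

Shapley values use the retrain-per-subset payoff: for every subset S of
features a model is refitted on S and the coalition value for a subject
is that model's prediction (the empty set predicts the target mean).
With five features all 2^5 subsets are enumerated, so the attributions
are exact and satisfy efficiency, symmetry and the null-player axiom by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .stats import knots_from_percentiles, pearson_corr, rcs_basis

__all__ = [
    "STRUCTURAL_FEATURES",
    "AdditiveModelFit",
    "ShapleyReport",
    "fit_additive_model",
    "cross_validate",
    "shapley_importance",
    "partial_dependence",
    "prediction_correlation",
]

#: canonical structural-feature columns, in reporting order
STRUCTURAL_FEATURES = [
    "tiv",
    "hippo_volume_ipsi",
    "amyg_volume_ipsi",
    "hippo_vai",
    "amyg_vai",
]

MAX_EXACT_FEATURES = 12


@dataclass
class AdditiveModelFit:
    """An unpenalized spline additive model y ~ sum_j f_j(x_j)."""

    features: list[str]
    knots: dict[str, np.ndarray | None]  # None -> linear term only
    coef: np.ndarray
    intercept_index: int
    col_slices: dict[str, slice]
    fitted: np.ndarray
    target_mean: float

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(X), 1))]
        for f in self.features:
            x = np.asarray(X[f], dtype=float)
            k = self.knots[f]
            cols.append(x[:, None] if k is None else rcs_basis(x, k))
        return np.hstack(cols)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self._design(X) @ self.coef

    def smooth(self, feature: str, x: np.ndarray) -> np.ndarray:
        """The fitted per-feature smooth f_j(x) (no intercept)."""
        x = np.asarray(x, dtype=float)
        k = self.knots[feature]
        block = x[:, None] if k is None else rcs_basis(x, k)
        return block @ self.coef[self.col_slices[feature]]


def _feature_knots(x: np.ndarray) -> np.ndarray | None:
    """Spline knots for a feature, or None to fall back to a linear term."""
    try:
        return knots_from_percentiles(x)
    except ValueError:
        return None  # too few distinct values for a stable smooth


def fit_additive_model(
    X: pd.DataFrame,
    y: np.ndarray,
    features: list[str] | None = None,
    allow_rank_deficient: bool = False,
) -> AdditiveModelFit:
    """Least-squares fit of the spline additive model.

    Raises on missing values and on rank deficiency, naming the feature
    whose columns are collinear. ``allow_rank_deficient=True`` keeps the
    minimum-norm least-squares solution instead (fitted values and
    predictions stay well defined — they are the projection onto the
    column space — even though individual coefficients are not); the
    Shapley payoffs use this, since feature subsets may be collinear.
    """
    features = list(features if features is not None else X.columns)
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ValueError("feature table and target length differ")
    sub = X[features]
    if sub.isna().any().any() or np.any(~np.isfinite(y)):
        raise ValueError("missing values in features or target; drop them first")

    knots: dict[str, np.ndarray | None] = {}
    col_slices: dict[str, slice] = {}
    cols = [np.ones((len(X), 1))]
    start = 1
    for f in features:
        x = np.asarray(sub[f], dtype=float)
        k = _feature_knots(x)
        knots[f] = k
        block = x[:, None] if k is None else rcs_basis(x, k)
        cols.append(block)
        col_slices[f] = slice(start, start + block.shape[1])
        start += block.shape[1]
    D = np.hstack(cols)
    if y.size <= D.shape[1]:
        raise ValueError(
            f"additive model has {D.shape[1]} parameters but only {y.size} observations"
        )
    if not allow_rank_deficient:
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            culprit = _rank_deficient_feature(D, col_slices, features)
            raise ValueError(f"rank-deficient design; feature {culprit!r} is collinear")
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return AdditiveModelFit(
        features=features,
        knots=knots,
        coef=coef,
        intercept_index=0,
        col_slices=col_slices,
        fitted=D @ coef,
        target_mean=float(y.mean()),
    )


def _rank_deficient_feature(
    D: np.ndarray, col_slices: dict[str, slice], features: list[str]
) -> str:
    for f in features:
        keep = [0] + [j for g in features if g != f for j in range(*col_slices[g].indices(D.shape[1]))]
        if np.linalg.matrix_rank(D[:, keep]) == np.linalg.matrix_rank(D):
            return f
    return features[-1]


# --------------------------------------------------------------------------
# cross-validation


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 5,
    iterations: int = 1000,
    seed: int = 0,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Repeated k-fold cross-validated predictions with percentile intervals.

    Each iteration draws a fresh seeded partition into k folds (sizes
    differing by at most one; every subject out-of-fold exactly once per
    iteration), refits the additive model on the training folds and
    predicts the held-out subjects. Returns one row per subject with the
    across-iteration mean prediction and the 2.5/97.5 percentile
    interval.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} subjects")
    if k < 2:
        raise ValueError("need at least 2 folds")
    features = list(features if features is not None else X.columns)
    rng = np.random.default_rng(seed)
    preds = np.empty((iterations, n))
    for it in range(iterations):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for hold in folds:
            train = np.setdiff1d(perm, hold, assume_unique=True)
            fit = fit_additive_model(X.iloc[train], y[train], features)
            preds[it, hold] = fit.predict(X.iloc[hold])
    lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "prediction": preds.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
            "actual": y,
        },
        index=X.index,
    )


# --------------------------------------------------------------------------
# Shapley attribution


@dataclass
class ShapleyReport:
    """Exact Shapley attribution of the additive-model predictions."""

    features: list[str]
    per_subject: pd.DataFrame          # (n_subjects, n_features) signed values
    mean_signed: pd.Series             # the reported "feature weight"
    mean_abs: pd.Series                # magnitude ranking
    baseline: float                    # empty-coalition prediction = mean target
    extra: dict = field(default_factory=dict)

    def top_feature(self) -> str:
        return str(self.mean_abs.idxmax())


def shapley_importance(
    X: pd.DataFrame, y: np.ndarray, features: list[str] | None = None
) -> ShapleyReport:
    """Exact Shapley values with the retrain-per-subset payoff.

    The coalition value v(S) for a subject is the prediction of an
    additive model refitted using only the features in S; v(empty) is
    the target mean. All subsets are enumerated, so per-subject
    contributions satisfy efficiency exactly: they sum to
    prediction(full model) - mean(target).
    """
    features = list(features if features is not None else X.columns)
    p = len(features)
    if p > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{p} features need 2^{p} refits; exact enumeration is capped at "
            f"{MAX_EXACT_FEATURES} — use a sampling approximation instead"
        )
    y = np.asarray(y, dtype=float)
    n = y.size
    baseline = float(y.mean())

    payoff: dict[frozenset, np.ndarray] = {frozenset(): np.full(n, baseline)}
    for r in range(1, p + 1):
        for subset in combinations(features, r):
            fit = fit_additive_model(X, y, list(subset), allow_rank_deficient=True)
            payoff[frozenset(subset)] = fit.predict(X)

    fact = [factorial(i) for i in range(p + 1)]
    values = np.zeros((n, p))
    for i, f in enumerate(features):
        others = [g for g in features if g != f]
        for r in range(p):
            w = fact[r] * fact[p - r - 1] / fact[p]
            for subset in combinations(others, r):
                s = frozenset(subset)
                values[:, i] += w * (payoff[s | {f}] - payoff[s])

    per_subject = pd.DataFrame(values, columns=features, index=X.index)
    return ShapleyReport(
        features=features,
        per_subject=per_subject,
        mean_signed=per_subject.mean(axis=0),
        mean_abs=per_subject.abs().mean(axis=0),
        baseline=baseline,
        extra={"payoff_models": 2 ** p, "payoff": "retrain-per-subset"},
    )


# --------------------------------------------------------------------------
# partial dependence and prediction quality


def partial_dependence(
    fit: AdditiveModelFit, X: pd.DataFrame, feature: str, grid: np.ndarray
) -> pd.DataFrame:
    """Partial dependence of the prediction on one feature.

    PD(v) is the mean prediction over subjects with the feature forced
    to v. For an additive model this equals the feature's fitted smooth
    plus a constant. Grid points outside the observed feature range are
    flagged as extrapolation (with a warning) but still evaluated.
    """
    import warnings

    grid = np.asarray(grid, dtype=float)
    obs = np.asarray(X[feature], dtype=float)
    extrapolated = (grid < obs.min()) | (grid > obs.max())
    if extrapolated.any():
        warnings.warn(
            f"{int(extrapolated.sum())} grid points outside the observed range of "
            f"{feature!r}: partial dependence is extrapolated there",
            stacklevel=2,
        )
    pd_vals = np.empty(grid.size)
    Xi = X.copy()
    for i, v in enumerate(grid):
        Xi[feature] = v
        pd_vals[i] = float(fit.predict(Xi).mean())
    return pd.DataFrame({"grid": grid, "pd": pd_vals, "extrapolated": extrapolated})


def prediction_correlation(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between actual and predicted targets (r, P)."""
    return pearson_corr(np.asarray(actual, float), np.asarray(predicted, float))
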