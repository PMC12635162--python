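"""Inferential statistics for the pNMS analysis.

Restricted-cubic-spline (RCS) logistic regression with BIC model
selection and inflection-point threshold discovery; odds-ratio reports;
ROC/Youden cutoff selection with balanced and prevalence-weighted
accuracy; and the standard two-group comparison tests (t, Mann-Whitney,
Pearson chi-square, likelihood-ratio G^2, Fisher exact, ANCOVA, Pearson
correlation).

The RCS uses Harrell's restricted basis: with three knots t1 < t2 < t3
the design adds, beyond the linear term x, a single nonlinear column

    s(x) = [ (x-t1)+^3 - (x-t2)+^3 (t3-t1)/(t3-t2)
                       + (x-t3)+^3 (t2-t1)/(t3-t2) ] / (t3-t1)^2

which makes the fitted function linear outside [t1, t3]. Knots sit at
the 10th/50th/90th percentiles of the predictor by default. The test of
nonlinearity is a 1-df likelihood-ratio test of the s(x) column; the
overall predictor test is the 2-df likelihood ratio of both columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "LogisticFit",
    "RCSFit",
    "InflectionResult",
    "ClassifierEval",
    "rcs_basis",
    "knots_from_percentiles",
    "fit_logistic",
    "odds_ratio_report",
    "rcs_logistic_curve",
    "select_rcs_by_bic",
    "find_inflection",
    "roc_youden",
    "confusion_metrics",
    "pearson_chi2",
    "g_test",
    "fisher_exact",
    "two_group_test",
    "ancova",
    "pearson_corr",
]


# --------------------------------------------------------------------------
# spline basis


def knots_from_percentiles(
    x: np.ndarray, probs: tuple[float, ...] = (0.10, 0.50, 0.90)
) -> np.ndarray:
    """Empirical-quantile knots (linear-interpolation / type-7 quantiles)."""
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 10:
        raise ValueError("need at least 10 distinct values to place knots")
    knots = np.quantile(x, probs)  # numpy default = linear interpolation (type 7)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"ties collapse the knots {knots}; spread the predictor or change probs")
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design columns [x, s(x)] of the 3-knot restricted cubic spline."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.size != 3:
        raise ValueError("exactly three knots are required")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    t1, t2, t3 = knots

    def p3(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    s = (
        p3(x - t1)
        - p3(x - t2) * (t3 - t1) / (t3 - t2)
        + p3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, s])


# --------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    bic: float
    n: int
    converged: bool
    separation: bool
    names: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS via statsmodels GLM).

    ``X`` must already contain the intercept column. BIC is computed as
    ``-2 loglik + k ln n``. (Quasi-)complete separation is detected from
    fitted probabilities pinned at 0/1 on a perfectly classified sample
    and reported via the ``separation`` flag together with a warning;
    the diverging coefficients are returned as-is for inspection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    if not set(classes).issubset({0.0, 1.0}):
        raise ValueError("outcome must be binary 0/1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200, tol=1e-10)
    mu = res.fittedvalues
    separation = bool(np.all((mu > 0.5) == (y > 0.5)) and
                      (np.min(np.abs(mu - 0.5)) > 0.4999))
    if separation:
        warnings.warn("perfect separation detected: coefficients diverge", stacklevel=2)
    ll = float(res.llf)
    return LogisticFit(
        params=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        loglik=ll,
        bic=-2.0 * ll + k * np.log(n),
        n=n,
        converged=bool(res.converged),
        separation=separation,
        names=names or [f"x{i}" for i in range(k)],
    )


def odds_ratio_report(
    feature: np.ndarray, y: np.ndarray, scale: float = 1.0
) -> dict:
    """Univariate logistic odds ratio with Wald 95% CI and P value.

    ``scale`` is the per-unit multiplier on the predictor: OR =
    exp(beta * scale), e.g. scale=0.01 reports the OR per 0.01 units of
    asymmetry index. The scale used is echoed in the result so it is
    never implicit.
    """
    feature = np.asarray(feature, dtype=float)
    X = sm.add_constant(feature)
    fit = fit_logistic(X, y, names=["const", "feature"])
    beta, se = fit.params[1], fit.se[1]
    z = sps.norm.ppf(0.975)
    return {
        "or": float(np.exp(beta * scale)),
        "ci_low": float(np.exp((beta - z * se) * scale)),
        "ci_high": float(np.exp((beta + z * se) * scale)),
        "p": float(2 * sps.norm.sf(abs(beta / se))) if se > 0 else np.nan,
        "beta": float(beta),
        "se": float(se),
        "scale": scale,
        "separation": fit.separation,
    }


# --------------------------------------------------------------------------
# RCS logistic curve


@dataclass
class RCSFit:
    """A fitted restricted-cubic-spline logistic model for one predictor."""

    knots: np.ndarray
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    bic: float
    n: int
    n_params: int
    grid_x: np.ndarray
    grid_logodds: np.ndarray
    grid_or: np.ndarray          # OR vs reference_x
    grid_or_ci: np.ndarray       # (grid, 2) Wald 95% CI of the OR
    p_nonlinearity: float
    p_overall: float
    reference_x: float
    predictor: str = "x"
    spline: bool = True


def _lr_pvalue(ll_full: float, ll_reduced: float, df: int) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(sps.chi2.sf(stat, df))


def rcs_logistic_curve(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    knot_probs: tuple[float, ...] = (0.10, 0.50, 0.90),
    grid_size: int = 200,
    reference_x: float | None = None,
    predictor: str = "x",
    linear: bool = False,
) -> RCSFit:
    """Fit outcome ~ rcs(x) + covariates by logistic regression.

    The fitted log-odds curve is evaluated on a ``grid_size``-point grid
    spanning the [2.5th, 97.5th] percentiles of ``x`` with covariates
    held at their means. The odds ratio is referenced at ``reference_x``
    (default: the median of x), where OR = 1 by construction.
    ``p_nonlinearity`` is the 1-df likelihood-ratio test of the spline
    column; ``p_overall`` the 2-df test of both predictor columns.
    ``linear=True`` fits the nested model without the spline column (its
    ``p_nonlinearity`` is NaN), for BIC comparison.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]

    knots = knots_from_percentiles(x, knot_probs)
    basis = rcs_basis(x, knots)
    if linear:
        basis = basis[:, :1]

    def design(b: np.ndarray, c: np.ndarray | None) -> np.ndarray:
        cols = [np.ones((b.shape[0], 1)), b]
        if c is not None:
            cols.append(c)
        return np.hstack(cols)

    fit_full = fit_logistic(design(basis, cov), y)
    # nested fits for the LR tests
    fit_nocurve = fit_logistic(design(basis[:, :1], cov), y) if not linear else fit_full
    X_null = np.hstack([np.ones((n, 1)), cov]) if cov is not None else np.ones((n, 1))
    fit_null = fit_logistic(X_null, y)

    p_nonlin = np.nan if linear else _lr_pvalue(fit_full.loglik, fit_nocurve.loglik, 1)
    p_overall = _lr_pvalue(fit_full.loglik, fit_null.loglik, basis.shape[1])

    lo, hi = np.percentile(x, [2.5, 97.5])
    grid = np.linspace(lo, hi, grid_size)
    ref = float(np.median(x)) if reference_x is None else float(reference_x)

    def predictor_block(g: np.ndarray) -> np.ndarray:
        b = rcs_basis(g, knots)
        return b[:, :1] if linear else b

    # design rows at grid (covariates at mean), for the curve and its CI
    cov_mean = cov.mean(axis=0) if cov is not None else None

    def full_rows(g: np.ndarray) -> np.ndarray:
        b = predictor_block(g)
        cols = [np.ones((g.size, 1)), b]
        if cov_mean is not None:
            cols.append(np.tile(cov_mean, (g.size, 1)))
        return np.hstack(cols)

    rows_g = full_rows(grid)
    rows_ref = full_rows(np.array([ref]))
    logodds = rows_g @ fit_full.params
    diff_rows = rows_g - rows_ref  # covariate columns cancel
    log_or = diff_rows @ fit_full.params
    var = np.einsum("ij,jk,ik->i", diff_rows, fit_full.cov, diff_rows)
    se = np.sqrt(np.maximum(var, 0.0))
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # near-separation CIs may hit inf
        or_ci = np.exp(np.column_stack([log_or - z * se, log_or + z * se]))

    return RCSFit(
        knots=knots,
        params=fit_full.params,
        cov=fit_full.cov,
        loglik=fit_full.loglik,
        bic=fit_full.bic,
        n=n,
        n_params=fit_full.params.size,
        grid_x=grid,
        grid_logodds=logodds,
        grid_or=np.exp(log_or),
        grid_or_ci=or_ci,
        p_nonlinearity=p_nonlin,
        p_overall=p_overall,
        reference_x=ref,
        predictor=predictor,
        spline=not linear,
    )


def select_rcs_by_bic(fits: list[RCSFit]) -> RCSFit:
    """Pick the candidate with the lowest BIC; ties go to fewer parameters."""
    if not fits:
        raise ValueError("no candidate fits")
    if len({f.n for f in fits}) != 1:
        raise ValueError("candidates were fitted on different sample sizes")
    return min(fits, key=lambda f: (f.bic, f.n_params))


# --------------------------------------------------------------------------
# inflection / reference-point discovery


@dataclass
class InflectionResult:
    """Reference thresholds read off a fitted log-odds curve."""

    points: list[float]          # x locations of direction changes (or the elbow)
    kinds: list[str]             # "extremum" per sign change, or a single "elbow"
    shape: str                   # one of {"U", "N", "L", "monotone", "flat"}
    reference: float | None      # the primary threshold (first point), None if flat


def find_inflection(fit: RCSFit, flat_tol: float = 1e-8) -> InflectionResult:
    """Locate where the fitted log-odds curve changes direction.

    Interior extrema — sign changes of the first difference of the
    fitted curve on its grid — are the reference points (a U or N
    shape). A curve with no sign change is monotone in the strict
    sense; clinically it may still be L-shaped (one flat arm, one steep
    arm). For those the point of maximum absolute second difference
    (the curvature elbow) is returned, labelled "elbow", with shape "L"
    when one arm is substantially flatter than the other and "monotone"
    otherwise. A flat curve (range below ``flat_tol``) yields no
    reference rather than an exception.
    """
    yg = np.asarray(fit.grid_logodds, dtype=float)
    xg = np.asarray(fit.grid_x, dtype=float)
    if yg.max() - yg.min() < flat_tol:
        return InflectionResult([], [], "flat", None)

    d1 = np.diff(yg)
    signs = np.sign(d1)
    signs[signs == 0] = 1  # treat exact plateaus as continuing direction
    changes = np.nonzero(signs[1:] != signs[:-1])[0]
    if changes.size:
        pts = [float(xg[i + 1]) for i in changes]
        # direction pattern: down-then-up = U, up-then-down = N
        shape = "U" if signs[changes[0]] < 0 else "N"
        return InflectionResult(pts, ["extremum"] * len(pts), shape, pts[0])

    # monotone: curvature elbow
    d2 = np.abs(np.diff(yg, 2))
    elbow_i = int(np.argmax(d2)) + 1
    elbow = float(xg[elbow_i])
    # L-shape if one third of the curve is much flatter than the other
    third = max(1, d1.size // 3)
    slope_lo = np.mean(np.abs(d1[:third]))
    slope_hi = np.mean(np.abs(d1[-third:]))
    flat_arm = min(slope_lo, slope_hi) < 0.25 * max(slope_lo, slope_hi)
    shape = "L" if flat_arm else "monotone"
    return InflectionResult([elbow], ["elbow"], shape, elbow)


# --------------------------------------------------------------------------
# classifier evaluation


@dataclass
class ClassifierEval:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float
    balanced_accuracy: float
    weighted_accuracy: float
    overall_accuracy: float
    chi2: float | None = None
    p_value: float | None = None
    threshold_defined: bool = True


def _confusion_at(score: np.ndarray, y: np.ndarray, thr: float) -> tuple[int, int, int, int]:
    pred = score >= thr
    pos, neg = y == 1, y == 0
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & neg))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & neg))
    return tp, fp, fn, tn


def roc_youden(
    score: np.ndarray,
    y: np.ndarray,
    weights: tuple[float, float] | None = None,
) -> ClassifierEval:
    """ROC analysis with the Youden-optimal cutoff.

    Candidate thresholds are the midpoints between consecutive sorted
    unique scores, plus sentinels below the minimum and above the
    maximum; a subject is called positive when ``score >= threshold``.
    The optimal threshold maximizes J = sensitivity + specificity - 1,
    ties broken toward the lower threshold. AUC is the trapezoidal area
    under the empirical ROC curve. ``weights`` sets the
    prevalence-weighted accuracy ``w*sens + (1-w)*spec`` (default: the
    observed positive-class prevalence).
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(score)
    degenerate = uniq.size < 2
    if degenerate:
        cands = np.array([uniq[0]])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        span = uniq[-1] - uniq[0]
        cands = np.concatenate([[uniq[0] - 0.5 * span - 1.0], mids,
                                [uniq[-1] + 0.5 * span + 1.0]])

    sens = np.empty(cands.size)
    spec = np.empty(cands.size)
    n_pos, n_neg = float(np.sum(y == 1)), float(np.sum(y == 0))
    for i, t in enumerate(cands):
        tp, fp, fn, tn = _confusion_at(score, y, t)
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg
    # ROC curve over all cut points: as the threshold falls, FPR and TPR
    # both rise monotonically, so traverse candidates in descending order
    fpr, tpr = 1.0 - spec, sens
    desc = np.argsort(-cands, kind="stable")
    auc = float(np.trapezoid(tpr[desc], fpr[desc])) if not degenerate else 0.5
    j = sens + spec - 1.0
    best = int(np.lexsort((cands, -j))[0])  # max J, then lowest threshold
    thr = float(cands[best])
    tp, fp, fn, tn = _confusion_at(score, y, thr)
    w = weights if weights is not None else (n_pos / (n_pos + n_neg), n_neg / (n_pos + n_neg))
    m = confusion_metrics(tp, fp, fn, tn, weights=w)
    chi2 = p = None
    if min(tp + fp, fn + tn) > 0:
        chi2, p = pearson_chi2(np.array([[tp, fn], [fp, tn]]))
    return ClassifierEval(
        threshold=thr if not degenerate else np.nan,
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        youden_j=m["youden_j"], auc=auc,
        balanced_accuracy=m["balanced_accuracy"],
        weighted_accuracy=m["weighted_accuracy"],
        overall_accuracy=m["overall_accuracy"],
        chi2=chi2, p_value=p,
        threshold_defined=not degenerate,
    )


def confusion_metrics(
    tp: int, fp: int, fn: int, tn: int, weights: tuple[float, float] | None = None
) -> dict:
    """Sensitivity, specificity and the accuracy family from counts.

    Balanced accuracy is the unweighted mean (sens + spec) / 2; the
    weighted accuracy ``w*sens + (1-w)*spec`` uses ``weights=(w, 1-w)``
    (default: the class prevalences, which makes it equal the overall
    accuracy (tp+tn)/n). A zero margin leaves the affected metric NaN.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be nonnegative")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty table")
    pos, neg = tp + fn, tn + fp
    sens = tp / pos if pos else np.nan
    spec = tn / neg if neg else np.nan
    if weights is None:
        weights = (pos / n, neg / n)
    w = weights[0] / (weights[0] + weights[1])
    return {
        "sensitivity": sens,
        "specificity": spec,
        "youden_j": sens + spec - 1.0,
        "balanced_accuracy": (sens + spec) / 2.0,
        "weighted_accuracy": w * sens + (1.0 - w) * spec,
        "overall_accuracy": (tp + tn) / n,
    }


# --------------------------------------------------------------------------
# categorical and auxiliary tests


def _table2x2(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    return t


def pearson_chi2(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of association on a 2x2 table.

    Uncorrected by default: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),
    referred to a 1-df chi-square. ``correction=True`` applies the Yates
    continuity correction.
    """
    t = _table2x2(table)
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero margin: chi-square undefined")
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    stat = n * num ** 2 / margins
    return float(stat), float(sps.chi2.sf(stat, 1))


def g_test(table: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio G^2 test on a 2x2 table (1 df)."""
    t = _table2x2(table)
    n = t.sum()
    expected = np.outer(t.sum(1), t.sum(0)) / n
    if np.any(expected == 0):
        raise ValueError("zero margin: G-test undefined")
    obs = t[t > 0]
    exp = expected[t > 0]
    g = 2.0 * np.sum(obs * np.log(obs / exp))
    return float(g), float(sps.chi2.sf(g, 1))


def fisher_exact(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test (hypergeometric); returns (odds ratio, P)."""
    t = _table2x2(table)
    oddsr, p = sps.fisher_exact(t, alternative="two-sided")
    return float(oddsr), float(p)


def two_group_test(a: np.ndarray, b: np.ndarray, kind: str = "t") -> dict:
    """Two-sided two-sample comparison.

    ``kind``: 't' (pooled-variance Student t), 'welch', or 'mannwhitney'
    (normal-approximated with tie correction; exact for small untied
    samples per scipy's default).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind == "t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    elif kind == "welch":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif kind == "mannwhitney":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return {"statistic": float(stat), "p": float(p), "kind": kind}


def ancova(y: np.ndarray, group: np.ndarray, covariate: np.ndarray) -> dict:
    """Group effect on y adjusted for one covariate (linear-model F test)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("need at least two groups")
    X_full = sm.add_constant(np.column_stack([g, c]))
    X_red = sm.add_constant(c)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_num = 1
    df_den = full.df_resid
    f = (red.ssr - full.ssr) / df_num / (full.ssr / df_den)
    return {"F": float(f), "p": float(sps.f.sf(f, df_num, df_den))}


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based P value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
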