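"""Outcome-model statistics: logistic regression, stratified split, AUROC,
DeLong paired comparison, Fisher exact, Wilcoxon rank-sum, cohort summaries.

These are implemented from first principles (IRLS, placement values,
hypergeometric enumeration, rank-sum enumeration) so that every quantity in
the biomarker-evaluation workflow is auditable; library equivalents serve
only as independent cross-checks in the test suite.

Conventions fixed here and documented because they vary between packages:

* "median [IQR]" quartiles use linear interpolation (type 7).
* The Fisher two-sided p-value uses the probability-ordering convention
  (sum of hypergeometric probabilities <= that of the observed table).
* Logistic odds-ratio intervals are Wald: exp(coef +/- 1.96 se).
* The Wilcoxon rank-sum p-value is exact by enumeration for small untied
  samples (n_x + n_y <= 12), otherwise a tie- and continuity-corrected
  normal approximation.
* No multiple-testing correction is applied anywhere; p-values are raw.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from .errors import (
    CollinearityError,
    DegenerateLabelError,
    DegenerateOutcomeError,
    PairingError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: Expected cohort-table columns (delimited-text schema).
COHORT_SCHEMA = ("subject_id", "age", "nihss", "tpa", "evt",
                 "avg_nwu", "weighted_nwu", "aspects", "outcome")


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table, checking the documented schema is present."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_SCHEMA if c not in df.columns]
    if missing:
        raise ParameterError(f"cohort table lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    coefficients: pd.Series
    standard_errors: pd.Series
    odds_ratios: pd.Series
    ci95: pd.DataFrame             # columns "low", "high"
    converged: bool
    n_used: int
    log_likelihood: float
    deviance_path: list = field(default_factory=list)
    predictor_cols: tuple = ()

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted outcome probabilities for new rows."""
        X = np.column_stack([np.ones(len(table))]
                            + [table[c].to_numpy(float) for c in self.predictor_cols])
        return expit(X @ self.coefficients.to_numpy())


def _check_design(X: np.ndarray, names: list) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        for j in range(1, X.shape[1]):  # skip intercept
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise CollinearityError(
            f"design matrix is rank deficient; offending columns: {bad or names[1:]}")


def fit_logistic(table: pd.DataFrame, outcome_col: str, predictor_cols,
                 max_iter: int = 100, tol: float = 1e-10,
                 ridge: float = 0.0) -> LogisticFit:
    """Fit P(outcome=1) = logit^-1(b0 + X b) by iteratively reweighted least
    squares with step halving (deviance never increases between iterations).

    Rows with missing values in the modeled columns are dropped (count
    logged).  Separation or non-convergence within ``max_iter`` is reported
    via ``converged=False``; an optional small ``ridge`` penalty stabilizes
    separated fits on request.
    """
    predictor_cols = list(predictor_cols)
    cols = [outcome_col] + predictor_cols
    sub = table[cols]
    complete = sub.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("fit_logistic: dropped %d row(s) with missing values", dropped)
    sub = sub[complete]
    n = len(sub)
    if n < 10:
        raise ParameterError(f"need >= 10 complete rows, got {n}")
    y = sub[outcome_col].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ParameterError(f"{outcome_col} must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError(f"{outcome_col} is constant; cannot fit")
    for c in predictor_cols:
        if sub[c].nunique() < 2:
            raise CollinearityError(f"predictor {c!r} is constant")
    X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(float) for c in predictor_cols])
    names = ["intercept"] + predictor_cols
    _check_design(X, names)

    beta = np.zeros(X.shape[1])
    pen = ridge * np.eye(X.shape[1])
    pen[0, 0] = 0.0

    def deviance(b):
        eta = np.clip(X @ b, -30, 30)
        return -2.0 * float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    dev = deviance(beta)
    path = [dev]
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X + pen, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        dev_new = deviance(beta + step)
        halvings = 0
        while dev_new > dev + 1e-12 and halvings < 12:
            step *= 0.5
            dev_new = deviance(beta + step)
            halvings += 1
        beta = beta + step
        path.append(dev_new)
        if abs(dev - dev_new) < tol * (abs(dev) + 0.1):
            converged = True
            dev = dev_new
            break
        dev = dev_new

    eta = np.clip(X @ beta, -30, 30)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X + pen)
    se = np.sqrt(np.diag(cov))
    # enormous standard errors indicate separation even if deviance plateaued
    if np.any(se > 1e3):
        converged = False
    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    or_s = np.exp(coef)
    ci = pd.DataFrame({"low": np.exp(coef - 1.96 * se_s),
                       "high": np.exp(coef + 1.96 * se_s)})
    return LogisticFit(coefficients=coef, standard_errors=se_s, odds_ratios=or_s,
                       ci95=ci, converged=converged, n_used=n,
                       log_likelihood=-dev / 2.0, deviance_path=path,
                       predictor_cols=tuple(predictor_cols))


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

def stratified_split(table: pd.DataFrame, outcome_col: str = "outcome",
                     test_fraction: float = 0.2, seed: int = 0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test partition preserving outcome-class representation.

    Each class contributes round(class_n * test_fraction) test rows (half-up;
    an exact .5 rounds up for the larger class and down for the smaller, so
    the overall test fraction stays close to the target).  Disjoint,
    exhaustive, and reproducible from ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ParameterError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = table[outcome_col].unique()
    sizes = {c: int((table[outcome_col] == c).sum()) for c in classes}
    largest = max(sorted(classes, key=str), key=lambda c: sizes[c])
    test_idx = []
    for c in sorted(classes, key=str):
        idx = table.index[table[outcome_col] == c].to_numpy()
        x = sizes[c] * test_fraction
        frac = x - math.floor(x)
        if abs(frac - 0.5) < 1e-9:
            n_test = math.floor(x) + (1 if c == largest else 0)
        else:
            n_test = int(math.floor(x + 0.5))
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[perm[:n_test]])
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask], table.loc[test_mask]


# ---------------------------------------------------------------------------
# AUROC and DeLong
# ---------------------------------------------------------------------------

def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise PairingError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelError("labels must contain both classes")
    return pos, neg


def auroc(scores, labels) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + 0.5 P(equal).

    Computed via the rank-sum (Mann-Whitney) identity; ties counted half.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


class DelongResult(NamedTuple):
    z: float
    p_two_sided: float
    var_a: float
    var_b: float
    cov_ab: float


def _placements(pos, neg):
    """DeLong structural components: per-positive and per-negative placement
    values, plus the AUROC (their common mean)."""
    cmp = ((pos[:, None] > neg[None, :]).astype(float)
           + 0.5 * (pos[:, None] == neg[None, :]))
    return cmp.mean(axis=1), cmp.mean(axis=0), float(cmp.mean())


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong's paired comparison of two correlated AUROCs.

    Both score vectors must be over the same subjects.  Variances and the
    covariance come from the empirical covariance of placement values; the
    statistic is z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov_ab) against
    the standard normal, two-sided.  Identical AUROCs with zero difference
    variance return z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise PairingError("paired score vectors have different lengths")
    pos_a, neg_a = _split_scores(scores_a, labels)
    pos_b, neg_b = _split_scores(scores_b, labels)
    m, n = len(pos_a), len(neg_a)
    v10_a, v01_a, auc_a = _placements(pos_a, neg_a)
    v10_b, v01_b, auc_b = _placements(pos_b, neg_b)

    def cov(x, y):
        if len(x) < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    s10 = np.array([[cov(v10_a, v10_a), cov(v10_a, v10_b)],
                    [cov(v10_b, v10_a), cov(v10_b, v10_b)]])
    s01 = np.array([[cov(v01_a, v01_a), cov(v01_a, v01_b)],
                    [cov(v01_b, v01_a), cov(v01_b, v01_b)]])
    S = s10 / m + s01 / n
    var_a, var_b, cov_ab = S[0, 0], S[1, 1], S[0, 1]
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff <= 1e-15:
        if abs(auc_a - auc_b) < 1e-12:
            return DelongResult(0.0, 1.0, var_a, var_b, cov_ab)
        z = math.copysign(math.inf, auc_a - auc_b)
        return DelongResult(z, 0.0, var_a, var_b, cov_ab)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * float(norm.sf(abs(z)))
    return DelongResult(float(z), min(p, 1.0), var_a, var_b, cov_ab)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUROC estimate."""
    pos, neg = _split_scores(scores, labels)
    v10, v01, _ = _placements(pos, neg)
    var10 = float(np.var(v10, ddof=1)) if len(v10) > 1 else 0.0
    var01 = float(np.var(v01, ddof=1)) if len(v01) > 1 else 0.0
    return var10 / len(pos) + var01 / len(neg)


# ---------------------------------------------------------------------------
# Fisher exact and Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table.

    Returns the sample odds ratio ad/bc (Haldane 0.5-correction applied to
    all cells when any is zero) and the two-sided p-value by the
    probability-ordering convention: sum the hypergeometric probabilities of
    every table, with the observed margins, that is no more probable than
    the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.rint(t)):
            raise ParameterError("need a 2x2 table of non-negative integer counts")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) == 0:
        oratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = (a * d) / (b * c)
    N, r1, c1 = a + b + c + d, a + b, a + c
    if N == 0:
        raise ParameterError("empty table")
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    denom = math.comb(N, r1)
    probs = np.array([math.comb(c1, k) * math.comb(N - c1, r1 - k) / denom
                      for k in range(lo, hi + 1)])
    p_obs = probs[a - lo]
    p = float(probs[probs <= p_obs * (1.0 + 1e-9)].sum())
    p = min(p, 1.0)
    if p > 1.0 - 1e-12:  # full support summed; absorb rounding
        p = 1.0
    return float(oratio), p


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U, p) where U counts pairs with x above y (ties half).  Exact
    enumeration over rank assignments when n_x + n_y <= 12 with no ties;
    otherwise normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ParameterError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mu = nx * ny / 2.0
    has_ties = len(np.unique(combined)) < nx + ny

    if nx + ny <= 12 and not has_ties:
        order = np.sort(ranks)
        dist = [sum(comb) for comb in itertools.combinations(order, nx)]
        dist = np.asarray(dist) - nx * (nx + 1) / 2.0
        p = float(np.mean(np.abs(dist - mu) >= abs(u - mu) - 1e-12))
        return u, min(p, 1.0)

    N = nx + ny
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (N * (N - 1))) if N > 1 else 0.0
    var = nx * ny / 12.0 * (N + 1 - tie_term)
    if var <= 0 or u == mu:
        return u, 1.0
    z = (u - mu - 0.5 * math.copysign(1.0, u - mu)) / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return u, min(p, 1.0)


# ---------------------------------------------------------------------------
# Model comparison workflow
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Two logistic models evaluated on one held-out stratified test set."""

    auroc_a: float
    auroc_b: float
    delong_z: float
    delong_p: float
    n_test: int
    split_seed: int
    predictors_a: tuple = ()
    predictors_b: tuple = ()
    fit_a: LogisticFit | None = None
    fit_b: LogisticFit | None = None

    def to_dict(self) -> dict:
        return {
            "auroc_a": self.auroc_a, "auroc_b": self.auroc_b,
            "delong_z": self.delong_z, "delong_p": self.delong_p,
            "n_test": self.n_test, "split_seed": self.split_seed,
            "predictors_a": list(self.predictors_a),
            "predictors_b": list(self.predictors_b),
        }


def compare_models(table: pd.DataFrame, predictors_a, predictors_b,
                   outcome_col: str = "outcome", test_fraction: float = 0.2,
                   seed: int = 0) -> ModelComparison:
    """Stratified split, fit two covariate-adjusted logistic models on the
    training rows, score the shared test rows, and compare the paired
    test-set AUROCs with the DeLong test."""
    train, test = stratified_split(table, outcome_col, test_fraction, seed)
    fit_a = fit_logistic(train, outcome_col, predictors_a)
    fit_b = fit_logistic(train, outcome_col, predictors_b)
    scores_a = fit_a.predict(test)
    scores_b = fit_b.predict(test)
    labels = test[outcome_col].to_numpy()
    res = delong_test(scores_a, scores_b, labels)
    return ModelComparison(
        auroc_a=auroc(scores_a, labels), auroc_b=auroc(scores_b, labels),
        delong_z=res.z, delong_p=res.p_two_sided, n_test=len(test),
        split_seed=seed, predictors_a=tuple(predictors_a),
        predictors_b=tuple(predictors_b), fit_a=fit_a, fit_b=fit_b)


# ---------------------------------------------------------------------------
# Cohort description
# ---------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles with linear (type-7) interpolation."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ParameterError("no finite values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def format_percent(count: int, group_n: int) -> str:
    """"139 (88.5%)"-style cell: percentage to one decimal."""
    if group_n <= 0:
        raise ParameterError("group size must be positive")
    return f"{count} ({100.0 * count / group_n:.1f}%)"


def describe_cohort(table: pd.DataFrame, group_col: str,
                    value_cols=None) -> pd.DataFrame:
    """Baseline-characteristics summary with between-group tests.

    Binary columns (values within {0,1}) are shown as ``n (xx.x%)`` and
    compared with Fisher's exact test; continuous columns as
    ``median [q1, q3]`` compared with the Wilcoxon rank-sum test.  The group
    column must have exactly two levels; an empty group raises.
    """
    levels = sorted(table[group_col].dropna().unique(), key=str)
    if len(levels) != 2:
        raise ParameterError(f"{group_col} must have exactly 2 levels, "
                             f"found {levels}")
    groups = {lev: table[table[group_col] == lev] for lev in levels}
    for lev, g in groups.items():
        if len(g) == 0:
            raise ParameterError(f"group {group_col}={lev!r} is empty")
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c not in (group_col, "subject_id")]

    rows = []
    for col in value_cols:
        vals = table[col].dropna()
        is_binary = vals.isin([0, 1]).all()
        cells = {}
        if is_binary:
            for lev, g in groups.items():
                cnt = int((g[col] == 1).sum())
                cells[str(lev)] = format_percent(cnt, len(g))
            counts = [[int((groups[lev][col] == 1).sum()),
                       int((groups[lev][col] == 0).sum())] for lev in levels]
            _, p = fisher_exact_2x2(counts)
            overall = format_percent(int((table[col] == 1).sum()), len(table))
        else:
            for lev, g in groups.items():
                med, q1, q3 = median_iqr(g[col])
                cells[str(lev)] = f"{med:g} [{q1:g}, {q3:g}]"
            _, p = wilcoxon_rank_sum(groups[levels[0]][col].dropna(),
                                     groups[levels[1]][col].dropna())
            med, q1, q3 = median_iqr(table[col])
            overall = f"{med:g} [{q1:g}, {q3:g}]"
        rows.append({"variable": col, "overall": overall, **cells,
                     "p_value": p})
    return pd.DataFrame(rows).set_index("variable")
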