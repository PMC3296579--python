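"""Classical burden collapsing and the logistic-regression test framework.

A region's rare variants are aggregated into a single per-sample score —
by indicator (any rare allele present), by sum (total rare-allele count),
or by a weighted sum using control-frequency weights — and that score is
tested against case/control status with a one-degree-of-freedom logistic
score test or likelihood-ratio test.  The combined multivariate collapsing
(CMC) test keeps the common variants as separate covariates next to the
collapsed rare score.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datatypes import CollapsedScore, GenotypeMatrix, PhenotypeVector, TestResult

_ZERO_VAR = 1e-12


def _rare_columns(G: GenotypeMatrix) -> np.ndarray:
    X = G.rare()
    if X.shape[1] == 0:
        raise ValueError("region has no rare variants to collapse")
    return X


def collapse_indicator(G: GenotypeMatrix) -> CollapsedScore:
    """Indicator collapsing: s_i = 1 if sample i carries any rare allele."""
    X = _rare_columns(G)
    members = tuple(np.flatnonzero(G.is_rare))
    s = (X.sum(axis=1) > 0).astype(float)
    return CollapsedScore(s=s, members=members, weights={k: 1.0 for k in members})


def collapse_sum(G: GenotypeMatrix) -> CollapsedScore:
    """Sum collapsing: s_i = total rare-allele count of sample i."""
    X = _rare_columns(G)
    members = tuple(np.flatnonzero(G.is_rare))
    return CollapsedScore(
        s=X.sum(axis=1), members=members, weights={k: 1.0 for k in members}
    )


def mb_weights(
    G: GenotypeMatrix, Y: PhenotypeVector, sqrt_form: bool = True
) -> np.ndarray:
    """Control-frequency weights for the weighted-sum burden score.

    The minor-allele frequency of variant k is estimated from controls with
    add-one smoothing, q_k = (sum over controls of X_ik + 1) / (2*N0 + 2),
    and the weight is 1/sqrt(q_k (1 - q_k)) (``sqrt_form=False`` drops the
    square root).  Low-frequency variants therefore get large weights, which
    lets rare alleles compete with common ones inside a single score.
    """
    if Y.n_control < 1:
        raise ValueError("weights need at least one control")
    controls = Y.y == 0
    n0 = Y.n_control
    q = (G.values[controls].astype(float).sum(axis=0) + 1.0) / (2.0 * n0 + 2.0)
    denom = q * (1.0 - q)
    return 1.0 / np.sqrt(denom) if sqrt_form else 1.0 / denom


def collapse_weighted(G: GenotypeMatrix, weights: np.ndarray) -> CollapsedScore:
    """Weighted-sum score over all K variants: s_i = sum_k w_k X_ik."""
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != G.n_variants:
        raise ValueError("one weight per variant required")
    s = G.values.astype(float) @ w
    members = tuple(range(G.n_variants))
    return CollapsedScore(s=s, members=members, weights=dict(enumerate(w)))


def score_statistic(s: np.ndarray, y: np.ndarray) -> float:
    """Rao score statistic Ts = U^2 / V for the 1-covariate logistic model.

    U = sum_i (y_i - ybar) s_i and V = ybar (1 - ybar) sum_i (s_i - sbar)^2.
    Returns 0.0 for a degenerate (constant) score.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    u = float((y - ybar) @ s)
    v = float(ybar * (1.0 - ybar) * ((s - s.mean()) ** 2).sum())
    if v <= _ZERO_VAR:
        return 0.0
    return u * u / v


def score_test(S: CollapsedScore | np.ndarray, Y: PhenotypeVector) -> TestResult:
    """One-df logistic score test of a collapsed score against the trait.

    Asymptotically chi-square with one degree of freedom.  A constant score
    yields statistic 0 and p = 1 so simulation loops never abort on
    degenerate regions.
    """
    s = S.s if isinstance(S, CollapsedScore) else np.asarray(S, dtype=float)
    Y.require_both_groups()
    ts = score_statistic(s, Y.y)
    if ts == 0.0:
        return TestResult(statistic=0.0, p_value=1.0, method="score", df=1)
    p = float(stats.chi2.sf(ts, df=1))
    return TestResult(statistic=ts, p_value=p, method="score", df=1)


def _drop_collinear(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent, non-constant column subset.

    Later columns are dropped in favour of earlier ones; rank is detected
    from the R factor of a pivoted-free sequential QR (greedy Gram-Schmidt
    against an intercept and the retained columns).
    """
    n, k = X.shape
    basis = [np.ones(n) / np.sqrt(n)]
    keep: list[int] = []
    for j in range(k):
        v = X[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        for b in basis:
            v -= (b @ v) * b
        if np.linalg.norm(v) > tol * max(norm0, 1.0):
            basis.append(v / np.linalg.norm(v))
            keep.append(j)
    return np.asarray(keep, dtype=int)


def _logit_lrt(X: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """LRT of a logistic model with design columns X against intercept-only.

    Returns (statistic, df, p).  Collinear/constant columns are dropped
    first; df is the number of retained columns.
    """
    keep = _drop_collinear(X)
    df = len(keep)
    if df == 0:
        return 0.0, 0, 1.0
    Xk = sm.add_constant(X[:, keep], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        try:
            full = sm.Logit(y, Xk).fit(disp=0, maxiter=200)
            llf_full = full.llf
        except Exception:
            # quasi-separation: refit with a ridge whisper for a finite llf
            full = sm.Logit(y, Xk).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
            llf_full = sm.Logit(y, Xk).loglike(np.asarray(full.params))
    stat = max(0.0, 2.0 * (llf_full - null.llf))
    p = float(stats.chi2.sf(stat, df=df)) if stat > 0 else 1.0
    return float(stat), df, p


def logistic_lrt(S: CollapsedScore | np.ndarray, Y: PhenotypeVector) -> TestResult:
    """Likelihood-ratio test of Logit P(Y=1) = b0 + b1 * S against b1 = 0."""
    s = S.s if isinstance(S, CollapsedScore) else np.asarray(S, dtype=float)
    Y.require_both_groups()
    if np.ptp(s) <= _ZERO_VAR:
        return TestResult(statistic=0.0, p_value=1.0, method="lrt", df=1)
    stat, df, p = _logit_lrt(s[:, None], Y.y)
    return TestResult(statistic=stat, p_value=p, method="lrt", df=max(df, 1))


def cmc_test(
    G_common: np.ndarray,
    S_rare: Optional[CollapsedScore],
    Y: PhenotypeVector,
    method: str = "cmc",
) -> TestResult:
    """Combined multivariate collapsing: common SNPs plus a collapsed rare score.

    Multivariate logistic LRT of H0: all slopes zero, with df = J + 1 (J
    common SNPs retained after collinearity pruning, plus the rare score).
    With ``S_rare=None`` this is the plain multivariate common-SNP test.
    """
    Y.require_both_groups()
    cols = [np.asarray(G_common, dtype=float)] if G_common.size else []
    if S_rare is not None:
        cols.append(S_rare.s[:, None])
    if not cols:
        return TestResult(statistic=0.0, p_value=1.0, method=method, df=0)
    X = np.hstack(cols)
    stat, df, p = _logit_lrt(X, Y.y)
    return TestResult(statistic=stat, p_value=p, method=method, df=df)


def wsum_test(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    n_perm: int = 500,
    seed: int = 0,
    sqrt_form: bool = True,
) -> TestResult:
    """Weighted-sum burden test over all variants with permutation p-value.

    The control-frequency weights are data-driven, so they are recomputed
    on every shuffled phenotype.  The score statistic of a collapsed score
    equals N * Cor(S, Y)^2 for binary Y, which lets all permutations be
    evaluated with a few matrix products.
    """
    from .permutation import PermutationPlan, permuted_labels, pvalue_from_draws

    Y.require_both_groups()
    plan = PermutationPlan(n_perm=n_perm, seed=seed)
    X = G.values.astype(float)
    n = X.shape[0]
    y_mat = np.vstack([Y.y[None, :], permuted_labels(Y.y, n_perm, plan.rng())])
    n0 = Y.n_control
    # per-shuffle control-frequency weights, K x (B+1)
    q = (X.T @ (1.0 - y_mat.T) + 1.0) / (2.0 * n0 + 2.0)
    denom = q * (1.0 - q)
    w = 1.0 / np.sqrt(denom) if sqrt_form else 1.0 / denom
    s_mat = X @ w                                    # N x (B+1)
    ybar = Y.y.mean()
    var_y = ybar * (1.0 - ybar)
    cov = np.einsum("nb,bn->b", s_mat, y_mat) / n - s_mat.mean(axis=0) * ybar
    var_s = s_mat.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(var_s > _ZERO_VAR, n * cov * cov / (var_s * var_y), 0.0)
    if ts[0] == 0.0:
        return TestResult(0.0, 1.0, "wSum", n_perm=n_perm)
    p = pvalue_from_draws(ts[0], ts[1:], add_one=plan.add_one)
    return TestResult(float(ts[0]), p, "wSum", n_perm=n_perm)


def bonferroni_single_marker(G_common: np.ndarray, Y: PhenotypeVector) -> TestResult:
    """Best single common-SNP score test with Bonferroni correction.

    p = min(1, J * min_k p_k) over the J common SNPs.
    """
    Y.require_both_groups()
    X = np.asarray(G_common, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("no common SNPs supplied")
    j = X.shape[1]
    stats_ = np.array([score_statistic(X[:, k], Y.y) for k in range(j)])
    best = int(np.argmax(stats_))
    p_min = float(stats.chi2.sf(stats_[best], df=1)) if stats_[best] > 0 else 1.0
    return TestResult(
        statistic=float(stats_[best]),
        p_value=min(1.0, j * p_min),
        method="bonferroni",
        df=1,
    )
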