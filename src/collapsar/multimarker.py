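"""Multi-marker comparator tests: SSU, SSUw, adaptive sums, ORWSS, kernel test.

These keep the K per-variant score components separate instead of
collapsing them.  With U_k = sum_i X_ik (y_i - ybar) and the null Fisher
information V = Cov(U) = ybar(1-ybar) * sum_i (X_i - Xbar)(X_i - Xbar)',
the statistics are SSU = U'U, SSUw = U' Diag(V)^-1 U (both with scaled
chi-square nulls), the adaptive minimum-p over growing variant prefixes
(aSSU/aSSUw, optionally after ordering variants by single-marker
statistic), the odds-ratio weighted rank-sum ORWSS, and the logistic
kernel-machine statistic Q, which for the linear kernel equals SSU / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .datatypes import GenotypeMatrix, PhenotypeVector, TestResult
from .permutation import PermutationPlan, permuted_labels, pvalue_from_draws

_ZV = 1e-12


def score_components(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score vector U and its null covariance (expected information) V."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    u = X.T @ (y - ybar)
    Xc = X - X.mean(axis=0)
    v = ybar * (1.0 - ybar) * (Xc.T @ Xc)
    return u, v


def _mixture_pvalue(
    lams: np.ndarray, q: float, method: str = "satterthwaite"
) -> float:
    """P(sum lam_j chi2_1 >= q) for a nonnegative eigenvalue mixture.

    Default is two-moment (Satterthwaite) matching to a scaled chi-square
    a * chi2_d with a = sum(lam^2)/sum(lam), d = (sum lam)^2 / sum(lam^2).
    ``method="imhof"`` evaluates Imhof's inversion integral numerically.
    """
    lams = np.asarray(lams, dtype=float)
    lams = lams[lams > _ZV * max(1.0, lams.max(initial=0.0))]
    if lams.size == 0 or q <= 0.0:
        return 1.0
    if method == "imhof":
        def integrand(u: float) -> float:
            theta = 0.5 * np.sum(np.arctan(lams * u)) - 0.5 * q * u
            rho = np.prod((1.0 + (lams * u) ** 2) ** 0.25)
            return np.sin(theta) / (u * rho)

        import warnings
        from scipy.integrate import IntegrationWarning

        with warnings.catch_warnings():
            # the integrand oscillates; quad's subdivision cap is expected
            warnings.simplefilter("ignore", IntegrationWarning)
            val, _ = quad(integrand, 0.0, np.inf, limit=400)
        return float(min(1.0, max(0.0, 0.5 + val / np.pi)))
    s1, s2 = lams.sum(), (lams**2).sum()
    a = s2 / s1
    d = s1 * s1 / s2
    return float(stats.chi2.sf(q / a, df=d))


def ssu(G: GenotypeMatrix | np.ndarray, Y: PhenotypeVector,
        pvalue_method: str = "satterthwaite") -> TestResult:
    """Sum of squared score components, U'U, with scaled chi-square null."""
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    u, v = score_components(X, Y.y)
    stat = float(u @ u)
    if stat <= 0.0 or np.trace(v) <= _ZV:
        return TestResult(0.0, 1.0, "SSU")
    lams = np.linalg.eigvalsh(v)
    p = _mixture_pvalue(lams, stat, pvalue_method)
    return TestResult(stat, p, "SSU")


def ssuw(G: GenotypeMatrix | np.ndarray, Y: PhenotypeVector,
         pvalue_method: str = "satterthwaite") -> TestResult:
    """Inverse-information-weighted SSU: U' Diag(V)^-1 U.

    Monomorphic variants (zero information) contribute nothing and are
    dropped before the eigenvalue mixture is formed.
    """
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    u, v = score_components(X, Y.y)
    d = np.diag(v)
    keep = d > _ZV
    if not keep.any():
        return TestResult(0.0, 1.0, "SSUw")
    u, v, d = u[keep], v[np.ix_(keep, keep)], d[keep]
    stat = float(np.sum(u * u / d))
    dinv = 1.0 / np.sqrt(d)
    lams = np.linalg.eigvalsh(dinv[:, None] * v * dinv[None, :])
    p = _mixture_pvalue(lams, stat, pvalue_method)
    return TestResult(stat, p, "SSUw")


def kernel_test(G: GenotypeMatrix | np.ndarray, Y: PhenotypeVector,
                kernel: str = "linear",
                pvalue_method: str = "satterthwaite") -> TestResult:
    """Logistic kernel-machine score statistic Q = (y-ybar)' K (y-ybar) / 2.

    Only the linear kernel K = G G' is supported, for which Q = SSU / 2
    exactly; the scaled chi-square null uses the eigenvalues of V / 2.
    """
    if kernel != "linear":
        raise NotImplementedError("only the linear kernel is implemented")
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    u, v = score_components(X, Y.y)
    stat = float(u @ u) / 2.0
    if stat <= 0.0 or np.trace(v) <= _ZV:
        return TestResult(0.0, 1.0, "KML")
    lams = np.linalg.eigvalsh(v) / 2.0
    p = _mixture_pvalue(lams, stat, pvalue_method)
    return TestResult(stat, p, "KML")


def _single_marker_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Variant order by descending single-marker statistic U_k^2 / V_kk."""
    u, v = score_components(X, y)
    d = np.diag(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(d > _ZV, u * u / np.where(d > _ZV, d, 1.0), 0.0)
    return np.argsort(-t, kind="stable")


def _adaptive_min_p(
    X: np.ndarray, y: np.ndarray, base: str, ordered: bool
) -> float:
    """aT = min over prefixes m of the base-test p-value on U_1..U_m."""
    order = _single_marker_order(X, y) if ordered else np.arange(X.shape[1])
    Xo = X[:, order]
    y_ph = PhenotypeVector(y)
    fn = ssu if base == "ssu" else ssuw
    best = 1.0
    for m in range(1, Xo.shape[1] + 1):
        p = fn(Xo[:, :m], y_ph).p_value
        if p < best:
            best = p
    return best


def adaptive_sum(
    G: GenotypeMatrix | np.ndarray,
    Y: PhenotypeVector,
    base_stat: str = "ssu",
    ordered: bool = False,
    n_perm: int = 500,
    seed: int = 0,
) -> TestResult:
    """Adaptive sum test: minimum base-test p over growing variant prefixes.

    The minimum p-value aT is not a p-value itself (it is selected), so the
    overall p comes from permutation: aT is recomputed — ordering and all
    prefixes included — on each shuffled phenotype, and compared in the
    "smaller is more extreme" direction.
    """
    if base_stat not in ("ssu", "ssuw"):
        raise ValueError("base_stat must be 'ssu' or 'ssuw'")
    X = G.values.astype(float) if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    Y.require_both_groups()
    at_obs = _adaptive_min_p(X, Y.y, base_stat, ordered)
    rng = np.random.default_rng(seed)
    perms = permuted_labels(Y.y, n_perm, rng)
    draws = np.array(
        [_adaptive_min_p(X, perms[b], base_stat, ordered) for b in range(n_perm)]
    )
    # smaller aT is more extreme: count permuted aT <= observed
    p = (1.0 + int((draws <= at_obs).sum())) / (n_perm + 1.0)
    name = f"a{base_stat.upper()}" + ("-Ord" if ordered else "")
    return TestResult(at_obs, p, name, n_perm=n_perm)


@dataclass
class OrwssConfig:
    """ORWSS weighting options: raw log-odds weights, or thresholded."""

    c: float = 1.0
    use_threshold: bool = False


def orwss_weights(
    X: np.ndarray, y: np.ndarray, cfg: OrwssConfig | None = None
) -> np.ndarray:
    """Per-variant log-odds-ratio weights from +0.5-amended allele tables.

    For variant k the 2x2 table counts minor/major alleles in cases and
    controls (2 alleles per sample); 0.5 is added to each cell before the
    odds ratio.  With ``use_threshold`` weights further than c standard
    deviations from the mean log-OR are kept and the rest zeroed.
    """
    cfg = cfg or OrwssConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = y.sum()
    n0 = len(y) - n1
    a = X[y == 1].sum(axis=0)          # case minor alleles
    b = X[y == 0].sum(axis=0)          # control minor alleles
    gamma = np.log(
        ((a + 0.5) * (2 * n0 - b + 0.5)) / ((b + 0.5) * (2 * n1 - a + 0.5))
    )
    if cfg.use_threshold:
        sd = gamma.std()
        keep = np.abs(gamma - gamma.mean()) > cfg.c * sd
        gamma = np.where(keep, gamma, 0.0)
    return gamma


def orwss_statistic(
    X: np.ndarray, y: np.ndarray, cfg: OrwssConfig | None = None
) -> float:
    """Rank-sum of weighted scores over cases (mid-ranks for ties)."""
    w = orwss_weights(X, y, cfg)
    s = np.asarray(X, dtype=float) @ w
    ranks = stats.rankdata(s, method="average")
    return float(ranks[np.asarray(y) == 1].sum())


def orwss(
    G: GenotypeMatrix | np.ndarray,
    Y: PhenotypeVector,
    cfg: OrwssConfig | None = None,
    n_perm: int = 500,
    seed: int = 0,
) -> TestResult:
    """Odds-ratio weighted sum test with permutation p-value.

    Because the weights adapt to the labels (case-enriched variants get
    positive log-OR weights), the observed rank-sum is stochastically large
    under association, and weights are recomputed on every permutation.
    """
    X = G.values.astype(float) if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    Y.require_both_groups()
    plan = PermutationPlan(n_perm=n_perm, seed=seed)
    t_obs = orwss_statistic(X, Y.y, cfg)
    perms = permuted_labels(Y.y, n_perm, plan.rng())
    draws = np.array([orwss_statistic(X, perms[b], cfg) for b in range(n_perm)])
    p = pvalue_from_draws(t_obs, draws)
    return TestResult(t_obs, p, "ORWSS", n_perm=n_perm)
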