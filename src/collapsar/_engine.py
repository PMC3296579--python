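"""Fast covariance-update kernel for the selective-collapsing permutation test.

The forward selection only ever needs correlations of candidate scores with
the phenotype, and a score is a weighted sum of genotype columns, so the
whole procedure can run on the K x K column covariance matrix instead of
length-N vectors: adding column k to a component updates its variance,
its covariance with Y and its covariance with every other column in O(K).
Per shuffled phenotype only two K-vectors change (column-phenotype
covariances and carrier case-fractions), and those are produced for all
shuffles at once by two matrix products.  The per-shuffle selection loop is
compiled with numba; the plain-vector implementation in :mod:`collapsar.wsc`
is the readable reference it is tested against.

Statistic identity used throughout: for binary Y the score test of a
collapsed score S satisfies Ts = U^2/V = N * Cor(S, Y)^2, because
Var(Y) = Ybar (1 - Ybar) exactly.  Maximising Cor^2 therefore maximises Ts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TOL = 1e-10      # strict-improvement tolerance (matches wsc.IMPROVE_TOL)
_ZV = 1e-15       # zero-variance guard
_TIE = 1e-12      # gains closer than this are ties; lowest index wins


@njit(cache=True)
def _pick(pool, avail, wv, Sigma, covYx, varY, var_s, covy_s, covw_s, cor_s, sign):
    """Best greedy addition for one component; returns (k, cor) or (-1, 0)."""
    best_k = -1
    best_cor = 0.0
    best_gain = -1.0e300
    for t in range(pool.shape[0]):
        k = pool[t]
        if not avail[k]:
            continue
        var_n = var_s + 2.0 * covw_s[k] + wv[k] * wv[k] * Sigma[k, k]
        if var_n <= _ZV:
            continue
        cov_n = covy_s + wv[k] * covYx[k]
        cor = cov_n / np.sqrt(var_n * varY)
        gain = sign * cor
        if gain > best_gain + _TIE:
            best_gain = gain
            best_k = k
            best_cor = cor
    if best_k < 0:
        return -1, 0.0
    floor = sign * cor_s
    if floor < 0.0:
        floor = 0.0
    if best_gain <= floor + _TOL:
        return -1, 0.0
    return best_k, best_cor


@njit(cache=True)
def _grow_pair(pool, avail, wv, Sigma, covYx, varY, state, covwP, covwM, members, tol):
    """Round-robin growth of S+ (first) and S- over a shared pool.

    ``state`` = [varP, covyP, corP, varM, covyM, corM], updated in place.
    ``members`` rows 0/1 hold member indices of S+/S-; returns (nP, nM)
    as counts appended this call on top of the counts in members[:, -1].
    """
    K = Sigma.shape[0]
    active_p = True
    active_m = True
    while active_p or active_m:
        if active_p:
            k, cor = _pick(pool, avail, wv, Sigma, covYx, varY,
                           state[0], state[1], covwP, state[2], 1.0)
            if k < 0:
                active_p = False
            else:
                state[0] = state[0] + 2.0 * covwP[k] + wv[k] * wv[k] * Sigma[k, k]
                state[1] = state[1] + wv[k] * covYx[k]
                state[2] = cor
                for j in range(K):
                    covwP[j] += wv[k] * wv[j] * Sigma[k, j]
                avail[k] = False
                members[0, int(members[0, K]) ] = k
                members[0, K] += 1
        if active_m:
            k, cor = _pick(pool, avail, wv, Sigma, covYx, varY,
                           state[3], state[4], covwM, state[5], -1.0)
            if k < 0:
                active_m = False
            else:
                state[3] = state[3] + 2.0 * covwM[k] + wv[k] * wv[k] * Sigma[k, k]
                state[4] = state[4] + wv[k] * covYx[k]
                state[5] = cor
                for j in range(K):
                    covwM[j] += wv[k] * wv[j] * Sigma[k, j]
                avail[k] = False
                members[1, int(members[1, K]) ] = k
                members[1, K] += 1


@njit(cache=True)
def _stat_pair(Sigma, covYx, varY, wv, common_idx, rare_idx, n_samples):
    """(wSC, wSCd) statistics for one phenotype vector's covariances."""
    K = Sigma.shape[0]
    avail = np.zeros(K, np.bool_)
    state = np.zeros(6)
    covwP = np.zeros(K)
    covwM = np.zeros(K)
    members = np.zeros((2, K + 1), np.int64)   # last column = count

    # Step 1: common SNPs (weight 1), then Step 2: rare on the same bases
    for t in range(common_idx.shape[0]):
        avail[common_idx[t]] = True
    _grow_pair(common_idx, avail, wv, Sigma, covYx, varY,
               state, covwP, covwM, members, _TOL)
    for t in range(rare_idx.shape[0]):
        avail[rare_idx[t]] = True
    _grow_pair(rare_idx, avail, wv, Sigma, covYx, varY,
               state, covwP, covwM, members, _TOL)
    corPB = state[2]
    corMB = state[5]
    # Cov(S+, S-) = sum over S- members of Cov(S+, w_j x_j)
    crossB = 0.0
    for t in range(int(members[1, K])):
        crossB += covwP[members[1, t]]
    varPB, covyPB = state[0], state[1]
    varMB, covyMB = state[3], state[4]

    # Step 3: rare-only pass from scratch
    avail[:] = False
    for t in range(rare_idx.shape[0]):
        avail[rare_idx[t]] = True
    state2 = np.zeros(6)
    covwP2 = np.zeros(K)
    covwM2 = np.zeros(K)
    members2 = np.zeros((2, K + 1), np.int64)
    _grow_pair(rare_idx, avail, wv, Sigma, covYx, varY,
               state2, covwP2, covwM2, members2, _TOL)
    corPR = state2[2]
    corMR = state2[5]
    crossR = 0.0
    for t in range(int(members2[1, K])):
        crossR += covwP2[members2[1, t]]
    varPR, covyPR = state2[0], state2[1]
    varMR, covyMR = state2[3], state2[4]

    # wSC: best squared correlation among the four components
    best = corPB * corPB
    if corMB * corMB > best:
        best = corMB * corMB
    if corPR * corPR > best:
        best = corPR * corPR
    if corMR * corMR > best:
        best = corMR * corMR
    t_wsc = n_samples * best

    # wSCd: best squared correlation among the two difference scores
    best_d = 0.0
    var_d = varPB + varMB - 2.0 * crossB
    if var_d > _ZV:
        cov_d = covyPB - covyMB
        c2 = cov_d * cov_d / (var_d * varY)
        if c2 > best_d:
            best_d = c2
    var_d = varPR + varMR - 2.0 * crossR
    if var_d > _ZV:
        cov_d = covyPR - covyMR
        c2 = cov_d * cov_d / (var_d * varY)
        if c2 > best_d:
            best_d = c2
    t_wscd = n_samples * best_d
    return t_wsc, t_wscd


@njit(cache=True)
def _batch_loop(Sigma, covYx_all, casefrac_all, has_carriers, varY,
                common_idx, rare_idx, n_samples):
    n_y = covYx_all.shape[1]
    K = Sigma.shape[0]
    Kr = rare_idx.shape[0]
    t_wsc = np.empty(n_y)
    t_wscd = np.empty(n_y)
    wv = np.empty(K)
    for b in range(n_y):
        # adaptive weights for this phenotype: w_k = p_k / (mean p), else 1
        for j in range(K):
            wv[j] = 1.0
        sump = 0.0
        for t in range(Kr):
            k = rare_idx[t]
            p = abs(casefrac_all[k, b] - 0.5) if has_carriers[k] else 0.0
            wv[k] = p
            sump += p
        if sump > 0.0:
            scale = Kr / sump
            for t in range(Kr):
                wv[rare_idx[t]] *= scale
        else:
            for t in range(Kr):
                wv[rare_idx[t]] = 1.0
        t1, t2 = _stat_pair(Sigma, covYx_all[:, b].copy(), varY, wv,
                            common_idx, rare_idx, n_samples)
        t_wsc[b] = t1
        t_wscd[b] = t2
    return t_wsc, t_wscd


def batch_statistics(G, y_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """wSC and wSCd statistics for many phenotype vectors over one region.

    ``y_mat`` is (n_y, N); row 0 is conventionally the observed phenotype
    and the remaining rows its permutations (all rows must share the same
    case count).  Returns two length-n_y arrays of score-test statistics.
    """
    X = G.values.astype(np.float64)
    n, k = X.shape
    y_mat = np.ascontiguousarray(y_mat, dtype=np.float64)
    mu = X.mean(axis=0)
    Sigma = (X.T @ X) / n - np.outer(mu, mu)
    ybar = float(y_mat[0].mean())
    var_y = ybar * (1.0 - ybar)
    if var_y <= _ZV:
        raise ValueError("phenotype is constant")
    covYx_all = (X.T @ y_mat.T) / n - mu[:, None] * ybar
    carriers = (X > 0).astype(np.float64).T          # K x N
    m_car = carriers.sum(axis=1)
    casefrac_all = (carriers @ y_mat.T) / np.maximum(m_car, 1.0)[:, None]
    common_idx = np.flatnonzero(~G.is_rare).astype(np.int64)
    rare_idx = np.flatnonzero(G.is_rare).astype(np.int64)
    return _batch_loop(
        Sigma, covYx_all, casefrac_all, m_car > 0, var_y,
        common_idx, rare_idx, float(n),
    )
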