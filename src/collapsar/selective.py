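"""Selective collapsing of rare variants by forward selection on R^2.

A covering-style procedure: starting from an empty score, the rare variant
whose addition most increases the squared correlation between the
collapsed score and the trait is added, until no addition improves it.
The screening statistic is direction-blind (R^2), unlike the signed
two-component selection of :mod:`collapsar.wsc`.  Both sum collapsing
(RsumSC) and indicator collapsing (RindSC) are supported; p-values come
from permutation with the selection re-run per shuffle.
"""

from __future__ import annotations

import numpy as np

from .collapsing import score_statistic
from .datatypes import CollapsedScore, GenotypeMatrix, PhenotypeVector, TestResult
from .permutation import PermutationPlan, permuted_labels, pvalue_from_draws

_TOL = 1e-10


def _cor2_columns(T: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared correlation of each column of T with y (0 for constants)."""
    yc = y - y.mean()
    vy = float(yc @ yc)
    Tc = T - T.mean(axis=0)
    vt = (Tc * Tc).sum(axis=0)
    cov = yc @ Tc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(vt > 1e-15, cov * cov / (vt * vy), 0.0)
    return r2


def selective_collapse(
    X_rare: np.ndarray, y: np.ndarray, mode: str = "sum"
) -> CollapsedScore:
    """Greedy R^2-maximising subset collapse of rare variants.

    ``mode="sum"`` collapses the selected subset by allele count,
    ``mode="indicator"`` by presence of any allele in the subset.  Ties go
    to the lowest variant index; a step must improve R^2 by more than 1e-10.
    """
    if mode not in ("sum", "indicator"):
        raise ValueError("mode must be 'sum' or 'indicator'")
    X = np.asarray(X_rare, dtype=float)
    n, k = X.shape
    y = np.asarray(y, dtype=float)
    counts = np.zeros(n)             # running allele count of the subset
    members: list[int] = []
    pool = np.arange(k)
    best_r2 = 0.0
    while pool.size:
        cand_counts = counts[:, None] + X[:, pool]
        cand = (cand_counts > 0).astype(float) if mode == "indicator" else cand_counts
        r2 = _cor2_columns(cand, y)
        j = int(np.argmax(r2))
        if r2[j] <= best_r2 + _TOL:
            break
        best_r2 = float(r2[j])
        counts = cand_counts[:, j]
        members.append(int(pool[j]))
        pool = np.delete(pool, j)
    s = (counts > 0).astype(float) if mode == "indicator" else counts
    return CollapsedScore(
        s=s, members=tuple(members), weights={m: 1.0 for m in members}
    )


def selective_statistic(X_rare: np.ndarray, y: np.ndarray, mode: str) -> float:
    """Score-test statistic of the greedily collapsed score."""
    return score_statistic(selective_collapse(X_rare, y, mode).s, y)


def _selective_test(
    G: GenotypeMatrix, Y: PhenotypeVector, mode: str, plan: PermutationPlan, name: str
) -> TestResult:
    Y.require_both_groups()
    X = G.rare()
    if X.shape[1] == 0:
        raise ValueError("region has no rare variants")
    t_obs = selective_statistic(X, Y.y, mode)
    perms = permuted_labels(Y.y, plan.n_perm, plan.rng())
    draws = np.array(
        [selective_statistic(X, perms[b], mode) for b in range(plan.n_perm)]
    )
    p = pvalue_from_draws(t_obs, draws, add_one=plan.add_one)
    return TestResult(t_obs, p, name, n_perm=plan.n_perm)


def rsum_sc_test(
    G: GenotypeMatrix, Y: PhenotypeVector, n_perm: int = 500, seed: int = 0
) -> TestResult:
    """Selective sum collapsing of rare variants (RsumSC), permutation p."""
    return _selective_test(G, Y, "sum", PermutationPlan(n_perm, seed), "RsumSC")


def rind_sc_test(
    G: GenotypeMatrix, Y: PhenotypeVector, n_perm: int = 500, seed: int = 0
) -> TestResult:
    """Selective indicator collapsing of rare variants (RindSC)."""
    return _selective_test(G, Y, "indicator", PermutationPlan(n_perm, seed), "RindSC")
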