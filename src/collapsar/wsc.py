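"""Weighted selective collapsing: the wSC and wSCd association tests.

The strategy builds two burden components for a region — a deleterious
component S+ grown to maximise its correlation with case status, and a
protective component S- grown to minimise it.  Common SNPs are forward
selected first by plain sum collapsing (Step 1); rare variants are then
forward selected on top of those bases with a data-driven weight that
favours variants whose carriers deviate from a 50/50 case/control split
(Step 2).  The rare-only selection is repeated without the common bases
(Step 3), giving four candidate scores {S+Both, S-Both, S+R, S-R}.  wSC
takes the candidate with the largest squared correlation with the trait;
wSCd instead compares the two difference scores S+ - S- so that mixed
deleterious/protective regions are captured in one statistic.  Because
every ingredient is selected on the data, p-values come from permutation
with the entire procedure (weights included) re-run on each shuffle.

This module is the plain-vector reference implementation; the permutation
loop delegates to the covariance-update kernel in :mod:`collapsar._engine`
(the two are checked against each other in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _engine
from .collapsing import score_statistic
from .datatypes import CollapsedScore, GenotypeMatrix, PhenotypeVector, TestResult
from .permutation import PermutationPlan, permuted_labels, pvalue_from_draws

#: a forward step is accepted only if it improves |Cor| by more than this
IMPROVE_TOL = 1e-10
#: gains within this of the best are ties; the lowest variant index wins
TIE_TOL = 1e-12
_ZERO_VAR = 1e-15


def _cor(s: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, defined as 0 when either vector is constant."""
    s = np.asarray(s, dtype=float)
    vs = s.var()
    vy = y.var()
    if vs <= _ZERO_VAR or vy <= _ZERO_VAR:
        return 0.0
    return float(((s - s.mean()) @ (y - y.mean())) / (len(y) * np.sqrt(vs * vy)))


def risk_deviation(x_k: np.ndarray, y: np.ndarray) -> float:
    """Deviation of the carrier case-fraction from 1/2 for one rare variant.

    p_k = | #{y_i=1, x_ik>0} / #{x_ik>0} - 0.5 |, i.e. how far the disease
    risk among mutation carriers sits from a coin flip, in either
    direction.  Defined as 0 when the variant has no carriers.
    """
    carriers = np.asarray(x_k) > 0
    m = int(carriers.sum())
    if m == 0:
        return 0.0
    return abs(float(np.asarray(y, dtype=float)[carriers].mean()) - 0.5)


@dataclass
class AdaptiveWeights:
    """Risk-deviation weights for the rare variants, normalised to mean one."""

    p: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.w = np.asarray(self.w, dtype=float)


def adaptive_weights(G_rare: np.ndarray, y: np.ndarray) -> AdaptiveWeights:
    """Per-rare-variant weights w_k = p_k / (mean of p), summing to K_rare.

    When every p_k is zero (no informative carriers anywhere) the
    normalisation is undefined and all weights fall back to 1.
    """
    X = np.asarray(G_rare, dtype=float)
    k = X.shape[1]
    p = np.array([risk_deviation(X[:, j], y) for j in range(k)])
    total = p.sum()
    w = p * (k / total) if total > 0 else np.ones(k)
    return AdaptiveWeights(p=p, w=w)


@dataclass
class ComponentPair:
    """The deleterious (S+) and protective (S-) components of a region."""

    s_plus: CollapsedScore
    s_minus: CollapsedScore
    cor_plus: float = 0.0
    cor_minus: float = 0.0

    @classmethod
    def empty(cls, n: int) -> "ComponentPair":
        z = np.zeros(n)
        return cls(
            s_plus=CollapsedScore(z.copy(), (), {}, "plus"),
            s_minus=CollapsedScore(z.copy(), (), {}, "minus"),
        )


class _Growing:
    """Mutable forward-selection state for one component."""

    def __init__(self, n: int, sign: float, score: Optional[CollapsedScore] = None,
                 cor: float = 0.0):
        self.sign = sign  # +1 grows toward positive Cor, -1 toward negative
        if score is None or score.is_empty:
            self.s = np.zeros(n)
            self.members: list[int] = []
            self.weights: dict[int, float] = {}
            self.cor = 0.0
        else:
            self.s = score.s.copy()
            self.members = list(score.members)
            self.weights = dict(score.weights)
            self.cor = cor

    def try_add(
        self,
        X: np.ndarray,
        y: np.ndarray,
        pool: list[int],
        col_of: dict[int, int],
        w: dict[int, float],
    ) -> bool:
        """Attempt one greedy addition; True if a variant was accepted."""
        best_k, best_cor = -1, 0.0
        best_gain = -np.inf
        for k in pool:
            cand = self.s + w[k] * X[:, col_of[k]]
            c = _cor(cand, y)
            if self.sign * c > best_gain + TIE_TOL:
                best_k, best_cor, best_gain = k, c, self.sign * c
        if best_k < 0:
            return False
        gain = self.sign * best_cor
        if gain <= max(self.sign * self.cor, 0.0) + IMPROVE_TOL:
            return False
        self.s = self.s + w[best_k] * X[:, col_of[best_k]]
        self.members.append(best_k)
        self.weights[best_k] = w[best_k]
        self.cor = best_cor
        pool.remove(best_k)
        return True

    def freeze(self, direction: str) -> CollapsedScore:
        return CollapsedScore(
            s=self.s, members=tuple(self.members),
            weights=dict(self.weights), direction=direction,
        )


def _grow_pair(
    X: np.ndarray,
    y: np.ndarray,
    indices: list[int],
    col_of: dict[int, int],
    w: dict[int, float],
    base: Optional[ComponentPair] = None,
) -> ComponentPair:
    """Round-robin forward selection of S+ then S- over a shared pool.

    The two components compete for variants: one accepted into S+ leaves
    the pool of S-.  S+ moves first each round; growth stops for a
    component as soon as no remaining variant strictly improves its
    correlation in its own direction.
    """
    n = X.shape[0]
    plus = _Growing(n, +1.0, base.s_plus if base else None,
                    base.cor_plus if base else 0.0)
    minus = _Growing(n, -1.0, base.s_minus if base else None,
                     base.cor_minus if base else 0.0)
    pool = list(indices)
    active_p = active_m = True
    while (active_p or active_m) and pool:
        if active_p:
            active_p = plus.try_add(X, y, pool, col_of, w)
        if active_m and pool:
            active_m = minus.try_add(X, y, pool, col_of, w)
    return ComponentPair(
        s_plus=plus.freeze("plus"), s_minus=minus.freeze("minus"),
        cor_plus=plus.cor, cor_minus=minus.cor,
    )


def forward_select_common(
    G_common: np.ndarray, Y: PhenotypeVector, indices: Optional[list[int]] = None
) -> ComponentPair:
    """Step 1: greedy sum-collapsing of common SNPs into S+ and S-.

    ``indices`` optionally names the original column index of each supplied
    column (defaults to 0..J-1); members of the returned components use
    those labels.
    """
    X = np.asarray(G_common, dtype=float)
    if X.ndim != 2:
        X = X.reshape(len(Y.y), -1)
    j = X.shape[1]
    idx = list(range(j)) if indices is None else list(indices)
    col_of = {k: c for c, k in enumerate(idx)}
    w = {k: 1.0 for k in idx}
    return _grow_pair(X, Y.y, idx, col_of, w)


def forward_select_rare(
    G_rare: np.ndarray,
    Y: PhenotypeVector,
    base: Optional[ComponentPair] = None,
    weights: Optional[AdaptiveWeights] = None,
    indices: Optional[list[int]] = None,
) -> ComponentPair:
    """Step 2: greedy weighted-sum collapsing of rare variants onto bases.

    Each candidate enters as w_k * x_k with the adaptive weight; ``base``
    carries the common-SNP components forward (empty base reproduces the
    rare-only Step 3 pass).
    """
    X = np.asarray(G_rare, dtype=float)
    if X.ndim != 2:
        X = X.reshape(len(Y.y), -1)
    k = X.shape[1]
    if weights is None:
        weights = adaptive_weights(X, Y.y)
    idx = list(range(k)) if indices is None else list(indices)
    col_of = {kk: c for c, kk in enumerate(idx)}
    w = {kk: float(weights.w[c]) for c, kk in enumerate(idx)}
    return _grow_pair(X, Y.y, idx, col_of, w, base=base)


@dataclass
class WscCandidates:
    """The four selective-collapsing candidates and the winning score."""

    both: ComponentPair
    rare_only: ComponentPair
    chosen: str
    score: CollapsedScore
    cor2: float
    weights: AdaptiveWeights = field(repr=False, default=None)

    @property
    def is_degenerate(self) -> bool:
        return self.cor2 <= 0.0


def _candidates(G: GenotypeMatrix, Y: PhenotypeVector) -> tuple[
    ComponentPair, ComponentPair, AdaptiveWeights
]:
    X = G.values.astype(float)
    common_idx = list(np.flatnonzero(~G.is_rare))
    rare_idx = list(np.flatnonzero(G.is_rare))
    w = adaptive_weights(X[:, rare_idx], Y.y)
    base = forward_select_common(X[:, common_idx], Y, indices=common_idx)
    both = forward_select_rare(X[:, rare_idx], Y, base=base, weights=w,
                               indices=rare_idx)
    rare_only = forward_select_rare(X[:, rare_idx], Y, base=None, weights=w,
                                    indices=rare_idx)
    return both, rare_only, w


def swsc_score(G: GenotypeMatrix, Y: PhenotypeVector) -> WscCandidates:
    """The wSC collapsed score: argmax of Cor^2 over the four components."""
    both, rare_only, w = _candidates(G, Y)
    labelled = [
        ("BothPlus", both.s_plus, both.cor_plus),
        ("BothMinus", both.s_minus, both.cor_minus),
        ("RPlus", rare_only.s_plus, rare_only.cor_plus),
        ("RMinus", rare_only.s_minus, rare_only.cor_minus),
    ]
    best = max(
        (c for c in labelled if not c[1].is_empty),
        key=lambda c: c[2] ** 2,
        default=None,
    )
    if best is None:
        n = G.n_samples
        return WscCandidates(both, rare_only, "degenerate",
                             CollapsedScore(np.zeros(n), (), {}), 0.0, w)
    return WscCandidates(both, rare_only, best[0], best[1], best[2] ** 2, w)


def _difference_score(pair: ComponentPair) -> CollapsedScore:
    members = pair.s_plus.members + pair.s_minus.members
    weights = dict(pair.s_plus.weights)
    weights.update({k: -v for k, v in pair.s_minus.weights.items()})
    return CollapsedScore(
        s=pair.s_plus.s - pair.s_minus.s, members=members,
        weights=weights, direction="none",
    )


def swscd_score(G: GenotypeMatrix, Y: PhenotypeVector) -> WscCandidates:
    """The wSCd collapsed score: argmax of Cor^2 over the two differences."""
    both, rare_only, w = _candidates(G, Y)
    labelled = []
    for name, pair in (("BothDiff", both), ("RDiff", rare_only)):
        if pair.s_plus.is_empty and pair.s_minus.is_empty:
            continue
        d = _difference_score(pair)
        labelled.append((name, d, _cor(d.s, Y.y)))
    best = max(labelled, key=lambda c: c[2] ** 2, default=None)
    if best is None:
        n = G.n_samples
        return WscCandidates(both, rare_only, "degenerate",
                             CollapsedScore(np.zeros(n), (), {}), 0.0, w)
    return WscCandidates(both, rare_only, best[0], best[1], best[2] ** 2, w)


def wsc_statistic(G: GenotypeMatrix, Y: PhenotypeVector) -> float:
    """Score-test statistic Ts of the chosen wSC score (equals N * Cor^2)."""
    return score_statistic(swsc_score(G, Y).score.s, Y.y)


def wscd_statistic(G: GenotypeMatrix, Y: PhenotypeVector) -> float:
    """Score-test statistic Ts of the chosen wSCd score."""
    return score_statistic(swscd_score(G, Y).score.s, Y.y)


def wsc_both_test(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    plan: PermutationPlan,
) -> tuple[TestResult, TestResult]:
    """Permutation tests for wSC and wSCd sharing one set of shuffles.

    The four components are identical for the two statistics, so the
    selection is run once per shuffle and both statistics are read off it.
    The whole procedure — adaptive weights included — is recomputed on
    every permuted phenotype to remove selection bias.
    """
    Y.require_both_groups()
    rng = plan.rng()
    perms = permuted_labels(Y.y, plan.n_perm, rng)
    y_mat = np.vstack([Y.y[None, :], perms])
    t_wsc, t_wscd = _engine.batch_statistics(G, y_mat)
    res = []
    for t, name in ((t_wsc, "wSC"), (t_wscd, "wSCd")):
        if t[0] <= 0.0:
            res.append(TestResult(0.0, 1.0, name, n_perm=plan.n_perm))
        else:
            p = pvalue_from_draws(t[0], t[1:], add_one=plan.add_one)
            res.append(TestResult(float(t[0]), p, name, n_perm=plan.n_perm))
    return res[0], res[1]


def wsc_test(
    G: GenotypeMatrix, Y: PhenotypeVector, n_perm: int = 500, seed: int = 0
) -> TestResult:
    """wSC permutation test (statistic = score test of the selected score)."""
    plan = PermutationPlan(n_perm=n_perm, seed=seed)
    return wsc_both_test(G, Y, plan)[0]


def wscd_test(
    G: GenotypeMatrix, Y: PhenotypeVector, n_perm: int = 500, seed: int = 0
) -> TestResult:
    """wSCd permutation test, robust to mixed effect directions."""
    plan = PermutationPlan(n_perm=n_perm, seed=seed)
    return wsc_both_test(G, Y, plan)[1]
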