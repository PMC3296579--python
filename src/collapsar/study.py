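"""Replicated simulation experiments: type-I error and power tables.

Runs a panel of association tests over many simulated replicates of one
scenario and reports per-test rejection proportions at a significance
level, with binomial Monte-Carlo standard errors.  Replicates are shared
across the tests of one run (paired comparisons), and every replicate's
simulation and permutation seeds derive deterministically from the base
seed, the scenario, the OR parameter and the replicate index, so any cell
can be recomputed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from . import multimarker, selective, wsc
from .collapsing import (
    bonferroni_single_marker,
    cmc_test,
    collapse_indicator,
    collapse_sum,
    score_test,
    wsum_test,
)
from .datatypes import GenotypeMatrix, PhenotypeVector
from .permutation import PermutationPlan
from .simulator import ScenarioSpec, simulate_dataset

#: tests usable when the scenario has no common-SNP signal (17 tests)
PANEL_RARE_ONLY = (
    "R_ind", "R_sum", "B_ind", "B_sum", "RindSC", "RsumSC",
    "B_wSum", "B_wOR", "B_KML", "B_SSU", "B_SSUw",
    "B_aSSU", "B_aSSUw", "B_aSSUOrd", "B_aSSUwOrd",
    "B_wSC", "B_wSCd",
)
#: full panel including the common-variant-only tests (19 tests)
PANEL_FULL = PANEL_RARE_ONLY[:6] + ("C_bon", "C_logit") + PANEL_RARE_ONLY[6:]

#: tests whose p-value needs a permutation budget
PERMUTATION_TESTS = frozenset(
    {"RindSC", "RsumSC", "B_wSum", "B_wOR",
     "B_aSSU", "B_aSSUw", "B_aSSUOrd", "B_aSSUwOrd", "B_wSC", "B_wSCd"}
)


def default_panel(scenario: str) -> tuple[str, ...]:
    """The paper-style panel for a scenario: 19 tests for A/C/E, 17 for B/D."""
    return PANEL_FULL if scenario.upper() in ("A", "C", "E") else PANEL_RARE_ONLY


def _derive_seeds(
    base_seed: int, scenario: str, or_param: float, rep: int
) -> tuple[int, int]:
    """(simulation seed, permutation seed) for one replicate, < 2^31."""
    ss = np.random.SeedSequence(
        [int(base_seed), ord(scenario.upper()), int(round(or_param * 1000)), rep]
    )
    s = ss.generate_state(2, dtype=np.uint64)
    return int(s[0] % (2**31)), int(s[1] % (2**31))


def evaluate_tests(
    test_names: Sequence[str],
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    plan: PermutationPlan,
) -> dict[str, float]:
    """P-values of the named panel tests on one dataset.

    wSC and wSCd share one permutation pass (their selection is common);
    every other test runs independently with the same permutation budget.
    """
    pvals: dict[str, float] = {}
    names = list(test_names)
    unknown = [t for t in names if t not in PANEL_FULL]
    if unknown:
        raise ValueError(f"unknown tests {unknown}; panel is {sorted(PANEL_FULL)}")
    b, s = plan.n_perm, plan.seed
    if "B_wSC" in names or "B_wSCd" in names:
        r_wsc, r_wscd = wsc.wsc_both_test(G, Y, plan)
        pvals["B_wSC"] = r_wsc.p_value
        pvals["B_wSCd"] = r_wscd.p_value
    for t in names:
        if t in pvals:
            continue
        if t == "R_ind":
            pvals[t] = score_test(collapse_indicator(G), Y).p_value
        elif t == "R_sum":
            pvals[t] = score_test(collapse_sum(G), Y).p_value
        elif t == "C_bon":
            pvals[t] = bonferroni_single_marker(G.common(), Y).p_value
        elif t == "C_logit":
            pvals[t] = cmc_test(G.common(), None, Y, method="C_logit").p_value
        elif t == "B_ind":
            pvals[t] = cmc_test(G.common(), collapse_indicator(G), Y).p_value
        elif t == "B_sum":
            pvals[t] = cmc_test(G.common(), collapse_sum(G), Y).p_value
        elif t == "RindSC":
            pvals[t] = selective.rind_sc_test(G, Y, n_perm=b, seed=s).p_value
        elif t == "RsumSC":
            pvals[t] = selective.rsum_sc_test(G, Y, n_perm=b, seed=s).p_value
        elif t == "B_wSum":
            pvals[t] = wsum_test(G, Y, n_perm=b, seed=s).p_value
        elif t == "B_wOR":
            pvals[t] = multimarker.orwss(G, Y, n_perm=b, seed=s).p_value
        elif t == "B_SSU":
            pvals[t] = multimarker.ssu(G, Y).p_value
        elif t == "B_SSUw":
            pvals[t] = multimarker.ssuw(G, Y).p_value
        elif t == "B_KML":
            pvals[t] = multimarker.kernel_test(G, Y).p_value
        elif t.startswith("B_aSSU"):
            base = "ssuw" if "w" in t.removeprefix("B_aSSU") else "ssu"
            ordered = t.endswith("Ord")
            pvals[t] = multimarker.adaptive_sum(
                G, Y, base_stat=base, ordered=ordered, n_perm=b, seed=s
            ).p_value
    return {t: pvals[t] for t in names}


@dataclass
class StudyTable:
    """Per-test rejection proportions over replicates (power-table rows)."""

    rows: dict[tuple[str, str, float], tuple[float, float]]
    n_reps: int
    alpha: float = 0.05

    def to_frame(self):
        import pandas as pd

        recs = [
            {"test": t, "scenario": sc, "or": orp, "power": p, "mc_se": se}
            for (t, sc, orp), (p, se) in self.rows.items()
        ]
        return pd.DataFrame.from_records(recs)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_scenario(
    test_names: Sequence[str],
    spec: ScenarioSpec,
    n_reps: int,
    plan: PermutationPlan,
    alpha: float = 0.05,
    progress: Optional[Callable[[int], None]] = None,
) -> dict[str, tuple[float, float]]:
    """Rejection proportion (and MC standard error) per test over replicates.

    All tests see the same simulated replicates; each replicate draws its
    own dataset and permutation seeds from the base seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rejects = {t: 0 for t in test_names}
    for rep in range(n_reps):
        sim_seed, perm_seed = _derive_seeds(
            spec.seed, spec.scenario, spec.or_param, rep
        )
        G, Y = simulate_dataset(replace(spec, seed=sim_seed))
        rep_plan = PermutationPlan(
            n_perm=plan.n_perm, seed=perm_seed, add_one=plan.add_one
        )
        pvals = evaluate_tests(test_names, G, Y, rep_plan)
        for t, p in pvals.items():
            rejects[t] += int(p < alpha)
        if progress is not None:
            progress(rep)
    out = {}
    for t, r in rejects.items():
        prop = r / n_reps
        out[t] = (prop, float(np.sqrt(prop * (1.0 - prop) / n_reps)))
    return out


def run_cell(
    test_name: str,
    spec: ScenarioSpec,
    n_reps: int,
    plan: PermutationPlan,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """One table cell: rejection proportion and MC standard error."""
    return run_scenario([test_name], spec, n_reps, plan, alpha)[test_name]


def run_table(
    scenario: str,
    or_grid: Iterable[float],
    panel: Sequence[str],
    n_reps: int,
    plan: PermutationPlan,
    base_seed: int = 0,
    alpha: float = 0.05,
    **spec_kwargs,
) -> StudyTable:
    """A full power table: the panel crossed with an odds-ratio grid."""
    rows: dict[tuple[str, str, float], tuple[float, float]] = {}
    for orp in or_grid:
        spec = ScenarioSpec(
            scenario=scenario, or_param=float(orp), seed=base_seed, **spec_kwargs
        )
        cells = run_scenario(list(panel), spec, n_reps, plan, alpha)
        for t, cell in cells.items():
            rows[(t, scenario.upper(), float(orp))] = cell
    return StudyTable(rows=rows, n_reps=n_reps, alpha=alpha)
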