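"""Case-control simulator for a region of common and rare variants.

The generator emulates a candidate-gene region: four observed common SNPs
in linkage disequilibrium with one unobserved causal common SNP in the
middle, plus 20 non-causal and 8 causal rare variants.  Haplotype alleles
come from thresholded latent multivariate normals (a Gaussian copula), so
LD is controlled through latent correlations; genotypes are the sum of two
haplotypes; disease status follows a logistic model on the causal dosages,
and a case-control sample is accrued by rejection sampling from that
population model.  Five scenarios (A-E) cover the null, same-direction
rare effects, a weak hidden common effect, and mixed-direction effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .datatypes import GenotypeMatrix, PhenotypeVector

#: layout of the full latent region (before dropping the hidden SNP)
N_COMMON = 5          # 4 observed + 1 hidden causal
HIDDEN_IDX = 2        # the middle common SNP is unobserved
N_RARE_NULL = 20
N_RARE_CAUSAL = 8
N_TOTAL = N_COMMON + N_RARE_NULL + N_RARE_CAUSAL   # 33
HIDDEN_OR = 1.5       # scenarios C and E

#: default baseline disease prevalence for the logistic model
DEFAULT_PREVALENCE = 0.05


@dataclass
class HaplotypeModel:
    """Latent-normal LD model and allele-frequency ranges for the region."""

    common_corr: float = 0.4
    causal_link: float = 0.4          # |corr| of observed SNPs to the hidden one
    rare_corr_base: float = 0.4       # decay base: corr = base ** |i - j|
    common_maf_range: tuple[float, float] = (0.1, 0.3)
    rare_maf_range: tuple[float, float] = (0.001, 0.005)

    def common_corr_matrix(self, a: int) -> np.ndarray:
        """5x5 latent correlation; ``a`` (+1/-1) signs the hidden-SNP links."""
        c = np.full((N_COMMON, N_COMMON), self.common_corr)
        np.fill_diagonal(c, 1.0)
        c[HIDDEN_IDX, :] = a * self.causal_link
        c[:, HIDDEN_IDX] = a * self.causal_link
        c[HIDDEN_IDX, HIDDEN_IDX] = 1.0
        return c

    def rare_corr_matrix(self, size: int) -> np.ndarray:
        idx = np.arange(size)
        return self.rare_corr_base ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class ScenarioSpec:
    """One simulation condition: scenario letter, OR knob, sizes, seed."""

    scenario: str
    or_param: float = 1.0
    n_case: int = 500
    n_control: int = 500
    seed: int = 0
    prevalence: float = DEFAULT_PREVALENCE
    literal_reciprocals: bool = False   # read scenario-D "12" as OR=12, not 1/2
    model: HaplotypeModel = field(default_factory=HaplotypeModel)

    def __post_init__(self) -> None:
        self.scenario = self.scenario.upper()
        if self.scenario not in "ABCDE" or len(self.scenario) != 1:
            raise ValueError("scenario must be one of A-E")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("sample counts must be positive")


def or_vector(
    scenario: str, or_param: float, literal_reciprocals: bool = False
) -> np.ndarray:
    """Odds ratios for the 33 latent variants under a scenario.

    Layout: 5 common (hidden causal at index 2), 20 null rare, 8 causal
    rare.  Scenario A is the global null.  B gives the causal rare block
    (OR x4, OR+1 x4); C adds the hidden common SNP at OR 1.5.  D makes half
    the causal rare block protective — (OR, OR, 1/OR, 1/OR, OR+1, OR+1,
    1/(OR+1), 1/(OR+1)) by default; ``literal_reciprocals=True`` instead
    uses the implausible literal reading where e.g. 1/2 becomes 12.  E is D
    plus the hidden common effect.
    """
    scenario = scenario.upper()
    ors = np.ones(N_TOTAL)
    lo, hi = or_param, or_param + 1.0
    causal = slice(N_COMMON + N_RARE_NULL, N_TOTAL)
    if scenario == "A":
        return ors
    if scenario in ("B", "C"):
        ors[causal] = [lo] * 4 + [hi] * 4
    elif scenario in ("D", "E"):
        if literal_reciprocals:
            inv_lo = float(f"1{int(round(lo))}") if lo == int(lo) else 1.0 / lo
            inv_hi = float(f"1{int(round(hi))}") if hi == int(hi) else 1.0 / hi
        else:
            inv_lo, inv_hi = 1.0 / lo, 1.0 / hi
        ors[causal] = [lo, lo, inv_lo, inv_lo, hi, hi, inv_hi, inv_hi]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario in ("C", "E"):
        ors[HIDDEN_IDX] = HIDDEN_OR
    return ors


def draw_haplotypes(
    chol: np.ndarray, thresholds: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n haplotypes for one latent block: allele=1 iff Z_k < Phi^-1(maf_k)."""
    z = rng.standard_normal((n, chol.shape[0])) @ chol.T
    return (z < thresholds).astype(np.int8)


def draw_haplotype(
    corr: np.ndarray, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Single haplotype under a latent correlation matrix (convenience)."""
    chol = np.linalg.cholesky(corr)
    thr = norm.ppf(np.asarray(mafs, dtype=float))
    return draw_haplotypes(chol, thr, 1, rng)[0]


def genotype_from_haplotypes(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Additive genotype = sum of the two haplotypes (entries 0/1/2)."""
    return (np.asarray(h1) + np.asarray(h2)).astype(np.int8)


class _RegionSampler:
    """Per-replicate frozen region: MAFs, latent Cholesky factors, ORs."""

    def __init__(self, spec: ScenarioSpec, rng: np.random.Generator):
        m = spec.model
        a = 1 if rng.random() < 0.5 else -1
        self.chols = [
            np.linalg.cholesky(m.common_corr_matrix(a)),
            np.linalg.cholesky(m.rare_corr_matrix(N_RARE_NULL)),
            np.linalg.cholesky(m.rare_corr_matrix(N_RARE_CAUSAL)),
        ]
        mafs = np.concatenate(
            [
                rng.uniform(*m.common_maf_range, N_COMMON),
                rng.uniform(*m.rare_maf_range, N_RARE_NULL),
                rng.uniform(*m.rare_maf_range, N_RARE_CAUSAL),
            ]
        )
        self.mafs = mafs
        self.thresholds = np.split(norm.ppf(mafs), [N_COMMON, N_COMMON + N_RARE_NULL])
        self.beta = np.log(
            or_vector(spec.scenario, spec.or_param, spec.literal_reciprocals)
        )
        self.beta0 = float(logit(spec.prevalence))

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """n individuals: (genotypes N x 33, phenotype N)."""
        blocks = []
        for chol, thr in zip(self.chols, self.thresholds):
            h1 = draw_haplotypes(chol, thr, n, rng)
            h2 = draw_haplotypes(chol, thr, n, rng)
            blocks.append(h1 + h2)
        x = np.hstack(blocks)
        eta = self.beta0 + x.astype(float) @ self.beta
        y = (rng.random(n) < expit(eta)).astype(float)
        return x, y


def simulate_dataset(spec: ScenarioSpec) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Simulate one case-control dataset under a scenario.

    Individuals are drawn from the population model until the requested
    numbers of cases and controls have accrued (rejection sampling keeps
    the retrospective design exact).  The hidden causal common SNP is
    dropped from the returned matrix and the 32 observed variant columns
    are shuffled, so adaptive tests cannot exploit variant order.
    """
    rng = np.random.default_rng(spec.seed)
    sampler = _RegionSampler(spec, rng)

    need_case, need_ctrl = spec.n_case, spec.n_control
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    got_case = got_ctrl = 0
    max_draws = 2_000_000 + 200 * (spec.n_case + spec.n_control)
    drawn = 0
    while got_case < need_case or got_ctrl < need_ctrl:
        if drawn > max_draws:
            raise RuntimeError(
                "case/control accrual failed: check prevalence and odds ratios"
            )
        # expected draws to finish, padded; prevalence bounds the case rate
        n_chunk = int(
            min(
                200_000,
                max(
                    2000,
                    1.3 * (need_case - got_case) / max(spec.prevalence, 1e-4),
                ),
            )
        )
        x, y = sampler.draw(n_chunk, rng)
        drawn += n_chunk
        if got_case < need_case:
            xc = x[y == 1][: need_case - got_case]
            cases.append(xc)
            got_case += len(xc)
        if got_ctrl < need_ctrl:
            xc = x[y == 0][: need_ctrl - got_ctrl]
            ctrls.append(xc)
            got_ctrl += len(xc)

    x_all = np.vstack(cases + ctrls)
    y_all = np.concatenate([np.ones(need_case), np.zeros(need_ctrl)])
    # shuffle sample order, drop the hidden SNP, shuffle variant order
    row_order = rng.permutation(len(y_all))
    x_all, y_all = x_all[row_order], y_all[row_order]
    observed = np.delete(x_all, HIDDEN_IDX, axis=1)
    observed_mafs = np.delete(sampler.mafs, HIDDEN_IDX)
    col_order = rng.permutation(observed.shape[1])
    observed = observed[:, col_order]
    observed_mafs = observed_mafs[col_order]

    latent_ids = [f"C{j+1}" for j in range(N_COMMON)]
    latent_ids += [f"R{j+1}" for j in range(N_RARE_NULL)]
    latent_ids += [f"RC{j+1}" for j in range(N_RARE_CAUSAL)]
    observed_ids = [v for i, v in enumerate(latent_ids) if i != HIDDEN_IDX]
    variant_ids = [observed_ids[j] for j in col_order]

    # the generator knows the population MAFs, so the rare/common split is
    # by construction (case enrichment cannot flip a rare variant common)
    threshold = 0.01
    G = GenotypeMatrix(
        values=observed.astype(np.int8),
        sample_ids=[f"S{i}" for i in range(len(y_all))],
        variant_ids=variant_ids,
        maf=observed_mafs,
        is_rare=observed_mafs < threshold,
        rare_threshold=threshold,
    )
    return G, PhenotypeVector(y_all)
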