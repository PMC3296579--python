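"""Core containers shared across the package.

Genotypes are held as an N x K additive-dosage matrix (0/1/2 counts of the
minor allele); phenotypes as a binary case/control vector.  Collapsed burden
scores and test outcomes get small dataclasses so every statistical routine
returns the same shape of result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: MAF below which a variant is classed as rare (overridable everywhere).
RARE_THRESHOLD = 0.01


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes for N samples at K variants.

    ``values[i, k]`` counts minor alleles (0, 1 or 2).  ``maf`` holds the
    per-variant minor-allele frequency (folded to [0, 0.5]); ``is_rare``
    flags variants with MAF below ``rare_threshold``.
    """

    values: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    maf: np.ndarray
    is_rare: np.ndarray
    rare_threshold: float = RARE_THRESHOLD

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        sample_ids: Optional[Sequence[str]] = None,
        variant_ids: Optional[Sequence[str]] = None,
        rare_threshold: float = RARE_THRESHOLD,
    ) -> "GenotypeMatrix":
        """Build a matrix computing MAF and rare flags from the data."""
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if not np.isin(values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        n, k = values.shape
        freq = values.sum(axis=0) / (2.0 * n)
        maf = np.minimum(freq, 1.0 - freq)
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(n)]
        if variant_ids is None:
            variant_ids = [f"V{j}" for j in range(k)]
        return cls(
            values=values.astype(np.int8),
            sample_ids=list(sample_ids),
            variant_ids=list(variant_ids),
            maf=maf,
            is_rare=maf < rare_threshold,
            rare_threshold=rare_threshold,
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def rare(self) -> np.ndarray:
        """Float view of the rare columns (N x K_rare)."""
        return self.values[:, self.is_rare].astype(float)

    def common(self) -> np.ndarray:
        """Float view of the common columns (N x J)."""
        return self.values[:, ~self.is_rare].astype(float)

    def validate(self) -> None:
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        if self.maf.shape[0] != self.n_variants:
            raise ValueError("maf length mismatch")
        if ((self.maf < self.rare_threshold) != self.is_rare).any():
            raise ValueError("is_rare inconsistent with maf")


@dataclass
class PhenotypeVector:
    """Binary case/control labels: 1 = case, 0 = control."""

    y: np.ndarray
    n_case: int = field(init=False)
    n_control: int = field(init=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotype entries must be 0 or 1")
        self.n_case = int(self.y.sum())
        self.n_control = int(len(self.y) - self.n_case)

    @property
    def n(self) -> int:
        return len(self.y)

    def require_both_groups(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")


@dataclass
class CollapsedScore:
    """A per-sample burden score with its provenance.

    ``s`` is the length-N score vector; ``members`` the variant (column)
    indices it aggregates; ``weights`` the per-member weight (1.0 when
    unweighted); ``direction`` labels selectively built components
    ("plus" deleterious, "minus" protective, "none" otherwise).
    """

    s: np.ndarray
    members: tuple[int, ...]
    weights: dict[int, float]
    direction: str = "none"

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0


@dataclass
class TestResult:
    """Outcome of one association test."""

    statistic: float
    p_value: float
    method: str
    df: Optional[int] = None
    n_perm: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
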