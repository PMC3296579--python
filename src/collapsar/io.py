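"""Reading and writing genotype/phenotype files.

Genotypes come in either as VCF (additive dosage from the GT field, read
with cyvcf2) or as a TSV of samples x variants; phenotypes as a two-column
TSV (sample_id, status 0/1).  Writing produces plain-text VCF 4.2 so
simulated regions can round-trip through standard tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import RARE_THRESHOLD, GenotypeMatrix, PhenotypeVector

_GT_CODES = {0: 0, 1: 1, 3: 2}  # cyvcf2 gt_types: HOM_REF, HET, HOM_ALT


def read_vcf(path: str | Path, rare_threshold: float = RARE_THRESHOLD) -> GenotypeMatrix:
    """Read a VCF into an additive genotype matrix (missing GTs rejected)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    ids = []
    for var in vcf:
        codes = var.gt_types
        if (codes == 2).any():  # 2 == UNKNOWN in cyvcf2
            raise ValueError(f"missing genotype at {var.ID or var.POS}")
        rows.append([_GT_CODES[int(c)] for c in codes])
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValueError("VCF contains no variants")
    values = np.asarray(rows, dtype=np.int8).T  # samples x variants
    return GenotypeMatrix.from_values(
        values, sample_ids=samples, variant_ids=ids, rare_threshold=rare_threshold
    )


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as minimal VCF 4.2 (chromosome 1, positions 1..K)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for k in range(G.n_variants):
            calls = "\t".join(gt[int(v)] for v in G.values[:, k])
            fh.write(f"1\t{k + 1}\t{G.variant_ids[k]}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_genotype_tsv(
    path: str | Path, rare_threshold: float = RARE_THRESHOLD
) -> GenotypeMatrix:
    """Read a samples x variants TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix.from_values(
        df.to_numpy(),
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
        rare_threshold=rare_threshold,
    )


def write_genotype_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(
        G.values, index=G.sample_ids, columns=G.variant_ids
    ).to_csv(path, sep="\t")


def read_phenotype_tsv(path: str | Path) -> PhenotypeVector:
    """Read (sample_id, status) TSV; status must be 0/1."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype TSV needs sample_id and status columns")
    return PhenotypeVector(df.iloc[:, 1].to_numpy(dtype=float))


def write_phenotype_tsv(Y: PhenotypeVector, sample_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": sample_ids, "status": Y.y.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_null_pool(path: str | Path) -> np.ndarray:
    """One statistic per line, plain text."""
    return np.loadtxt(path, ndmin=1)
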