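"""Linkage disequilibrium (Hill-Robertson r^2) from phased haplotypes.

With phased haplotypes the two-locus haplotype frequencies are observed
directly, so r^2 is exact:

    D   = p_AB - p_A p_B
    r^2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B))

which equals the squared Pearson correlation of the two 0/1 haplotype
columns. No EM estimation from genotypes is needed at this stage of the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import HaplotypeMatrix, MarkerMap

__all__ = ["LDResult", "r2", "region_mean_r2"]


@dataclass(frozen=True)
class LDResult:
    i: int
    j: int
    p_ab: float
    p_a: float
    p_b: float
    d: float
    r2: float


def r2(hap: HaplotypeMatrix, i: int, j: int) -> LDResult:
    """Hill-Robertson r^2 between SNP columns i and j.

    Allele "A"/"B" is the 1-coded allele at each locus; r^2 is invariant
    to which label is chosen. Raises ``ValueError`` if either SNP is
    monomorphic (r^2 undefined).
    """
    a = hap.values[:, i].astype(np.float64)
    b = hap.values[:, j].astype(np.float64)
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError(f"monomorphic SNP in pair ({i}, {j}); r^2 undefined")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    denom = p_a * (1.0 - p_a) * p_b * (1.0 - p_b)
    return LDResult(i, j, p_ab, p_a, p_b, d, float(d * d / denom))


def region_mean_r2(
    hap: HaplotypeMatrix,
    mmap: MarkerMap,
    chrom: str,
    start: int,
    end: int,
    max_pairs: int = 100_000,
    seed: int = 0,
) -> tuple[float, int, int]:
    """Mean r^2 over SNP pairs inside [start, end] on ``chrom`` (1-based incl.).

    Monomorphic SNPs are excluded up front. If the number of pairs exceeds
    ``max_pairs`` a seeded uniform subsample of pairs is used. Returns
    (mean r^2, number of pairs used, number of SNPs skipped as
    monomorphic); raises ``ValueError`` with fewer than two usable SNPs.
    """
    in_region = (mmap.chrom == str(chrom)) & (mmap.pos >= start) & (mmap.pos <= end)
    idx = np.nonzero(in_region)[0]
    freq = hap.values[:, idx].mean(axis=0) if idx.size else np.empty(0)
    poly = (freq > 0.0) & (freq < 1.0)
    skipped = int((~poly).sum())
    idx = idx[poly]
    m = idx.size
    if m < 2:
        raise ValueError("fewer than 2 polymorphic SNPs in region; mean r^2 undefined")
    total = m * (m - 1) // 2
    ii, jj = np.triu_indices(m, k=1)
    if total > max_pairs:
        rng = np.random.default_rng(seed)
        take = rng.choice(total, size=max_pairs, replace=False)
        ii, jj = ii[take], jj[take]
    cols = hap.values[:, idx].astype(np.float64)
    p = cols.mean(axis=0)
    p_ab = (cols[:, ii] * cols[:, jj]).mean(axis=0)
    d = p_ab - p[ii] * p[jj]
    denom = p[ii] * (1.0 - p[ii]) * p[jj] * (1.0 - p[jj])
    return float(np.mean(d * d / denom)), int(ii.size), skipped
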