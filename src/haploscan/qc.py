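"""Genotype quality-control cascade with per-step accounting.

Steps, in a fixed documented order so survivor counts are reproducible:

1. mask genotypes with call score < 0.20 as missing (nothing removed);
2. keep only autosomal SNPs with a defined map position;
3. drop SNPs with call rate < 0.95;
4. drop samples with call rate < 0.90;
5. drop SNPs with MAF < 0.01, recomputed on the surviving samples.

MAF is computed from non-missing genotypes only and last, so frequencies
reflect the final sample set. Fixed alleles (derived frequency 0 or 1)
are removed separately at the haplotype stage (:func:`drop_fixed`), just
before the iHS scan, not as part of genotype QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix, HaplotypeMatrix, MarkerMap

__all__ = [
    "QCReport",
    "mask_low_score",
    "filter_autosomal_mapped",
    "filter_call_rates_and_maf",
    "drop_fixed",
    "run_qc",
]

AUTOSOME_MAX = 29  # Bos taurus; configurable via filter_autosomal_mapped


@dataclass
class QCReport:
    """Ordered per-step (name, snps_before, snps_after, samples_before, samples_after)."""

    steps: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def add(self, name, snps_before, snps_after, samples_before, samples_after):
        if snps_after > snps_before or samples_after > samples_before:
            raise ValueError(f"QC step {name!r} increased counts")
        self.steps.append((name, int(snps_before), int(snps_after),
                           int(samples_before), int(samples_after)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=[
            "step", "snps_before", "snps_after", "samples_before", "samples_after",
        ])


def mask_low_score(geno: GenotypeMatrix, threshold: float = 0.20) -> GenotypeMatrix:
    """Set genotypes with call score < threshold to missing; removes nothing."""
    if geno.call_score is None:
        warnings.warn("no call scores available; score masking is a no-op", stacklevel=2)
        return geno
    dosage = geno.dosage.copy()
    dosage[geno.call_score < threshold] = np.nan
    return GenotypeMatrix(dosage, geno.call_score, geno.sample_ids)


def _is_autosomal(chrom: np.ndarray, autosome_max: int) -> np.ndarray:
    out = np.zeros(len(chrom), dtype=bool)
    for i, c in enumerate(chrom):
        c = str(c).removeprefix("chr")
        out[i] = c.isdigit() and 1 <= int(c) <= autosome_max
    return out


def filter_autosomal_mapped(
    mmap: MarkerMap, geno: GenotypeMatrix, autosome_max: int = AUTOSOME_MAX,
) -> tuple[GenotypeMatrix, MarkerMap, np.ndarray]:
    """Keep only SNPs on an autosome with a defined (> 0) position."""
    keep = _is_autosomal(mmap.chrom, autosome_max) & (mmap.pos > 0)
    idx = np.nonzero(keep)[0]
    out = GenotypeMatrix(
        geno.dosage[:, idx],
        geno.call_score[:, idx] if geno.call_score is not None else None,
        geno.sample_ids,
    )
    return out, mmap.take(idx), idx


def _snp_call_rate(dosage: np.ndarray) -> np.ndarray:
    return 1.0 - np.isnan(dosage).mean(axis=0)


def _sample_call_rate(dosage: np.ndarray) -> np.ndarray:
    return 1.0 - np.isnan(dosage).mean(axis=1)


def _maf(dosage: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nanmean(dosage, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    return np.minimum(freq, 1.0 - freq)


def filter_call_rates_and_maf(
    geno: GenotypeMatrix,
    mmap: MarkerMap,
    snp_cr: float = 0.95,
    sample_cr: float = 0.90,
    maf_min: float = 0.01,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """SNP call rate, then sample call rate, then MAF on the survivors.

    Removing a sample changes every SNP's call-rate denominator (and vice
    versa), so a single pass is not always a fixed point of its own
    thresholds; the three filters are re-applied until nothing more is
    removed, which makes the cascade idempotent. The second iteration is
    a no-op except on threshold-boundary data and is only recorded in the
    report when it removes something.
    """
    if report is None:
        report = QCReport()
    report.thresholds.update({"snp_cr": snp_cr, "sample_cr": sample_cr, "maf_min": maf_min})
    dosage = geno.dosage
    scores = geno.call_score
    samples = list(geno.sample_ids)
    map_df = mmap.df

    iteration = 0
    while True:
        iteration += 1
        suffix = "" if iteration == 1 else f"_{iteration}"
        removed_any = False

        n_snps, n_samples = dosage.shape[1], dosage.shape[0]
        keep_snp = _snp_call_rate(dosage) >= snp_cr
        dosage = dosage[:, keep_snp]
        scores = scores[:, keep_snp] if scores is not None else None
        map_df = map_df.loc[keep_snp].reset_index(drop=True)
        if iteration == 1 or not keep_snp.all():
            report.add(f"snp_call_rate{suffix}", n_snps, dosage.shape[1],
                       n_samples, n_samples)
        removed_any |= not keep_snp.all()

        keep_sample = _sample_call_rate(dosage) >= sample_cr
        dosage = dosage[keep_sample]
        scores = scores[keep_sample] if scores is not None else None
        samples = [s for s, k in zip(samples, keep_sample) if k]
        if iteration == 1 or not keep_sample.all():
            report.add(f"sample_call_rate{suffix}", dosage.shape[1], dosage.shape[1],
                       n_samples, dosage.shape[0])
        removed_any |= not keep_sample.all()

        n_before = dosage.shape[1]
        keep_maf = _maf(dosage) >= maf_min
        dosage = dosage[:, keep_maf]
        scores = scores[:, keep_maf] if scores is not None else None
        map_df = map_df.loc[keep_maf].reset_index(drop=True)
        if iteration == 1 or not keep_maf.all():
            report.add(f"maf{suffix}", n_before, dosage.shape[1],
                       dosage.shape[0], dosage.shape[0])
        removed_any |= not keep_maf.all()

        if dosage.shape[0] == 0 or dosage.shape[1] == 0:
            raise ValueError("empty dataset after QC")
        if not removed_any:
            break
    return GenotypeMatrix(dosage, scores, samples), MarkerMap(map_df, validate=False), report


def drop_fixed(hap: HaplotypeMatrix, mmap: MarkerMap) -> tuple[HaplotypeMatrix, MarkerMap, int]:
    """Remove SNPs fixed in the haplotype set (derived frequency 0 or 1)."""
    freq = hap.derived_freq()
    keep = (freq > 0.0) & (freq < 1.0)
    idx = np.nonzero(keep)[0]
    return hap.take_snps(idx), mmap.take(idx), int((~keep).sum())


def run_qc(
    geno: GenotypeMatrix,
    mmap: MarkerMap,
    score_min: float = 0.20,
    snp_cr: float = 0.95,
    sample_cr: float = 0.90,
    maf_min: float = 0.01,
    autosome_max: int = AUTOSOME_MAX,
) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """The full cascade in its fixed order. Idempotent."""
    report = QCReport(thresholds={
        "score_min": score_min, "snp_cr": snp_cr,
        "sample_cr": sample_cr, "maf_min": maf_min,
    })
    n_snps, n_samples = geno.n_snps, geno.n_samples
    geno = mask_low_score(geno, score_min) if geno.call_score is not None else geno
    report.add("score_mask", n_snps, geno.n_snps, n_samples, geno.n_samples)
    geno, mmap, _ = filter_autosomal_mapped(mmap, geno, autosome_max)
    report.add("autosomal_mapped", n_snps, geno.n_snps, n_samples, geno.n_samples)
    return filter_call_rates_and_maf(geno, mmap, snp_cr, sample_cr, maf_min, report)
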