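"""Data model and I/O for the formats the scan pipeline touches.

In-memory containers
--------------------
:class:`MarkerMap`
    Per-SNP chromosome, 1-based position, allele labels, ancestral state
    and derived-allele frequency.
:class:`HaplotypeMatrix`
    Binary phased haplotypes, rows = haplotypes (two consecutive rows per
    sample), columns = SNPs. Allele 0 is the ancestral allele once
    :func:`set_ancestral` has been applied; straight off a VCF it is the
    REF allele.
:class:`GenotypeMatrix`
    Diploid dosages in {0, 1, 2} with NaN for missing calls, plus an
    optional per-genotype call score in [0, 1] used by quality control.
:class:`GeneInterval`
    A gene (or any genomic feature) as a 1-based inclusive interval,
    optionally carrying sub-features (exons, UTRs) for genic
    sub-classification.

All genomic coordinates are held 1-based inclusive internally; BED's
0-based half-open convention is converted at the read/write boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "HaplotypeMatrix",
    "GenotypeMatrix",
    "GeneInterval",
    "read_phased_vcf",
    "write_phased_vcf",
    "set_ancestral",
    "read_ancestral_table",
    "read_gene_intervals",
    "write_results",
    "read_results",
    "write_regions_bed",
]

MAP_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "ancestral", "derived_freq", "maf"]

RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "derived_freq", "ihs", "pihs",
    "significant_1e5", "significant_1e4", "window_id",
]


class MarkerMap:
    """Ordered table of SNP markers.

    Wraps a :class:`pandas.DataFrame` with columns ``snp_id, chrom, pos,
    ref_allele, alt_allele, ancestral, derived_freq, maf``. ``ancestral``
    is one of ``{"ref", "alt", "unknown"}``. Positions must be strictly
    increasing within each chromosome.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in ("snp_id", "chrom", "pos") if c not in df.columns]
        if missing:
            raise ValueError(f"MarkerMap missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        for col, default in (
            ("ref_allele", "A"), ("alt_allele", "G"),
            ("ancestral", "unknown"), ("derived_freq", np.nan), ("maf", np.nan),
        ):
            if col not in df.columns:
                df[col] = default
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        self.df = df[MAP_COLUMNS]
        if validate:
            self._check_sorted()

    def _check_sorted(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def ancestral_known(self) -> np.ndarray:
        return (self.df["ancestral"] != "unknown").to_numpy()

    def take(self, indices) -> "MarkerMap":
        return MarkerMap(self.df.iloc[np.asarray(indices)], validate=False)


class HaplotypeMatrix:
    """Binary phased haplotypes: ``(2 * n_samples, n_snps)`` array of 0/1.

    Row order is fixed as (sample1_hapA, sample1_hapB, sample2_hapA, ...)
    so that results are reproducible across runs.
    """

    def __init__(self, values: np.ndarray, sample_ids=None):
        values = np.ascontiguousarray(values, dtype=np.int8)
        if values.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if values.shape[0] % 2:
            raise ValueError("haplotype row count must be even (two rows per sample)")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            raise ValueError("haplotype entries must be 0/1 with no missing values")
        self.values = values
        if sample_ids is None:
            sample_ids = [f"S{i + 1}" for i in range(values.shape[0] // 2)]
        if len(sample_ids) * 2 != values.shape[0]:
            raise ValueError("sample_ids length inconsistent with row count")
        self.sample_ids = list(sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Per-SNP mean of the 1-coded allele (derived allele once polarized)."""
        return self.values.mean(axis=0)

    def take_snps(self, indices) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.values[:, np.asarray(indices)], self.sample_ids)

    def take_samples(self, indices) -> "HaplotypeMatrix":
        rows = np.repeat(np.asarray(indices) * 2, 2)
        rows[1::2] += 1
        return HaplotypeMatrix(self.values[rows], [self.sample_ids[i] for i in indices])

    def to_dosage(self) -> np.ndarray:
        return self.values[0::2].astype(np.float64) + self.values[1::2]


class GenotypeMatrix:
    """Diploid dosages (samples x SNPs) with NaN = missing, plus call scores."""

    def __init__(self, dosage: np.ndarray, call_score: np.ndarray | None = None, sample_ids=None):
        dosage = np.asarray(dosage, dtype=np.float64)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D")
        ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or NaN")
        self.dosage = dosage
        if call_score is not None:
            call_score = np.asarray(call_score, dtype=np.float64)
            if call_score.shape != dosage.shape:
                raise ValueError("call_score shape must match dosage")
        self.call_score = call_score
        if sample_ids is None:
            sample_ids = [f"S{i + 1}" for i in range(dosage.shape[0])]
        self.sample_ids = list(sample_ids)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a 1-based inclusive interval, with optional sub-features.

    ``features`` is a tuple of ``(kind, start, end)`` where kind is one of
    ``exon``, ``five_prime_UTR``, ``three_prime_UTR`` (1-based inclusive).
    """

    chrom: str
    start: int
    end: int
    name: str
    features: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start > end for {self.name}: {self.start} > {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# VCF

def read_phased_vcf(path) -> tuple[HaplotypeMatrix, MarkerMap, list]:
    """Read a phased, biallelic-SNP VCF into a haplotype matrix and marker map.

    Alleles are provisionally coded 0 = REF; apply :func:`set_ancestral`
    to recode to ancestral/derived polarity. Raises ``ValueError`` on
    unphased, missing or multiallelic genotypes: the scan requires
    complete phased input (phasing/imputation is upstream of this
    package).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows = []
        columns = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"multiallelic or ALT-less record at {rec.chrom}:{rec.pos}")
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, sample in enumerate(rec.samples.values()):
                alleles = sample.allele_indices
                if alleles is None or any(a is None for a in alleles):
                    raise ValueError(f"missing GT at {rec.chrom}:{rec.pos} sample {samples[i]}")
                if len(alleles) != 2:
                    raise ValueError(f"non-diploid GT at {rec.chrom}:{rec.pos} sample {samples[i]}")
                if not sample.phased:
                    raise ValueError(f"unphased genotype at {rec.chrom}:{rec.pos} sample {samples[i]}")
                col[2 * i] = alleles[0]
                col[2 * i + 1] = alleles[1]
            columns.append(col)
            rows.append({
                "snp_id": rec.id if rec.id else f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref_allele": rec.ref,
                "alt_allele": rec.alts[0],
            })
    if not rows:
        raise ValueError("VCF contains no records")
    values = np.column_stack(columns)
    mmap = MarkerMap(pd.DataFrame(rows))
    hap = HaplotypeMatrix(values, samples)
    freq = hap.derived_freq()
    mmap.df["derived_freq"] = freq
    mmap.df["maf"] = np.minimum(freq, 1.0 - freq)
    return hap, mmap, samples


def write_phased_vcf(hap: HaplotypeMatrix, mmap: MarkerMap, path) -> None:
    """Write haplotypes + map as a minimal phased VCF (text, v4.2)."""
    df = mmap.df
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haploscan\n")
        for chrom in pd.unique(df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hap.sample_ids) + "\n")
        values = hap.values
        for j in range(len(df)):
            row = df.iloc[j]
            gts = "\t".join(
                f"{values[2 * i, j]}|{values[2 * i + 1, j]}" for i in range(hap.n_samples)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref_allele}\t"
                     f"{row.alt_allele}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Ancestral-allele polarization

def read_ancestral_table(path) -> pd.DataFrame:
    """Read a 3-column TSV (snp_id, chrom:pos, ancestral_allele)."""
    tab = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    tab.columns = [c.strip().lower() for c in tab.columns]
    expected = {"snp_id", "chrom:pos", "ancestral_allele"}
    if not expected.issubset(tab.columns):
        raise ValueError(f"ancestral table must have columns {sorted(expected)}")
    return tab


def set_ancestral(
    hap: HaplotypeMatrix,
    mmap: MarkerMap,
    table: pd.DataFrame,
) -> tuple[HaplotypeMatrix, MarkerMap]:
    """Recode haplotypes so allele 0 is ancestral everywhere.

    ``table`` is keyed by SNP id with a (chrom, pos) fallback (the columns
    of :func:`read_ancestral_table`). SNPs whose ancestral allele is
    absent from the table, or matches neither REF nor ALT, are flagged
    ``unknown`` (kept for QC and LD, excluded from iHS downstream).
    Derived-allele frequencies are recomputed after recoding.
    """
    by_id: dict[str, str] = {}
    by_pos: dict[str, str] = {}
    for _, r in table.iterrows():
        anc = str(r["ancestral_allele"]).strip().upper()
        if r.get("snp_id") and str(r["snp_id"]) != "nan":
            by_id[str(r["snp_id"])] = anc
        if r.get("chrom:pos") and str(r["chrom:pos"]) != "nan":
            by_pos[str(r["chrom:pos"])] = anc

    df = mmap.df.copy()
    values = hap.values.copy()
    n_unknown = 0
    ancestral = []
    for j, row in enumerate(df.itertuples(index=False)):
        anc = by_id.get(str(row.snp_id)) or by_pos.get(f"{row.chrom}:{row.pos}")
        if anc == str(row.ref_allele).upper():
            ancestral.append("ref")
        elif anc == str(row.alt_allele).upper():
            ancestral.append("alt")
            values[:, j] = 1 - values[:, j]  # ALT is ancestral: flip polarity
        else:
            ancestral.append("unknown")
            n_unknown += 1
    if n_unknown:
        warnings.warn(f"{n_unknown} SNPs with unknown ancestral state "
                      "(kept for QC/LD, excluded from iHS)", stacklevel=2)
    df["ancestral"] = ancestral
    out_hap = HaplotypeMatrix(values, hap.sample_ids)
    freq = out_hap.derived_freq()
    df["derived_freq"] = freq
    df["maf"] = np.minimum(freq, 1.0 - freq)
    return out_hap, MarkerMap(df, validate=False)


# ---------------------------------------------------------------------------
# Gene intervals

def read_gene_intervals(path, dialect: str | None = None, feature_type: str = "gene") -> list[GeneInterval]:
    """Read gene intervals from BED or GFF3 into 1-based inclusive intervals.

    ``dialect`` is ``"bed"`` or ``"gff3"``; inferred from the file
    extension when omitted. For GFF3, records of ``feature_type`` become
    genes and any exon/UTR children are attached as sub-features.
    """
    path = str(path)
    if dialect is None:
        low = path.lower()
        if low.endswith((".gff", ".gff3")):
            dialect = "gff3"
        elif low.endswith(".bed"):
            dialect = "bed"
        else:
            raise ValueError("cannot infer dialect from extension; pass dialect=")
    if dialect == "bed":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if bed.shape[1] < 3:
            raise ValueError("BED needs at least 3 columns")
        out = []
        for i, r in bed.iterrows():
            start = int(r[1]) + 1  # 0-based half-open -> 1-based inclusive
            end = int(r[2])
            name = str(r[3]) if bed.shape[1] > 3 else f"feature{i + 1}"
            out.append(GeneInterval(str(r[0]), start, end, name))
        return out
    if dialect == "gff3":
        import gffutils

        db = gffutils.create_db(path, ":memory:", force=True, merge_strategy="create_unique")
        out = []
        for g in db.features_of_type(feature_type):
            feats = []
            for child in db.children(g.id):
                if child.featuretype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                    feats.append((child.featuretype, child.start, child.end))
            name = g.attributes.get("Name", [g.id])[0]
            out.append(GeneInterval(g.seqid, g.start, g.end, name, tuple(sorted(feats))))
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Result tables

def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table (iHS table, regions, LD ...) as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write candidate regions as BED (internal 1-based -> 0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.first_sig_pos - 1}\t{r.last_sig_pos}\t"
                     f"window_{r.window_id}\t{r.n_sig_snps}\n")
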