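"""Nearest-gene annotation of significant SNPs.

A SNP inside a gene interval is genic with distance 0 (sub-classified as
exon/UTR/intron when feature intervals are available); otherwise the
nearest gene is the one whose closest boundary (start or end) is nearest,
with ties broken by lower coordinate then name. Distances are in bp on
the 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GeneInterval

__all__ = ["SnpAnnotation", "annotate_snp", "annotate_table", "summarize_labels"]


@dataclass(frozen=True)
class SnpAnnotation:
    snp_id: str
    gene: str               # "none" when the chromosome has no genes
    distance: float         # 0 if inside; inf when no gene available
    label: str              # genic | intergenic | none
    sub_label: str = ""     # intron / exon / 5' UTR / 3' UTR when features known


_UTR_LABEL = {"five_prime_UTR": "5' UTR", "three_prime_UTR": "3' UTR"}


def _sub_label(gene: GeneInterval, pos: int) -> str:
    if not gene.features:
        return ""
    for kind, start, end in gene.features:
        if kind in _UTR_LABEL and start <= pos <= end:
            return _UTR_LABEL[kind]
    for kind, start, end in gene.features:
        if kind == "exon" and start <= pos <= end:
            return "exon"
    return "intron"


def annotate_snp(pos: int, chrom: str, genes: list[GeneInterval], snp_id: str = "") -> SnpAnnotation:
    """Annotate one SNP against a gene set (any ordering; ties deterministic)."""
    here = [g for g in genes if g.chrom == str(chrom)]
    if not here:
        return SnpAnnotation(snp_id, "none", float("inf"), "none")
    covering = sorted((g for g in here if g.contains(pos)), key=lambda g: (g.start, g.name))
    if covering:
        g = covering[0]
        return SnpAnnotation(snp_id, g.name, 0.0, "genic", _sub_label(g, pos))
    starts = np.array([g.start for g in here])
    ends = np.array([g.end for g in here])
    dist = np.minimum(np.abs(pos - starts), np.abs(pos - ends))
    order = sorted(range(len(here)), key=lambda k: (dist[k], here[k].start, here[k].name))
    best = here[order[0]]
    return SnpAnnotation(snp_id, best.name, float(dist[order[0]]), "intergenic")


def annotate_table(table: pd.DataFrame, genes: list[GeneInterval]) -> pd.DataFrame:
    """Annotate every row of a SNP table (columns snp_id, chrom, pos)."""
    rows = []
    for r in table.itertuples(index=False):
        ann = annotate_snp(int(r.pos), str(r.chrom), genes, str(r.snp_id))
        rows.append({
            "snp_id": ann.snp_id, "chrom": r.chrom, "pos": r.pos,
            "gene": ann.gene, "distance": ann.distance,
            "label": ann.label, "sub_label": ann.sub_label,
        })
    return pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "pos", "gene", "distance", "label", "sub_label",
    ])


def summarize_labels(annotations: pd.DataFrame) -> pd.Series:
    """Tally annotations by label (sub-label where present, else label)."""
    if annotations.empty:
        return pd.Series(dtype=np.int64)
    key = annotations["sub_label"].where(annotations["sub_label"] != "", annotations["label"])
    return key.value_counts().sort_index()
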