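"""Model/results interface for the selection scan.

:class:`SelectionScan` is built from phased, polarized haplotypes plus a
marker map (or straight from a phased VCF and ancestral-allele table);
``fit()`` runs the EHH/iHS scan and returns a
:class:`SelectionScanResults` carrying the per-SNP table, the
standardization bins, significance calls, and methods for window
aggregation, candidate-region delineation, within-region LD, gene
annotation and plotting.

    >>> scan = SelectionScan(hap, mmap, maf_min=0.05)
    >>> res = scan.fit()
    >>> print(res.summary())
    >>> res.candidate_regions()
"""

from __future__ import annotations

import pandas as pd

from . import ehh as _ehh
from . import ld as _ld
from . import regions as _regions
from .annotate import annotate_table
from .formats import HaplotypeMatrix, MarkerMap

__all__ = ["SelectionScan", "SelectionScanResults"]


class SelectionScan:
    """iHS selection-signature scan on phased, ancestrally polarized haplotypes.

    Parameters
    ----------
    haplotypes, marker_map
        Phased binary haplotypes (0 = ancestral after polarization) and
        the matching marker map. SNPs with unknown ancestral state are
        skipped.
    maf_min
        Minimum minor-allele frequency for a SNP to enter the scan
        (default 0.05: near-fixed alleles reflect background ancestry,
        not recent selection).
    trunc_ehh, max_extension, max_gap, min_carriers, censor_chromosome_ends
        EHH profile controls; see :mod:`haploscan.ehh`.
    n_bins, min_bin_n, standardization
        iHS standardization: equal-width derived-frequency bins
        (default 20) or ``"global"`` for a single bin.
    """

    def __init__(
        self,
        haplotypes: HaplotypeMatrix,
        marker_map: MarkerMap,
        *,
        maf_min: float = 0.05,
        trunc_ehh: float = 0.05,
        max_extension: int = 2_000_000,
        max_gap: int = 200_000,
        min_carriers: int = 4,
        censor_chromosome_ends: bool = True,
        n_bins: int = 20,
        min_bin_n: int = 10,
        standardization: str = "binned",
        sig_config: _regions.SignificanceConfig | None = None,
    ):
        if haplotypes.n_snps != len(marker_map):
            raise ValueError("haplotype and marker-map SNP counts differ")
        self.haplotypes = haplotypes
        self.marker_map = marker_map
        self.config = {
            "maf_min": maf_min, "trunc_ehh": trunc_ehh,
            "max_extension": max_extension, "max_gap": max_gap,
            "min_carriers": min_carriers,
            "censor_chromosome_ends": censor_chromosome_ends,
            "n_bins": n_bins, "min_bin_n": min_bin_n,
            "standardization": standardization,
        }
        self.sig_config = sig_config or _regions.SignificanceConfig()

    @classmethod
    def from_vcf(cls, path, ancestral_table=None, **kwargs) -> "SelectionScan":
        """Build a scan from a phased VCF and (optionally) an ancestral table.

        ``ancestral_table`` is a path to the 3-column TSV or a DataFrame;
        without it REF is taken as ancestral for every SNP (only
        appropriate when the VCF was written that way).
        """
        from .formats import read_ancestral_table, read_phased_vcf, set_ancestral

        hap, mmap, _ = read_phased_vcf(path)
        if ancestral_table is not None:
            if not isinstance(ancestral_table, pd.DataFrame):
                ancestral_table = read_ancestral_table(ancestral_table)
            hap, mmap = set_ancestral(hap, mmap, ancestral_table)
        else:
            mmap.df["ancestral"] = "ref"
        return cls(hap, mmap, **kwargs)

    def fit(self) -> "SelectionScanResults":
        """Run the scan: per-SNP iHH/u, standardization, piHS, significance."""
        table, bins = _ehh.scan_ihs(self.haplotypes, self.marker_map, **self.config)
        table = _regions.call_significant(table, self.sig_config)
        table = _regions.assign_windows(table, self.sig_config)
        return SelectionScanResults(self, table, bins)


class SelectionScanResults:
    """Results of a fitted :class:`SelectionScan`."""

    def __init__(self, model: SelectionScan, table: pd.DataFrame, bins: _ehh.StandardizationBins):
        self.model = model
        self.table = table
        self.bins = bins

    # -- convenience views ---------------------------------------------------

    @property
    def n_scanned(self) -> int:
        return len(self.table)

    @property
    def n_valid(self) -> int:
        return int(self.table["valid"].sum()) if len(self.table) else 0

    def significant(self, tier: str = "1e5") -> pd.DataFrame:
        """Rows passing the primary (``"1e5"``) or secondary (``"1e4"``) tier."""
        col = {"1e5": "significant_1e5", "1e4": "significant_1e4"}[tier]
        return self.table[self.table[col]]

    def window_stats(self) -> pd.DataFrame:
        return _regions.window_stats(self.table, self.model.sig_config)

    def candidate_regions(self) -> pd.DataFrame:
        return _regions.candidate_regions(self.table, self.model.sig_config)

    def region_ld(self, region, max_pairs: int = 100_000, seed: int = 0):
        """Mean r^2 inside one candidate region (row of ``candidate_regions()``)."""
        return _ld.region_mean_r2(
            self.model.haplotypes, self.model.marker_map,
            str(region["chrom"]), int(region["first_sig_pos"]),
            int(region["last_sig_pos"]), max_pairs=max_pairs, seed=seed,
        )

    def annotate(self, genes) -> pd.DataFrame:
        """Nearest-gene annotation of the primary-significant SNPs."""
        return annotate_table(self.significant(), genes)

    def plot(self, ax=None, kind: str = "pihs"):
        from .plotting import plot_scores

        return plot_scores(self.table, ax=ax, kind=kind,
                           sig_line=self.model.sig_config.pihs_primary)

    # -- summary -------------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary in the spirit of a model-results table."""
        cfg = self.model.config
        sig = self.significant()
        regions = self.candidate_regions()
        lines = [
            "Selection-signature scan (iHS)",
            "=" * 46,
            f"haplotypes:          {self.model.haplotypes.n_haplotypes} "
            f"({self.model.haplotypes.n_samples} diploids)",
            f"SNPs in map:         {len(self.model.marker_map)}",
            f"SNPs scanned (MAF >= {cfg['maf_min']:g}): {self.n_scanned}",
            f"valid iHS:           {self.n_valid}",
            f"standardization:     {cfg['standardization']} "
            f"({int(self.bins.usable.sum())} usable bins)",
            f"piHS >= {self.model.sig_config.pihs_primary:g} (P < 1e-5): {len(sig)} SNPs",
            f"piHS >= {self.model.sig_config.pihs_secondary:g} (P < 1e-4): "
            f"{len(self.significant('1e4'))} SNPs",
            f"candidate regions:   {len(regions)}",
        ]
        if len(sig):
            per_chrom = sig.groupby("chrom", sort=True).size()
            lines.append("significant SNPs per chromosome: "
                         + ", ".join(f"{c}: {n}" for c, n in per_chrom.items()))
        if len(regions):
            lines.append("-" * 46)
            lines.append("regions (chrom, window, first..last, span bp, n):")
            for r in regions.itertuples(index=False):
                lines.append(f"  {r.chrom}  w{r.window_id}  "
                             f"{r.first_sig_pos:,}..{r.last_sig_pos:,}  "
                             f"{r.span_bp:,}  {r.n_sig_snps}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<SelectionScanResults: {self.n_scanned} SNPs scanned, "
                f"{len(self.significant())} significant>")
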