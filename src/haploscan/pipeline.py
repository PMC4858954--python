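"""End-to-end pipeline: simulate/read -> polarize -> QC -> scan -> regions -> LD.

Deterministic given config + seed: a single integer seed drives named
substreams for simulation and LD pair subsampling, outputs carry no
timestamps, and re-running the same config writes byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .formats import (
    MarkerMap,
    read_ancestral_table,
    read_phased_vcf,
    set_ancestral,
    write_regions_bed,
    write_results,
)
from .ld import region_mean_r2
from .model import SelectionScan
from .qc import drop_fixed
from .regions import SignificanceConfig
from .synthetic import SimParams, simulate

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every pipeline threshold, with conventional defaults.

    Round-trips unchanged through YAML (``to_yaml``/``from_yaml``).
    """

    # inputs: either a phased VCF (+ ancestral table) or a simulation
    vcf: str | None = None
    ancestral: str | None = None
    simulate: dict | None = None     # SimParams fields; seed is overridden below

    # genotype QC thresholds
    call_score_min: float = 0.20
    snp_call_rate: float = 0.95
    sample_call_rate: float = 0.90
    qc_maf_min: float = 0.01

    # scan
    ihs_maf_min: float = 0.05
    trunc_ehh: float = 0.05
    max_extension: int = 2_000_000
    max_gap: int = 200_000
    min_carriers: int = 4
    censor_chromosome_ends: bool = True
    n_bins: int = 20
    min_bin_n: int = 10
    standardization: str = "binned"

    # significance / regions
    pihs_primary: float = 5.0
    pihs_secondary: float = 4.0
    window_size: int = 500_000

    # LD
    ld_max_pairs: int = 100_000

    # run control
    seed: int = 0
    out_prefix: str = "haploscan_run"
    genes: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _config_hash(cfg: PipelineConfig) -> str:
    fields = asdict(cfg)
    fields.pop("out_prefix")  # output location is not part of the run identity
    return hashlib.sha256(
        json.dumps(fields, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> dict:
    """Run all stages; returns a bundle dict and (optionally) writes artifacts.

    Bundle keys: ``table`` (iHS table), ``regions``, ``window_stats``,
    ``ld`` (per-region mean r^2), ``annotations`` (when genes given),
    ``manifest`` (config hash, per-stage counts), ``truth`` (simulation
    only). Any stage error propagates wrapped with the stage name.
    """
    manifest: dict = {"haploscan_version": __version__, "config_hash": _config_hash(cfg),
                      "seed": cfg.seed, "stages": {}}
    truth = None

    # --- input stage
    try:
        if cfg.simulate is not None:
            params = SimParams(**{**cfg.simulate, "seed": cfg.seed})
            hap, mmap, truth = simulate(params)
        elif cfg.vcf is not None:
            hap, mmap, _ = read_phased_vcf(cfg.vcf)
            if cfg.ancestral is not None:
                hap, mmap = set_ancestral(hap, mmap, read_ancestral_table(cfg.ancestral))
            else:
                mmap.df["ancestral"] = "ref"
        else:
            raise ValueError("config must give either 'vcf' or 'simulate'")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed: {exc}") from exc
    manifest["stages"]["input"] = {"snps": hap.n_snps, "samples": hap.n_samples}

    # --- fixed-allele exclusion (haplotype stage, just before the scan)
    hap, mmap, n_fixed = drop_fixed(hap, mmap)
    manifest["stages"]["drop_fixed"] = {"removed": n_fixed, "snps": hap.n_snps}

    # --- scan
    try:
        scan = SelectionScan(
            hap, mmap,
            maf_min=cfg.ihs_maf_min, trunc_ehh=cfg.trunc_ehh,
            max_extension=cfg.max_extension, max_gap=cfg.max_gap,
            min_carriers=cfg.min_carriers,
            censor_chromosome_ends=cfg.censor_chromosome_ends, n_bins=cfg.n_bins,
            min_bin_n=cfg.min_bin_n, standardization=cfg.standardization,
            sig_config=SignificanceConfig(cfg.pihs_primary, cfg.pihs_secondary,
                                          cfg.window_size),
        )
        res = scan.fit()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'scan' failed: {exc}") from exc
    table = res.table
    regions = res.candidate_regions()
    windows = res.window_stats()
    manifest["stages"]["scan"] = {
        "scanned": res.n_scanned, "valid": res.n_valid,
        "significant_1e5": int(table["significant_1e5"].sum()) if len(table) else 0,
        "significant_1e4": int(table["significant_1e4"].sum()) if len(table) else 0,
    }
    manifest["stages"]["regions"] = {"n_regions": len(regions),
                                     "sig_snps_in_regions": int(regions["n_sig_snps"].sum())
                                     if len(regions) else 0}

    # --- LD within regions
    ld_rows = []
    for _, region in regions.iterrows():
        try:
            mean_r2, n_pairs, skipped = res.region_ld(
                region, max_pairs=cfg.ld_max_pairs, seed=cfg.seed,
            )
        except ValueError:
            mean_r2, n_pairs, skipped = np.nan, 0, 0
        ld_rows.append({"chrom": region["chrom"], "window_id": region["window_id"],
                        "mean_r2": mean_r2, "n_pairs": n_pairs, "n_skipped": skipped})
    ld_table = pd.DataFrame(ld_rows, columns=["chrom", "window_id", "mean_r2",
                                              "n_pairs", "n_skipped"])
    manifest["stages"]["ld"] = {"regions_with_ld": int(ld_table["mean_r2"].notna().sum())}

    # --- gene annotation
    annotations = None
    if cfg.genes is not None:
        from .annotate import annotate_table
        from .formats import read_gene_intervals

        genes = read_gene_intervals(cfg.genes)
        annotations = annotate_table(res.significant(), genes)
        manifest["stages"]["annotate"] = {"annotated": len(annotations)}

    bundle = {"table": table, "regions": regions, "window_stats": windows,
              "ld": ld_table, "annotations": annotations,
              "manifest": manifest, "truth": truth, "results": res}

    if write:
        prefix = cfg.out_prefix
        out_cols = [c for c in ["snp_id", "chrom", "pos", "derived_freq", "ihs", "pihs",
                                "significant_1e5", "significant_1e4", "window_id"]
                    if c in table.columns]
        write_results(table[out_cols], f"{prefix}.ihs.tsv")
        write_results(regions, f"{prefix}.regions.tsv")
        write_results(windows, f"{prefix}.windows.tsv")
        write_results(ld_table, f"{prefix}.ld.tsv")
        write_regions_bed(regions, f"{prefix}.regions.bed")
        if annotations is not None:
            write_results(annotations, f"{prefix}.annotations.tsv")
        with open(f"{prefix}.manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return bundle
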