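"""Extended haplotype homozygosity (EHH), integrated EHH (iHH) and iHS.

EHH at a test SNP, for the haplotypes carrying a given core allele, is the
probability that two randomly chosen carriers are identical at every SNP
between the core and the test SNP (inclusive):

    EHH = sum_h c_h (c_h - 1) / (n_c (n_c - 1))

where the c_h are the sizes of the exact-identity haplotype groups among
the n_c carriers. At the core itself EHH = 1, and extending the interval
can only split groups, so EHH is non-increasing with distance -- the decay
rate reflects local recombination and haplotype age. Recent positive
selection leaves unusually slow decay around the selected allele.

iHH is the area under the EHH decay curve against physical distance
(trapezoid rule, both flanks summed). The unstandardized score at a SNP is

    u = ln(iHH_A / iHH_D)

contrasting ancestral (A) and derived (D) core alleles, and iHS is u
standardized to zero mean and unit variance -- by default within
derived-allele-frequency bins, so that scores are comparable across SNPs
regardless of allele frequency. Large negative iHS marks unusually long
haplotypes around a derived allele; large positive iHS around an
ancestral allele.

The profile extension is the hot loop of a scan and is compiled with
numba; groups that have decayed to singletons are dropped from the active
set (they can never rejoin), which keeps long extensions cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .formats import HaplotypeMatrix, MarkerMap

__all__ = [
    "EHHProfile",
    "IHSRecord",
    "StandardizationBins",
    "ehh_at",
    "ehh_profile",
    "ihh",
    "unstandardized_ihs",
    "standardize",
    "scan_ihs",
]

# truncation reason codes shared with the numba kernel
_BELOW, _CHROM_END, _MAX_EXT, _MAX_GAP = 0, 1, 2, 3
TRUNCATION_REASONS = {
    _BELOW: "below_threshold",
    _CHROM_END: "chromosome_end",
    _MAX_EXT: "max_extension",
    _MAX_GAP: "max_gap",
}

ANCESTRAL, DERIVED = 0, 1
_ALLELE_CODE = {"ancestral": ANCESTRAL, "derived": DERIVED, 0: ANCESTRAL, 1: DERIVED}


@njit(cache=True)
def _ehh_side(hap, positions, carriers, core, direction, trunc_ehh, max_extension, max_gap):
    """Extend identity groups SNP-by-SNP on one side of the core.

    Returns (ehh values, snp indices, truncation reason code). Only points
    with EHH >= trunc_ehh are recorded; the first point below the
    threshold terminates the side and is not recorded.
    """
    n_c = carriers.shape[0]
    denom = n_c * (n_c - 1)
    n_snps = positions.shape[0]
    ehh_out = np.empty(n_snps, np.float64)
    idx_out = np.empty(n_snps, np.int64)
    n_out = 0

    act = carriers.copy()          # members of non-singleton groups, contiguous
    gstart = np.empty(n_c + 1, np.int64)
    gstart[0] = 0
    gstart[1] = n_c
    n_groups = 1
    buf = np.empty(n_c, np.int64)
    new_gstart = np.empty(n_c + 1, np.int64)

    j = core
    while True:
        jn = j + direction
        if jn < 0 or jn >= n_snps:
            return ehh_out[:n_out], idx_out[:n_out], _CHROM_END
        gap = positions[jn] - positions[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            return ehh_out[:n_out], idx_out[:n_out], _MAX_GAP
        dist = positions[jn] - positions[core]
        if dist < 0:
            dist = -dist
        if dist > max_extension:
            return ehh_out[:n_out], idx_out[:n_out], _MAX_EXT

        pairs = 0
        w = 0
        ng = 0
        new_gstart[0] = 0
        for g in range(n_groups):
            a = gstart[g]
            b = gstart[g + 1]
            c0 = 0
            for t in range(a, b):
                if hap[act[t], jn] == 0:
                    c0 += 1
            c1 = (b - a) - c0
            if c0 >= 2:
                for t in range(a, b):
                    if hap[act[t], jn] == 0:
                        buf[w] = act[t]
                        w += 1
                ng += 1
                new_gstart[ng] = w
                pairs += c0 * (c0 - 1)
            if c1 >= 2:
                for t in range(a, b):
                    if hap[act[t], jn] != 0:
                        buf[w] = act[t]
                        w += 1
                ng += 1
                new_gstart[ng] = w
                pairs += c1 * (c1 - 1)
        ehh = pairs / denom
        if ehh < trunc_ehh:
            return ehh_out[:n_out], idx_out[:n_out], _BELOW
        for t in range(w):
            act[t] = buf[t]
        for g in range(ng + 1):
            gstart[g] = new_gstart[g]
        n_groups = ng
        ehh_out[n_out] = ehh
        idx_out[n_out] = jn
        n_out += 1
        j = jn


@dataclass
class EHHProfile:
    """EHH decay away from a core SNP for one core allele.

    ``left``/``right`` are (distance bp, EHH) arrays ordered by increasing
    distance from the core, excluding the core itself (which has EHH = 1
    at distance 0 by definition).
    """

    core: int
    allele: int                 # 0 = ancestral, 1 = derived
    n_carriers: int
    left: np.ndarray            # shape (k, 2): distance bp, EHH
    right: np.ndarray
    left_reason: str
    right_reason: str

    def side_points(self, side: str) -> np.ndarray:
        """Points on one side including the core anchor (0, 1.0)."""
        arr = self.left if side == "left" else self.right
        return np.vstack([np.array([[0.0, 1.0]]), arr]) if arr.size else np.array([[0.0, 1.0]])

    @property
    def edge_censored(self) -> bool:
        """True when a flank hit the chromosome end with EHH still above threshold."""
        return self.left_reason == "chromosome_end" or self.right_reason == "chromosome_end"


def _carriers(hap: HaplotypeMatrix, core: int, allele) -> np.ndarray:
    code = _ALLELE_CODE[allele]
    return np.nonzero(hap.values[:, core] == code)[0].astype(np.int64)


def ehh_at(hap: HaplotypeMatrix, core: int, allele, target: int) -> float:
    """EHH of ``allele`` at ``core`` measured at ``target``.

    Groups the carriers by exact identity over the inclusive SNP interval
    between core and target. Requires at least two carriers.
    """
    carriers = _carriers(hap, core, allele)
    n_c = carriers.size
    if n_c < 2:
        raise ValueError(f"core allele has {n_c} carriers; EHH needs >= 2")
    lo, hi = min(core, target), max(core, target)
    sub = hap.values[np.ix_(carriers, np.arange(lo, hi + 1))]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n_c * (n_c - 1)))


def ehh_profile(
    hap: HaplotypeMatrix,
    mmap: MarkerMap,
    core: int,
    allele,
    trunc_ehh: float = 0.05,
    max_extension: int = 2_000_000,
    max_gap: int = 200_000,
) -> EHHProfile:
    """Full EHH decay profile for one core allele, both flanks.

    Extension stops on a side when EHH drops below ``trunc_ehh``, the
    chromosome ends, the distance from the core exceeds ``max_extension``,
    or an inter-SNP gap exceeds ``max_gap``; the reason is recorded.
    """
    carriers = _carriers(hap, core, allele)
    if carriers.size < 2:
        raise ValueError(f"core allele has {carriers.size} carriers; EHH needs >= 2")
    pos = np.ascontiguousarray(mmap.pos, dtype=np.int64)
    sides = {}
    reasons = {}
    for name, direction in (("left", -1), ("right", 1)):
        vals, idx, code = _ehh_side(
            hap.values, pos, carriers, core, direction,
            float(trunc_ehh), float(max_extension), float(max_gap),
        )
        dist = np.abs(pos[idx] - pos[core]).astype(np.float64)
        sides[name] = np.column_stack([dist, vals]) if vals.size else np.empty((0, 2))
        reasons[name] = TRUNCATION_REASONS[int(code)]
    return EHHProfile(
        core=core, allele=_ALLELE_CODE[allele], n_carriers=int(carriers.size),
        left=sides["left"], right=sides["right"],
        left_reason=reasons["left"], right_reason=reasons["right"],
    )


def ihh(profile: EHHProfile) -> float:
    """Integrated EHH: trapezoid area against bp distance, both flanks summed.

    The core contributes EHH = 1 at distance 0 on each side. A side
    truncated below the threshold integrates only down to its last
    recorded point (the last with EHH >= trunc_ehh).
    """
    total = 0.0
    for side in ("left", "right"):
        pts = profile.side_points(side)
        total += float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return total


@dataclass
class IHSRecord:
    """Per-SNP unstandardized iHS ingredients and validity."""

    snp: int
    ihh_a: float
    ihh_d: float
    u: float                    # ln(iHH_A / iHH_D)
    derived_freq: float
    ihs: float = np.nan
    valid: bool = True
    reason: str = ""


def unstandardized_ihs(
    hap: HaplotypeMatrix,
    mmap: MarkerMap,
    snp: int,
    trunc_ehh: float = 0.05,
    max_extension: int = 2_000_000,
    max_gap: int = 200_000,
    min_carriers: int = 4,
    censor_chromosome_ends: bool = True,
) -> IHSRecord:
    """u = ln(iHH_A / iHH_D) at one SNP, or an invalid record with a reason.

    Invalid (never an exception): a carrier class below ``min_carriers``,
    a flank censored at the chromosome end (when
    ``censor_chromosome_ends``), or a zero iHH on either side.
    """
    col = hap.values[:, snp]
    freq = float(col.mean())
    n_d = int(col.sum())
    n_a = col.size - n_d
    if min(n_a, n_d) < min_carriers:
        return IHSRecord(snp, np.nan, np.nan, np.nan, freq, valid=False, reason="few_carriers")
    prof_a = ehh_profile(hap, mmap, snp, ANCESTRAL, trunc_ehh, max_extension, max_gap)
    prof_d = ehh_profile(hap, mmap, snp, DERIVED, trunc_ehh, max_extension, max_gap)
    if censor_chromosome_ends and (prof_a.edge_censored or prof_d.edge_censored):
        return IHSRecord(snp, np.nan, np.nan, np.nan, freq, valid=False, reason="edge_censored")
    ihh_a = ihh(prof_a)
    ihh_d = ihh(prof_d)
    if ihh_a <= 0 or ihh_d <= 0:
        return IHSRecord(snp, ihh_a, ihh_d, np.nan, freq, valid=False, reason="zero_ihh")
    return IHSRecord(snp, ihh_a, ihh_d, float(np.log(ihh_a / ihh_d)), freq)


@dataclass
class StandardizationBins:
    """Frequency-bin moments used to standardize u into iHS."""

    edges: np.ndarray           # len n_bins + 1, on derived_freq
    mean: np.ndarray            # per-bin E[u] (NaN where unusable)
    sd: np.ndarray              # per-bin SD[u] (population sd, ddof=0)
    count: np.ndarray
    usable: np.ndarray          # bool per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.edges[:-1], "bin_high": self.edges[1:],
            "n": self.count, "mean_u": self.mean, "sd_u": self.sd,
            "usable": self.usable,
        })


def standardize(
    table: pd.DataFrame,
    n_bins: int = 20,
    min_bin_n: int = 10,
    mode: str = "binned",
) -> tuple[pd.DataFrame, StandardizationBins]:
    """Standardize u to iHS: (u - E[u]) / SD[u] within derived-frequency bins.

    ``mode="binned"`` (default) uses ``n_bins`` equal-width bins on
    derived_freq in [0, 1]; bins with fewer than ``min_bin_n`` valid SNPs
    or zero spread are unusable and their SNPs are marked invalid.
    ``mode="global"`` uses a single bin over all valid SNPs.
    """
    table = table.copy()
    if mode == "global":
        n_bins = 1
    elif mode != "binned":
        raise ValueError(f"unknown standardization mode {mode!r}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    valid = table["valid"].to_numpy(dtype=bool) & np.isfinite(table["u"].to_numpy(dtype=float))
    freq = table["derived_freq"].to_numpy(dtype=float)
    u = table["u"].to_numpy(dtype=float)
    which = np.clip(np.digitize(freq, edges[1:-1]), 0, n_bins - 1)

    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=np.int64)
    usable = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        sel = valid & (which == b)
        count[b] = sel.sum()
        if count[b] >= max(min_bin_n, 2):
            m = u[sel].mean()
            s = u[sel].std(ddof=0)
            if s > 0:
                mean[b], sd[b] = m, s
                usable[b] = True

    ihs = np.full(len(table), np.nan)
    ok = valid & usable[which]
    ihs[ok] = (u[ok] - mean[which[ok]]) / sd[which[ok]]
    table["ihs"] = ihs
    newly_bad = valid & ~ok
    table.loc[newly_bad, "valid"] = False
    table.loc[newly_bad, "reason"] = "unusable_bin"
    bins = StandardizationBins(edges, mean, sd, count, usable)
    return table, bins


def scan_ihs(
    hap: HaplotypeMatrix,
    mmap: MarkerMap,
    maf_min: float = 0.05,
    trunc_ehh: float = 0.05,
    max_extension: int = 2_000_000,
    max_gap: int = 200_000,
    min_carriers: int = 4,
    censor_chromosome_ends: bool = True,
    n_bins: int = 20,
    min_bin_n: int = 10,
    standardization: str = "binned",
) -> tuple[pd.DataFrame, StandardizationBins]:
    """Genome scan: u at every polarized SNP with MAF >= ``maf_min``,
    standardized within that analysis set.

    Returns the iHS table (one row per scanned SNP) and the
    standardization bins. SNPs with unknown ancestral state or MAF below
    the cutoff are absent from the table.
    """
    freq = hap.derived_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_min) & mmap.ancestral_known
    idx = np.nonzero(keep)[0]
    rows = []
    for snp in idx:
        rec = unstandardized_ihs(
            hap, mmap, int(snp), trunc_ehh, max_extension, max_gap,
            min_carriers, censor_chromosome_ends,
        )
        rows.append({
            "snp_index": rec.snp,
            "snp_id": mmap.df.at[rec.snp, "snp_id"],
            "chrom": mmap.df.at[rec.snp, "chrom"],
            "pos": int(mmap.df.at[rec.snp, "pos"]),
            "derived_freq": rec.derived_freq,
            "ihh_a": rec.ihh_a,
            "ihh_d": rec.ihh_d,
            "u": rec.u,
            "valid": rec.valid,
            "reason": rec.reason,
        })
    table = pd.DataFrame(rows, columns=[
        "snp_index", "snp_id", "chrom", "pos", "derived_freq",
        "ihh_a", "ihh_d", "u", "valid", "reason",
    ])
    if table.empty:
        table["ihs"] = pd.Series(dtype=float)
        return table, StandardizationBins(
            np.linspace(0, 1, n_bins + 1), np.full(n_bins, np.nan),
            np.full(n_bins, np.nan), np.zeros(n_bins, dtype=np.int64),
            np.zeros(n_bins, dtype=bool),
        )
    return standardize(table, n_bins=n_bins, min_bin_n=min_bin_n, mode=standardization)
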