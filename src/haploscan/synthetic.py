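"""Forward Wright-Fisher sweep simulator and genotyping-noise layer.

Generates every input the scan pipeline consumes: phased, ancestrally
polarized haplotypes for a few hundred diploids at dense biallelic SNPs,
with an optional additive selective sweep at a focal site and a
genotype-observation layer (call scores, missingness) to exercise QC.

The model is deliberately simple: a single chromosome, standing variation
drawn from a neutral 1/x frequency spectrum, no new mutation during the
simulated generations, additive fitness (1, 1+s, 1+2s by focal-site
genotype) and crossovers placed uniformly with a per-bp, per-generation
probability. Allele 0 is ancestral by construction, so the simulator's
truth is directly comparable with what the EHH/iHS scan infers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix, HaplotypeMatrix, MarkerMap

__all__ = ["SimParams", "SweepTruth", "simulate", "add_observation_noise", "write_simulation"]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one forward simulation.

    Defaults are sized to a composite-cattle study design: ~400 genotyped
    diploids on a dense SNP chip, a 5-Mb chromosome with 5,000 segregating
    sites and a human-scale recombination rate of 1e-8 per bp per
    generation. ``G`` defaults to 100 generations, which takes an additive
    sweep with ``s = 0.05`` from 5 % to roughly 90 % derived frequency --
    the regime where haplotype-contrast statistics are most powerful.
    """

    N: int = 500                 # diploid population size
    L: int = 5_000_000           # chromosome length, bp
    n_snps: int = 5_000          # segregating sites
    rec_rate: float = 1e-8      # per-bp per-generation crossover probability
    s: float = 0.0              # additive selection coefficient at focal site
    focal_pos: int | None = None  # bp; default mid-chromosome
    f0: float = 0.05            # initial derived frequency at focal site
    G: int = 100                # generations simulated
    n_sample: int = 396         # diploids sampled at the end
    seed: int = 0
    sfs_min: float | None = None  # truncation of the 1/x SFS; default 1/(2N)
    resample_lost: bool = True   # restart (seed+1) if a selected allele is lost
    max_restarts: int = 20
    focal_ibd_flank: float | None = None  # bp; mean IBD flank around a selected
    # standing variant (None = neutral-age default when s > 0; 0 disables)

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 < self.f0 < 1:
            raise ValueError("f0 must be in (0, 1)")
        if self.n_sample > self.N:
            raise ValueError("n_sample cannot exceed N")
        if self.rec_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_snps > self.L:
            raise ValueError("n_snps cannot exceed L (distinct bp positions)")


@dataclass
class SweepTruth:
    """Simulator ground truth for downstream power checks."""

    focal_index: int
    focal_pos: int
    s: float
    trajectory: np.ndarray  # derived-frequency per generation, length G+1
    n_restarts: int = 0

    @property
    def final_freq(self) -> float:
        return float(self.trajectory[-1])


def _init_population(params: SimParams, rng: np.random.Generator):
    """Standing variation: positions uniform, frequencies from a truncated 1/x SFS."""
    two_n = 2 * params.N
    pos = np.sort(rng.choice(params.L, size=params.n_snps, replace=False)) + 1
    focal_pos = params.focal_pos if params.focal_pos is not None else params.L // 2
    focal = int(np.searchsorted(pos, focal_pos))
    if focal == params.n_snps:
        focal -= 1
    pos[focal] = focal_pos
    # keep positions strictly increasing after planting the focal site
    if (focal > 0 and pos[focal] <= pos[focal - 1]) or (
        focal < params.n_snps - 1 and pos[focal] >= pos[focal + 1]
    ):
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        focal = int(np.nonzero(pos == focal_pos)[0][0])

    lo = params.sfs_min if params.sfs_min is not None else 1.0 / two_n
    hi = 1.0 - lo
    # density prop. to 1/x on [lo, hi]: inverse-CDF sampling
    u = rng.random(params.n_snps)
    freqs = lo * (hi / lo) ** u
    haps = (rng.random((two_n, params.n_snps)) < freqs).astype(np.int8)
    # plant the focal derived allele at exactly round(2N * f0) copies
    k = max(1, int(round(two_n * params.f0)))
    col = np.zeros(two_n, dtype=np.int8)
    carriers = rng.choice(two_n, size=k, replace=False)
    col[carriers] = 1
    haps[:, focal] = col

    # A selected standing variant is a single mutation: its carriers are
    # identical by descent around the focal site. Plant a shared core
    # segment with per-carrier exponential flanks whose mean reflects the
    # neutral age of an allele at frequency f0 (age ~ -4N f0 ln f0 / (1-f0)
    # generations, flank scale 1/(rec_rate * age)).
    flank = params.focal_ibd_flank
    if flank is None and params.s > 0:
        age = -4.0 * params.N * params.f0 * np.log(params.f0) / (1.0 - params.f0)
        flank = 1.0 / max(params.rec_rate * age, 1.0 / params.L)
    if flank:
        template = haps[carriers[0]].copy()
        left = rng.exponential(flank, size=k)
        right = rng.exponential(flank, size=k)
        focal_bp = pos[focal]
        for t, c in enumerate(carriers):
            lo = np.searchsorted(pos, focal_bp - left[t], side="left")
            hi = np.searchsorted(pos, focal_bp + right[t], side="right")
            haps[c, lo:hi] = template[lo:hi]
        haps[:, focal] = col  # template copy must not erase the allele itself
    return haps, pos, focal


def _next_generation(haps, pos, focal, params: SimParams, rng: np.random.Generator):
    """One Wright-Fisher generation: fitness-weighted parents, recombinant gametes."""
    two_n = haps.shape[0]
    n = params.N
    dosage = haps[0::2, focal].astype(np.float64) + haps[1::2, focal]
    w = 1.0 + params.s * dosage
    p = w / w.sum()
    parents = rng.choice(n, size=two_n, replace=True, p=p)  # one parent per gamete
    start = rng.integers(0, 2, size=two_n)
    n_cross = rng.binomial(params.L - 1, params.rec_rate, size=two_n)
    out = np.empty_like(haps)
    plain = n_cross == 0
    out[plain] = haps[2 * parents[plain] + start[plain]]
    for g in np.nonzero(~plain)[0]:
        cuts = np.sort(rng.integers(1, params.L, size=n_cross[g]))
        # source haplotype switches at each cut; parity of cuts left of a marker
        phase = (start[g] + np.searchsorted(cuts, pos, side="right")) % 2
        p0 = haps[2 * parents[g]]
        p1 = haps[2 * parents[g] + 1]
        out[g] = np.where(phase == 0, p0, p1)
    return out


def simulate(params: SimParams) -> tuple[HaplotypeMatrix, MarkerMap, SweepTruth]:
    """Run a forward simulation; returns sampled haplotypes, map and truth.

    The returned haplotypes are already polarized (allele 0 = ancestral)
    and the marker map has ``ancestral = "ref"`` throughout, with
    derived-allele frequencies of the *sampled* haplotypes. Columns fixed
    in the sample are retained (QC removes them downstream). The
    simulation is a pure function of ``params``: the same seed gives
    bit-identical output.
    """
    n_restarts = 0
    seed = params.seed
    while True:
        rng = np.random.default_rng(seed)
        haps, pos, focal = _init_population(params, rng)
        traj = np.empty(params.G + 1)
        traj[0] = haps[:, focal].mean()
        for g in range(params.G):
            haps = _next_generation(haps, pos, focal, params, rng)
            traj[g + 1] = haps[:, focal].mean()
        if params.s > 0 and params.resample_lost and traj[-1] == 0.0:
            n_restarts += 1
            if n_restarts > params.max_restarts:
                raise RuntimeError("selected allele lost in every restart")
            seed += 1
            continue
        break

    chosen = np.sort(rng.choice(params.N, size=params.n_sample, replace=False))
    rows = np.repeat(chosen * 2, 2)
    rows[1::2] += 1
    sampled = haps[rows]
    hap = HaplotypeMatrix(sampled, [f"S{i + 1}" for i in range(params.n_sample)])

    freq = hap.derived_freq()
    df = pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(params.n_snps)],
        "chrom": "1",
        "pos": pos,
        "ref_allele": "A",
        "alt_allele": "G",
        "ancestral": "ref",
        "derived_freq": freq,
        "maf": np.minimum(freq, 1.0 - freq),
    })
    truth = SweepTruth(focal_index=focal, focal_pos=int(pos[focal]),
                       s=params.s, trajectory=traj, n_restarts=n_restarts)
    return hap, MarkerMap(df, validate=False), truth


def add_observation_noise(
    hap: HaplotypeMatrix,
    miss_rate: float = 0.0,
    low_score_frac: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Collapse haplotypes to diploid dosages with missingness and call scores.

    Entries go missing independently at ``miss_rate``. Call scores are
    uniform on [0.2, 1] except for a planted ``low_score_frac`` of entries
    uniform on [0, 0.2), i.e. below the conventional 0.20 reliability
    threshold, so QC masking has a known expected effect.
    """
    if not (0 <= miss_rate <= 1 and 0 <= low_score_frac <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = hap.to_dosage()
    if miss_rate > 0:
        mask = rng.random(dosage.shape) < miss_rate
        dosage = dosage.copy()
        dosage[mask] = np.nan
    scores = rng.uniform(0.2, 1.0, size=dosage.shape)
    if low_score_frac > 0:
        low = rng.random(dosage.shape) < low_score_frac
        scores[low] = rng.uniform(0.0, 0.2, size=int(low.sum()))
    return GenotypeMatrix(dosage, scores, hap.sample_ids)


def write_simulation(params: SimParams, prefix: str, scramble_ref: bool = True):
    """Simulate and write phased VCF, map TSV, ancestral table TSV, truth JSON.

    With ``scramble_ref`` (default), a random half of the SNPs are written
    with the derived allele as VCF REF, so that reading the VCF and
    re-polarizing from the ancestral table is a real exercise rather than
    an identity operation.
    """
    import json

    from .formats import write_phased_vcf

    hap, mmap, truth = simulate(params)
    df = mmap.df.copy()
    values = hap.values
    anc_allele = df["ref_allele"].to_numpy().copy()
    if scramble_ref:
        rng = np.random.default_rng(params.seed + 104729)
        flip = rng.random(len(df)) < 0.5
        ref = df["ref_allele"].to_numpy().copy()
        alt = df["alt_allele"].to_numpy().copy()
        ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
        df["ref_allele"], df["alt_allele"] = ref, alt
        df["ancestral"] = np.where(flip, "alt", "ref")
        values = values.copy()
        values[:, flip] = 1 - values[:, flip]  # re-express as REF-coded
        anc_allele = np.where(flip, df["alt_allele"], df["ref_allele"])
    out_hap = HaplotypeMatrix(values, hap.sample_ids)
    out_map = MarkerMap(df, validate=False)
    write_phased_vcf(out_hap, out_map, f"{prefix}.vcf")
    df.to_csv(f"{prefix}.map.tsv", sep="\t", index=False)
    pd.DataFrame({
        "snp_id": df["snp_id"],
        "chrom:pos": df["chrom"].astype(str) + ":" + df["pos"].astype(str),
        "ancestral_allele": anc_allele,
    }).to_csv(f"{prefix}.ancestral.tsv", sep="\t", index=False)
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump({
            "focal_index": truth.focal_index,
            "focal_pos": truth.focal_pos,
            "s": truth.s,
            "final_freq": truth.final_freq,
            "trajectory": truth.trajectory.tolist(),
            "n_restarts": truth.n_restarts,
        }, fh, indent=1, sort_keys=True)
    return hap, mmap, truth
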