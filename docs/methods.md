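# Methods

## The statistic

haploscan detects recent positive selection from phased, ancestrally
polarized SNP haplotypes using the integrated haplotype score (iHS),
derived from extended haplotype homozygosity (EHH).

For a core SNP and one of its alleles, EHH at a test SNP is the
probability that two randomly drawn carrier haplotypes are identical at
every SNP between core and test SNP (inclusive):

    EHH = sum_h c_h (c_h - 1) / (n_c (n_c - 1)),

where the `c_h` are the sizes of the exact-identity groups among the
`n_c` carriers. EHH equals 1 at the core and can only fall as the
interval grows (extending the interval only splits groups), so each
profile is monotone non-increasing on each flank — asserted as an
invariant in the test suite.

iHH is the area under the EHH decay curve against physical distance in
bp (trapezoid rule, both flanks summed, the core anchoring each flank at
EHH = 1, distance 0). The per-SNP unstandardized score is

    u = ln(iHH_A / iHH_D),

contrasting the ancestral (A) and derived (D) core alleles, and

    iHS = (u - E[u]) / SD[u]

standardized so that scores are comparable across allele frequencies.
Large negative iHS marks unusually long haplotypes around a derived
allele (the classic sweep-in-progress signature); large positive iHS
marks long haplotypes around an ancestral allele (hitchhiking of the
ancestral background).

Scores are mapped to a -log10 P-value scale via the two-sided standard
normal tail: piHS = -log10(2 Q(|iHS|)). The textbook form
`-log10(1 - 2|Phi - 0.5|)` underflows to infinity past |iHS| ~ 5.6 in
double precision — exactly the regime where genome-wide hits live — so
the implementation evaluates the tail in log space (`norm.logsf`),
accurate to |iHS| ~ 38. piHS >= 5 (P < 1e-5) is the primary significance
tier and piHS >= 4 (P < 1e-4) the secondary tier; no multiple-testing
correction is applied by default (a Bonferroni hook exists in
`SignificanceConfig`).

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `maf_min` | 0.05 | scan set: near-fixed alleles reflect background ancestry, not recent selection |
| `trunc_ehh` | 0.05 | EHH level below which a flank stops contributing; the conventional value in the EHH software family |
| `max_extension` | 2 Mb | cap on flank length, bounds runtime on high-LD regions |
| `max_gap` | 200 kb | inter-SNP gap that truncates a flank (sparse-region guard) |
| `min_carriers` | 4 | below this an allele class supports fewer than 6 pairs and EHH is noise |
| `censor_chromosome_ends` | True | a flank that hits the chromosome end with EHH still above threshold has unknowable missing area; strict mode invalidates the SNP |
| `n_bins`, `min_bin_n` | 20, 10 | equal-width derived-frequency bins for standardization; bins that are too small or have zero spread are unusable |
| window size | 500 kb | non-overlapping windows, `floor(pos / size)`, half-open |
| QC thresholds | score 0.20, SNP CR 0.95, sample CR 0.90, MAF 0.01 | conventional chip-QC cascade |

Standardization moments are population moments (ddof = 0), so per-bin
mean/SD of iHS are exactly 0/1 among valid SNPs. Binned standardization
is the default because a single global E and SD cannot make scores
comparable across allele frequencies (u depends strongly on derived
frequency); a `standardization="global"` mode is available.

### Design choices where the design was open

- **Edge censoring.** A flank truncated at `max_extension` or at a large
  gap still integrates the area it saw (the cap is a deliberate scan
  radius); only a flank stopped by the chromosome end with EHH above
  threshold invalidates the SNP in strict mode, because the missing area
  is unbounded. On short simulated chromosomes strict mode can discard
  most of the map (the EHH plateau of a small population stays above
  0.05 for megabases); the permissive mode
  (`censor_chromosome_ends=False`) is the recommended and documented
  setting there, and is what the simulation-based tests use.
- **Window anchoring.** Windows are `floor(pos / 500 kb)`, 0-based,
  half-open. Published window labels from other tools are not expected
  to be reproduced (different anchoring conventions disagree and no
  single convention reproduces all published labels); spans between
  first and last significant SNP are anchor-invariant for SNPs sharing a
  window, and those are what the acceptance checks compare.
- **QC fixpoint.** Removing a sample changes every SNP's call-rate
  denominator and vice versa, so a single pass of the
  SNP-CR -> sample-CR -> MAF cascade is not always a fixed point of its
  own thresholds at quantization boundaries. The cascade re-applies the
  three filters until nothing more is removed, making QC idempotent; the
  extra iterations are recorded in the report only when they act.
- **Unknown ancestral state.** SNPs whose ancestral allele is absent
  from the polarization table (or matches neither REF nor ALT) are kept
  for QC and LD but excluded from iHS, which requires polarity.
- **LD.** r^2 is computed by direct haplotype counting
  (D = p_AB - p_A p_B; r^2 = D^2 / (p_A q_A p_B q_B)) — the pipeline
  owns phased data, so no EM estimation from genotypes is needed. Region
  means subsample pairs above `max_pairs=100,000` with a logged seed.
- **Gene distance.** Distance to the nearest gene boundary (start or
  end), ties broken by lower coordinate then name; 0 means inside the
  gene. Sub-classification (exon/UTR/intron) only when feature intervals
  are supplied.

## The simulator

`haploscan.synthetic` generates the study-shaped inputs end to end: a
single chromosome, defaults N = 500 diploids, L = 5 Mb, 5,000
segregating biallelic SNPs, recombination 1e-8 per bp per generation,
G = 100 generations, 396 diploids sampled — a dense-chip, few-hundred-
sample composite-cattle design. The model:

- standing variation drawn from a neutral 1/x frequency spectrum
  truncated to [1/(2N), 1 - 1/(2N)], sites initially independent;
- Wright-Fisher reproduction with additive fitness (1, 1+s, 1+2s by
  focal-site genotype), crossover counts Binomial(L-1, r) placed
  uniformly, no new mutation during the G generations;
- the focal derived allele planted at exactly round(2N f0) copies
  (default f0 = 0.05); when s > 0 its carriers additionally share an
  identical-by-descent core segment around the focal site, with
  per-carrier exponential flank lengths whose mean is set by the neutral
  age of an allele at frequency f0 (age ~ -4N f0 ln f0 / (1 - f0)
  generations; flank scale 1/(r * age), about 320 kb at the defaults).
  A standing variant is a single historical mutation; without this
  shared core the simulated "sweep" amplifies 2N f0 unrelated
  backgrounds — a maximally soft sweep that carries almost no
  haplotype-contrast signal and does not represent a variant with a
  mutational origin;
- G = 100 is chosen so that an additive sweep with s = 0.05 starting at
  5 % reaches ~90 % derived frequency (logistic passage time
  (1/s) ln(p q0 / (q p0)) ~ 118 generations to 95 %), the regime where
  haplotype-contrast statistics are most informative;
- an observation layer collapses haplotypes to diploid dosages with
  independent missingness and per-genotype call scores (uniform on
  [0.2, 1], with a planted fraction below the 0.20 reliability
  threshold) to exercise QC.

Everything is a pure function of the parameter set: one seed, bit-
identical outputs. A selected allele lost to drift restarts the run with
an incremented seed (bounded retries, counted in the truth record).

### What the simulator does and does not emulate

It emulates dense polarized SNPs, sweep-elongated haplotype
homozygosity, familial relatedness of a small herd, genotyping noise and
fixed alleles. It does **not** emulate deep coalescent history: the
population is founded G generations ago from linkage equilibrium, so all
background EHH comes from recent familial coalescence. Two consequences
matter for interpreting test results. First, background EHH has a
plateau of roughly P(pair coalesces within G) ~ G/2N ~ 0.1 that extends
for megabases, so iHH is plateau-dominated and log-ratios are compressed
relative to real data. Second, a single 5-Mb chromosome means iHS is
standardized over ~2,000 valid scores that include the sweep itself;
the expected maximum of ~2,000 standard normal scores is ~3.3, while
piHS >= 5 demands 4.42. Primary-tier hits are therefore essentially
unreachable at this scale in sweep and neutral runs alike — the tests
verify the *relative* near-focal enrichment of |iHS| (and of within-
region r^2), which is robust, rather than absolute tail exceedances,
which are a genome-scale phenomenon. Passing tests show the machinery is
correct and the signal is recovered where the simulated conditions carry
it; they do not certify power on real genome-scale data.

## Problem sizes in the test suite

The simulation-based tests use N = 500, 5 Mb, 5,000 SNPs, 200 sampled
diploids, with 20 sweep and 20 matched neutral replicates for the
detection checks and single replicates elsewhere; unit tests use
populations of 30-300 with tens-to-thousands of SNPs. A full 40-
replicate detection run takes a few minutes on one core; the whole suite
runs in well under half an hour.

## Numerical notes

- EHH group refinement keeps only non-singleton groups active
  (singletons cannot rejoin), so long extensions on decayed profiles are
  cheap; the kernel is numba-compiled and single-threaded,
  deterministic.
- Trapezoid integration is exact for the piecewise-linear EHH decay
  representation; refining the grid with interpolated midpoints leaves
  iHH unchanged (tested).
- piHS uses `norm.logsf`; pihs(0) = 0 by convention.
- Zero-spread or under-filled standardization bins invalidate their
  SNPs rather than producing infinities.
- Degenerate inputs (monomorphic SNPs in LD, allele classes below
  `min_carriers`, empty gene chromosomes, empty region sets) return
  flagged/empty results, not exceptions, except where the spec of the
  operation is a precondition violation (unphased VCF, inverted
  intervals, empty post-QC datasets).

## Known limitations

- Single-population iHS only; no cross-population statistics (XP-EHH,
  Rsb) and no genetic-map distances (bp only).
- The simulator has no demography, no multi-chromosome linkage and no
  coalescent back-end; see above for what that implies.
- Phasing and imputation are upstream: the pipeline requires complete
  phased input and will refuse unphased or missing genotypes.
- Published genome-scale numbers that depend on unreleased genotype
  data (post-QC SNP/sample counts, the genome-wide iHS values
  themselves, per-region mean r^2 levels) cannot be recomputed; the
  packaged reference table of 48 published significant SNPs validates
  the piHS transform, the significance rule and the region arithmetic,
  which are data-independent given the printed scores and positions.
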