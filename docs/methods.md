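# Methods

`acidsel` implements, as one reproducible pipeline, the pool-seq
evolve-and-resequence analysis of a two-pH mussel larval selection
experiment — SNP panel filtering, allele-frequency shift testing (FET/CMH +
q-values), cross-day outlier-locus intersection with a treatment partition,
and pooled F_ST — together with a forward simulator of the experiment itself,
so every stage can be exercised and calibrated without the raw sequencing
data.

## The experimental design being simulated

A founder panel of 12 dams and 16 sires is crossed in full factorial (192
crosses) to seed a day-0 zygote pool; 100,000 zygotes go into each of six
replicate buckets per pH treatment (ambient ~8.05 and low ~7.4). Three
replicates per treatment are destructively sampled on day 6: two of them are
split at a shell-size quantile (largest 18% in ambient, 21% in low pH) into
"fastest"/"slowest" pools, the third is sequenced whole. The remaining
replicates are sampled on day 26 and at settlement on day 43, where the
ambient treatment contributes two pools and low pH three. All pools are
sequenced at ~100x mean coverage, founders individually at ~40x, giving 28
founder samples plus 22 pooled larval samples on one shared SNP axis.

## The forward model

**Genetics.** Loci are biallelic and unlinked, drawn at population
frequencies from a parametric law (uniform on [0.1, 0.9] by default) and
instantiated in founders as binomial(2, p) dosages. Offspring are assigned
uniformly to the 192 crosses and inherit one Mendelian allele per parent per
locus. No linkage or mutation: exome SNPs on transcriptome contigs are
analysed marginally and no genetic map is available, so haplotype structure
would add parameters without adding testable structure.

**Viability selection.** An episode culls a pool to an exact census target.
Latent fitness per individual is the sum over active loci of
`effect x {0, h, 1}[dosage]` plus standard-Gumbel micro-environmental noise;
the lowest-ranked individuals die. Because top-K selection under Gumbel
noise is exactly weighted sampling without replacement with weight
`exp(fitness)`, each round is multiplicative viability selection; with the
noise scale set to 0 the episode degenerates to deterministic rank
truncation. A configurable fraction of deaths is uniformly random
("drift deaths"). Episodes spanning several days run one culling round per
day with geometrically interpolated census targets: survival weights then
multiply across rounds, which matters quantitatively — a single fixed-count
cull caps the per-locus frequency shift at roughly `i * sqrt(pq/2L)` for L
equally loaded loci, far below the near-complete purges the day-6 data of
such experiments show, whereas compounding daily rounds approaches
independent per-locus viability selection.

**Selection regime.** Three locus classes: environment-specific loci for
each treatment (2 per environment by default, effect -2.0 per daily round,
h = 0.5) and shared "load" loci deleterious in both environments (10 by
default, effect -0.3). Causal SNPs are drawn one per contig at founder
frequencies in [0.48, 0.60] and are required to have at least 3 dams and 3
sires homozygous for the favoured allele — the premise of the experiment is
that tolerant genotypes exist in the founders; without such backgrounds a
purge stalls in heterozygous families and the realised shift becomes a
founder-sampling lottery. Selective mortality is front-loaded: the day 0-6
episode (to 6% of seeding; the census on day 6 was never observed, and the
F_ST-by-exposure trajectory implies three- to five-fold more differentiation
before day 6 than after) is 95% selective, while the day-26 and day-43
episodes are pure drift. Under these defaults environment-specific loci
shift from ~0.54 to ~0.10 — a relative shift well above 50% — while shared
load loci shift moderately in both treatments.

An important emergent feature is family-level hitchhiking: with only 28
founders, strong selection concentrates survivors into few crosses and drags
neutral frequencies with a *consistent* direction across replicates (the
direction is fixed by founder genotypes). This reproduces the pervasive
"thousands of significant SNPs" character of real cross-based
evolve-and-resequence data and is why the outlier definition demands
significance on every sampling day.

**Phenotypes.** Shell length (µm) = day baseline (100 + 5·day) x
(1 - deficit) + centred additive growth-locus effects + Gaussian noise
(sd 3 µm). The low-pH deficit is 8% through day 7 and declines linearly to
2.5% by day 26. Growth loci (1 shared + 2 per-environment contigs, 3 µm per
allele) are disjoint from viability loci; effects are centred at the founder
mean dosage so the deficit schedule is expressed in the group means.
Environment-specific growth variance also elevates the low-pH coefficient of
variation early, qualitatively matching the released-variation signature of
the real data.

**Sequencing.** Per-SNP coverage = 100 (pools) or 40 (founders) x a
locus-specific capture efficiency (gamma with shape 100, shared by all
samples of a run — a badly captured SNP is shallow everywhere) x per-sample
negative-binomial noise (size 200). Alternate read counts are binomial at
the pool's true allele frequency: reads sample gene copies with replacement,
valid because simulated pools (>=10^2-10^5 individuals) are large relative
to coverage. The shared efficiency term is essential: independent per-sample
coverage noise makes the 50x minimum-depth filter an accidental lottery
across 22 samples and silently deletes causal SNPs from the panel.

## The analysis pipeline

**Panel.** Two-stage filter with the study's thresholds: founder stage —
callable (>=10 reads) in >=75% of founders, founder minor-allele frequency
>=0.05 (from summed reads over callable founders); pool stage — in *every*
pooled sample, depth in [50, 450] and read-frequency MAF >= 0.01. Per-sample
MAF is the stricter reading of the pool threshold and is what the attrition
report records. Positions are 1-based (sync/VCF convention); internal
indexing is 0-based.

**Shift tests.** Tables are raw read depths, rows (baseline, focal), columns
(ref, alt); no normalisation or effective-pool-size rescaling. Day 6 has no
replicates, so the day-0 pool is compared by a two-sided exact FET
(point-probability rule); days 26/43 and the fastest-vs-slowest contrasts
use the CMH chi-square with replicates as strata and a continuity correction
by default (exposed as a flag; with |sum a - sum E| < 1/2 the corrected
statistic is clamped to 0). P-values become q-values by Storey's estimator
with lambda = 0.5 (no spline; BH available), and significance is the strict
q < 0.01.

**Outliers.** A locus is a transcriptome contig (simulated: 3 SNPs per
contig). A single significant SNP qualifies a locus for a day; a treatment's
outliers are the loci significant on *all* of its sampling days (SNP-level
intersection is available but locus-level is the default reading). The two
treatments' outlier lists are partitioned into unique and shared sets with
percent-unique reported rounded and unrounded.

**Pooled F_ST.** Identity-in-state form: within-pool read-pair identity
`Q1_reads = [a(a-1)+r(r-1)]/[n(n-1)]` corrected for reads re-sampling the
same gene copy, `Q1 = (Q1_reads - 1/c)/(1 - 1/c)` with c = ploidy x assumed
pool size; between-pool identity `Q2 = p_a p_b + q_a q_b` from read
frequencies; per-SNP `F = (Q1bar - Q2)/(1 - Q2)` and the multilocus
statistic is the ratio of sums. Q1bar is the unweighted mean of the two
pools' Q1. SNPs with depth < 2 in either pool or `1 - Q2 <= 1e-12` are
excluded and counted; negative per-SNP values are retained (unbiased moment
estimator). Because the cited ANOVA estimator's exact locus/sample weighting
is not recoverable from the study alone, the estimator is validated by
parameter recovery on a known-truth island model (F = 0.10 recovered within
+-0.005 at 10,000 SNPs) and by a neutral same-population null, not by
matching another implementation's output. Pool sizes enter in individuals
and are doubled for diploidy; the day-6 and day-43 censuses are only known
as ranges, so `pool_size_sweep` evaluates the multilocus value over
10,000-40,000 and 100-400 individual grids.

**Structure/phenotypes.** Sample-level PCA standardises SNP columns (zero
variance columns dropped, unit variance with the n-1 convention) and takes
scores from the SVD, with each component's sign fixed by its
largest-magnitude loading — fully deterministic. Phenotype summaries are
descriptive (n, mean, SD, CV with the n-1 SD, quantiles, log-scale
moments); inferential mixed-effects modelling of shell length is out of
scope.

**Orchestration.** `RunConfig` validates against the known field sets before
any stage runs; a single seed fans out to stage seeds through
`numpy.random.SeedSequence` spawning in fixed execution order; floats are
serialized at 12 significant digits so output digests are stable, and the
manifest records config hash and per-stage digests (used by `--resume`).

## What the simulator does and does not emulate

It emulates the design topology, census schedule (~97.7%/97.6% mortality by
day 26), founder-limited standing variation, Mendelian inheritance,
viability selection with load and environment-specific components,
truncation on a size phenotype, and capture-sequencing noise. It does not
emulate linkage, de-novo mutation, read-level artefacts (mapping error, PCR
duplicates, reference bias), culling-free death processes (e.g. disease), or
carbonate-system physiology. Passing tests therefore demonstrate that the
statistics recover truth under an idealised but structurally faithful
null/alternative; they do not certify behaviour under mapping artefacts or
linked selection.

## Problem sizes and numerical choices

Desk-scale runs use 40,000 zygotes per replicate and a 2,001-SNP panel
(667 contigs), preserving every design ratio of the 100,000 x 10,000
default; the full scale remains available through `ExperimentConfig`.
Power and calibration summaries average over several seeded replicate runs
because single-run recovery over 4 environment-specific loci is quantized in
steps of 0.25. Tie-breaks are deterministic everywhere (stable sorts by
identifier); degenerate inputs (monomorphic tables, all-degenerate strata,
empty panels) return the documented conventions (p = 1, errors with
attrition tables) rather than NaN.

Known limitations: the exact FET's discreteness makes its p-values
conservative, so null p-value distributions are stochastically larger than
uniform (tail calibration is clean: ~0.9% of null SNPs at p < 0.01); the
day-6 FET on a single 100x pool pair is the power bottleneck of the whole
outlier scan, which is why detectable simulated selection requires few loci
of large effect; and with 28 founders the family-hitchhiking background is
irreducible — outlier lists on selected data legitimately contain loci with
no direct effect, which the null-calibration criterion (run without
selection) deliberately excludes.
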