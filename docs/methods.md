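# Methods

`micronet` implements a network-based nutrigenomics analysis: a latent
metabolite phenotype is constructed by PCA, associated with genotype SNP by
SNP under family clustering, aggregated to LD-aware gene-level evidence,
and projected onto topological modules of a gene interaction network,
where enrichment tests identify modules that carry both statistical and
curated functional links to micronutrients. Because no real cohort of this
design is publicly available, the package ships a first-class synthetic
study generator whose outputs exercise every assumption the analysis
makes; all calibration and recovery guarantees are stated with respect to
those synthetic conditions.

## Synthetic cohort generator

**Genotypes.** SNPs live in LD blocks (default 5 SNPs). Within a block,
haplotypes are drawn from an equicorrelated Gaussian copula: a latent
vector `z = sqrt(r)*shared + sqrt(1-r)*own` is thresholded at each SNP's
allele-frequency quantile, so `within_block_r` (default 0.8) controls LD
without constraining marginal frequencies, which are Uniform(0.15, 0.5)
by default. Families (1–3 siblings, default 200 subjects in 130 families)
get four parental haplotypes per block; each child inherits one maternal
and one paternal haplotype uniformly, so siblings share each parental
haplotype with probability 1/2 per block. This haplotype bookkeeping is
the minimal state that preserves both LD and kinship; a haplotype-free
shortcut cannot represent sibling sharing correctly. The minor allele is
defined per SNP from the realized sample (frequency > 1/2 flips the
column), deliberately exercising the QC orientation path. Per-call quality
scores are Uniform(0.7, 1) except a `low_quality_rate` fraction drawn
Uniform(0, 0.7); a `missing_call_rate` fraction of calls is missing.
Defaults (0.05 % low-quality, 0.1 % missing per call) mirror the >98 %
call rates of production genotyping arrays; under the strict any-call QC
rules, per-call error rates interact exponentially with cohort size, and
rates much above these leave no usable SNPs.

**Phenotype.** A latent factor
`L = standardize(sum_j beta*g_j + gamma_age*age + gamma_sex*sex + eps)`
sums minor-allele counts over all causal SNPs (default: 8 causal genes x
5 SNPs planted in one network block, `beta_snp = 0.45`,
`eps ~ N(0, 1.7^2)`), plus mild age/sex confounding (0.05 SD/yr, 0.2 SD).
Under the defaults each causal gene carries roughly a tenth of the latent
variance — large effects, consistent with a design whose original-scale
analogue reported thousands of multiplicity-surviving SNP associations in
a tiny cohort. Each of 8 metabolites is `loading*L + N(0, noise_sd)`,
observed as three assessments with additional noise of SD
`0.3*noise_sd` (the analysis averages assessments, so only a third-scale
perturbation survives averaging). Six metabolites load at 1.0; vitamin D
and riboflavin load at 0.2, leaving them to minor components. Proteins:
20 of 200 have slope `protein_beta = 0.5` on L with Student-t (df 3)
noise on the log2 scale (heavy tails are what the robust screen is for);
null proteins are pure t noise; panels are written on the linear scale.

**Network and gene sets.** A stochastic block model over the genes
(default 10 blocks of 100, `p_in = 0.2`, `p_out = 0.01`) provides planted
topological modules. Causal genes are drawn from designated blocks; the
neighborhood gene list (default 80 genes) overlaps one designated block
at 70 %; QTL intervals for one phenotype are placed within 1 Mbp of 80 %
of the causal genes, with random intervals for the remaining phenotypes.
Genes tile two chromosomes at 300-kb spacing (20-kb bodies), so default
50-kb flanks never merge neighbours.

All randomness flows from a single root seed through named
`numpy.random.SeedSequence` child streams (one per independent source:
haplotypes, quality, covariates, latent noise, metabolites, proteins,
network, neighborhood, QTL, causal-gene choice), making every output
bit-reproducible and stages independently perturbable.

**What the generator does not emulate:** realistic human LD maps and
recombination hotspots, ancestry/admixture structure, assay batch
effects, genotyping-intensity-level error, and the dependence structure
of a real curated interaction network (degree heterogeneity, hubs).
Passing tests therefore demonstrate correctness and calibration of the
machinery under the stated generative assumptions, not performance on
real cohorts.

## Metabolite phenotype

Assessments are averaged per subject (mean over available values).
Columns are z-scored before PCA because metabolite assays are on
incommensurable units; PCA is computed by SVD of the centered/scaled
matrix. Missing data are handled complete-case — with small cohorts,
imputation would inject structure the downstream tests could not track.
The SAM/SAH methylation index enters as a single ratio column. Component
signs are fixed by an anchor metabolite (vitamin E loads positively on
component 1 by default; other components are signed by their largest
loading), so scores are invariant to column order and run-to-run.

## Genotype QC

Filter order is fixed: per-call quality, completeness, MAF, HWE; each SNP
is charged to the first filter that removes it, so removals plus
survivors always partition the input (asserted at run time). The quality
rule defaults to "any present call below 0.7 removes the SNP" — the
strictest reading, consistent in spirit with requiring complete
genotyping — with a mean-score mode available. MAF is computed after the
completeness filter so denominators are uniform. The HWE test is the
exact conditional test (Levene/Haldane distribution of the heterozygote
count given allele counts; two-sided by summing probabilities no larger
than the observed outcome's), chosen over the chi-square approximation
because target cohorts are tens of subjects. The HWE alpha defaults to
0.001, a conventional QC screen level.

## SNP association

Gaussian GEE with identity link and independence working correlation
over sibling clusters. Under that working correlation the coefficient
path is ordinary least squares; the implementation computes it in closed
form and builds the cluster-robust sandwich covariance directly, with
the whole genome scan vectorised (covariates residualised once, per-SNP
bread/meat assembled as batched arrays). statsmodels' GEE is used in the
test suite as an independent cross-check, never as the implementation.
The Wald z is referred to the standard normal, the GEE convention; with
~100–130 clusters this is mildly liberal (measured null size ≈ 0.05–0.07
at nominal 0.05), a documented small-sample limitation rather than a bug.
Genotype coding is additive (minor-allele count) by default, with a 2-df
genotype-class mode available. One phenotype value per unique participant
is used. BH correction is applied over all tested SNPs; NaN p-values
(constant SNPs) propagate and are excluded from the family size.

## Gene-level aggregation

The gene statistic is `T = sum_i qchisq(1 - p_i, df = 1)` over member
SNPs. SNPs belong to every gene whose interval, extended by a flank
(default 50 kb per side, the convention of gene-based association tools;
a 0-flank mode exists), contains their position. The null distribution of
T respects local LD: under the null, SNP z-scores are ~MVN(0, R) with R
the in-cohort genotype correlation matrix (no external reference panel —
the analysis is strictly in-sample), so null statistics are simulated as
`sum(Z^2)`, `Z ~ MVN(0, R)` via Cholesky of an eigenvalue-clipped
(1e-8), diagonal-rescaled repair of R. The Monte-Carlo p-value is the
add-one estimator `(1 + exceedances)/(1 + n_sims)`, never zero, with an
adaptive schedule (library default 10^3 → 10^4 → 10^6; the pipeline
default caps at 10^5, which resolves q < 0.1 comfortably over ~10^3
genes) escalating while `p < 10/n_sims`. Each gene draws its own
`SeedSequence` child keyed by sorted gene id, so results are independent
of iteration order and bit-reproducible. p = 0 inputs (possible only via
upstream underflow) are clamped to the smallest positive float and
flagged.

## Network modules

The interaction graph is undirected and simple; self-loops and duplicate
edges are dropped at load. Analysis runs on the largest connected
component (ties break to the lexicographically smallest node set, for
determinism). Modules minimize the Reichardt–Bornholdt Potts Hamiltonian
`H = -sum_{i<j} (A_ij - gamma*k_i*k_j/2m) * delta(s_i, s_j)` by
single-node-move simulated annealing: proposal = random node to random
spin; acceptance `min(1, exp(-dH/T))`; geometric cooling (factor 0.99)
from a start temperature chosen so sampled uphill moves accept at ~1/2;
stop on a sweep with no accepted move once T < 0.01, or after
`max_sweeps`. Best-of-N restarts (default 5; pipeline 3) with distinct
sub-seeds keep the minimum-H configuration. Empty spins are dropped and
modules relabeled 1..n by decreasing size. With gamma = 1 and this
configuration-model null, minimizing H is equivalent (up to a constant)
to maximizing Newman–Girvan modularity, which is reported for every
partition. The default spin budget q = 100 exceeds any plausible module
count; the incremental dH bookkeeping is verified against a brute-force
pairwise evaluator in the tests. The annealing kernel is
nopython-compatible Python jitted with numba when importable, with an
identical uncompiled fallback. Weighted or negative edges are
unsupported (curated interaction networks are unweighted); module counts
are data-dependent outputs, never targets.

## Enrichment

One primitive serves all analyses: the exact hypergeometric upper tail
`P(X >= k)` computed by log-space summation over the support (exact to
~1e-14 against rational-arithmetic enumeration). Module tests use the
LCC gene set as the universe — the partition is a partition of exactly
that set — with "genes with ≥1 tested SNP" available as an alternative.
Expected hits `n*K/N` are reported beside observed. BH families are
always per-analysis (over modules, or over QTL phenotypes), never
pooled. A module significant at q < 0.1 in both the statistical-hit and
the neighborhood analysis is flagged a "micronutrient system". QTL gene
sets take every gene whose interval intersects a phenotype's QTL
interval expanded by 1 Mbp on both sides (closed-interval intersection;
genes are counted once per phenotype); QTL enrichment is flagged at
q < 0.15. Files use BED conventions (0-based half-open); all in-memory
coordinates are 1-based inclusive, converted exactly once at I/O.

## Protein screen

Per protein: Huber M-estimation (tuning 1.345, MAD scale, IRLS to 1e-8,
max 200 iterations) of log2 abundance on the phenotype; abundances are
log2-transformed by default because aptamer panels are right-skewed
(flag to disable); Tukey bisquare is selectable. The association is
deliberately bivariate (no covariates). "Corrected p < 0.1" is read as
BH q < 0.1, matching the correction used everywhere else. Significant
proteins are clustered by average linkage on correlation distance
(1 - r, clipped to [0, 2] so perfectly correlated or identical proteins
degenerate gracefully); the dendrogram's two top-level branches are
reported left-to-right with their plasma/membrane annotation fractions
when an annotation is supplied.

## Pipeline, sizes, and numerical choices

The orchestrator runs simulate → metpc → qc → scan → genes → modules →
enrich → proteins, writing plain-text tables plus a manifest with a
configuration hash (scientific parameters only; output paths excluded)
and SHA-256 checksums per stage output. Identical config + seed
reproduces identical checksums. Default pipeline problem sizes — 200
subjects, 5,000 SNPs, 1,000 genes, 10 modules, 10^5 max gene
simulations, 25 spins, 3 restarts — were chosen so a complete run
finishes in seconds-to-minutes on one core while every significance
threshold in play (q < 0.1, q < 0.15, adjusted p < 0.05) remains
resolvable; the library defaults are larger where convention dictates
(10^6 simulations, 100 spins, 5 restarts).

Known limitations: normal-reference Wald inference is liberal at tens of
clusters; the MVN null for the gene statistic assumes the SNP z-scores
are jointly normal (exact only asymptotically); the spin-glass optimum is
stochastic — only seeded determinism, not global optimality, is
guaranteed; and the synthetic generator's homogeneous SBM understates the
degree heterogeneity of real interaction networks, which makes module
recovery easier than it would be in practice.
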