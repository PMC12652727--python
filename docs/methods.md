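# Methods

`rohscan` implements a within-breed selection-signature workflow for dense
SNP-array genotypes of grouped individuals (e.g. usage groups inside a
single dog breed), together with a ground-truth simulator that makes every
stage testable without real data. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Genotype model and quality control

Genotypes are diploid autosomal calls coded 0/1/2 as copies of a counted
allele, −1 for missing. On PED/MAP input the counted allele is the minor
allele observed at load (frequency ties broken toward the lexicographically
greater symbol, so write→read round trips are stable); on VCF input it is
ALT. Coordinates are 1-based inclusive throughout; BED's half-open 0-based
spans are converted at the boundary. Panels are sorted by (chromosome,
position) on load, and multi-allelic or non-autosomal records are dropped
with logged counts. The autosome count defaults to 38 (dog).

QC is a fixed four-stage cascade with recomputation between stages:

1. drop samples with call rate < 0.95,
2. drop SNPs with call rate < 0.95,
3. drop SNPs with minor-allele frequency < 0.01 (retain at exactly 0.01),
4. drop SNPs whose observed/expected heterozygote-frequency ratio falls
   outside [0.05, 1.1] (inclusive retain).

The O/E-ratio Hardy–Weinberg screen is a ratio test, not an exact test, and
at modest sample sizes (tens of individuals) its upper bound is reached by
binomial noise alone for an appreciable fraction of SNPs; with hundreds of
samples it behaves as a genotyping-artefact filter. Monomorphic SNPs are
removed at the MAF stage before the ratio is evaluated, so the ratio is
never formed with a zero denominator. An alternative reading of the SNP
call-rate threshold as a missingness ceiling is available via
`QCConfig.snp_call_rate_is_max_missing` but is off by default.

## Runs of homozygosity

Detection is the windowless consecutive-runs method. Per individual and
chromosome, a left-to-right scan grows a candidate run over consecutive map
SNPs; a SNP is admissible if it is homozygous, or heterozygous while fewer
than `max_het` heterozygotes are already in the run, or missing while fewer
than `max_missing` missing calls are, and its gap to the previous SNP is at
most `max_gap_bp`. The SNP that violates closes the run; scanning resumes
immediately after it (for a gap violation, at the SNP following the gap),
so one individual's runs never overlap. Runs are trimmed to homozygous
non-missing SNPs at both ends — tolerated het/missing calls may sit inside
a run but never define its boundary or inflate its length — and emitted
only if they have at least `min_snps` SNPs, span at least `min_length_bp`
(length computed as `end_bp − start_bp`, no +1), and, when the density
parameter is set, average at most `min_density_bp_per_snp` per SNP.

Two presets are provided. Island mode (`ISLAND_PARAMS`): 55 SNPs, 1000 kb,
≤1 het, ≤1 missing, gaps ≤1000 kb. Cluster mode (`CLUSTER_PARAMS`) adds a
minimum density of 1 SNP per 150 kb. "Minimum window size of 55 SNPs" is
interpreted as the minimum SNP count of a run, since the consecutive
method has no windows.

The detector is verified against a brute-force enumeration of maximal
admissible windows under the same scan-restart rule, recounted from whole
windows rather than incremental counters, plus a fuzz test asserting that
every emitted run satisfies all constraints and cannot absorb a flanking
SNP without violating one.

Length classes are half-open Mb bins [0,6), [6,12), [12,24), [24,∞).
Genomic inbreeding is F_ROH = Σ L_ROH / L_AUTO with L_AUTO the mapped
extent (per-chromosome last-minus-first SNP position, summed); a published
constant (e.g. 2,201,878 kb for the dog array map) can override the
denominator. Per-class F_ROH values sum exactly to the total.

## Islands, clusters, and homozygosity association

Per-population in-ROH frequency at each map SNP counts the individuals
whose (merged) runs cover the position, divided by the post-QC population
size. ROH islands are maximal runs of consecutive SNPs with frequency at or
above the threshold (default 50%, inclusive); no bridging across
sub-threshold SNPs is performed. ROH clusters are the support-count
analogue on breed-wide counts from cluster-mode segments, thresholded at
`min_support` (default 20) individuals; single-SNP clusters are retained.

The homozygosity association test represents each cluster by its lead SNP
(lowest position) and cross-tabulates the binary in-ROH state there against
membership in two disjoint groups: Pearson chi-square (1 df, no continuity
correction) when all expected counts are ≥5, otherwise two-sided Fisher
exact; Bonferroni correction over the clusters tested in the comparison;
significance at corrected p ≤ 0.05. −log10(p) is emitted for Manhattan
plotting.

A known sensitivity, visible in simulation: the lead SNP of a consensus
region can fall in the stochastic "shoulder" where individual runs extend
beyond a shared core haplotype, and group frequencies a single SNP outside
the core need not match the core frequencies. Interpreting borderline
associations at cluster edges therefore warrants inspecting the per-SNP
counts across the cluster, not only the lead SNP.

## Weir–Cockerham F_ST

Per-SNP two-population variance components a (among populations), b (among
individuals within populations) and c (within individuals) follow the 1984
genotype-based estimator, computed from per-group complete-case sample
sizes, allele frequencies and observed heterozygote frequencies; θ =
a/(a+b+c), the genome-wide summary is Σa/Σ(a+b+c). Negative per-SNP
estimates are reported as-is; θ is undefined (NaN, never 0) for SNPs
monomorphic across both groups or with fewer than two non-missing genotypes
in either group. Scan designs: all pairwise, one-vs-all (second population
is the union of the rest), or a designated subgroup pair. The significant
set uses an inclusive threshold, default θ ≥ 0.6.

Calibration relies on the Balding–Nichols identity E[θ̂] = F when both
populations drift independently at F from a shared ancestor: at F = 0.2
(20,000 SNPs, 2×100 individuals) the weighted estimate falls within
[0.18, 0.22], and a random split of one panmictic population gives |θ̂| <
0.01. A fixed difference with complete data gives θ = 1 to 1e−12.

## Population structure and morphometrics

The genomic relationship matrix is ZZ′/m over SNPs with z = (x − 2p)/
√(2p(1−p)); missing calls are mean-imputed (z = 0) and zero-variance SNPs
skipped with a logged count; per-pair complete-case SNP counts are reported
alongside. Genotype PCA takes the top-k eigenpairs of the GRM, scales
eigenvectors by √λ, and fixes signs so each component's largest-magnitude
entry is positive. This equals direct PCA of the standardized genotype
matrix up to sign and 1e−8.

Morphometric PCA standardizes the 18 traits to unit variance before
decomposition — the traits span ~4 cm (eye width) to ~67 cm (chest girth),
and unscaled PCA would be girth-dominated. Both proportion-of-variance
conventions are reported: λᵢ/Σ(all λ) and λᵢ/Σ(top-k λ), since published
analyses sometimes normalize within the retained components only.

Trait comparisons run, per trait: Shapiro–Wilk per group (minimum p
reported), median-centered Levene across groups, one-way ANOVA, and — only
when ANOVA p < α = 0.05 — Tukey–Kramer HSD (unequal-n form, via
statsmodels) with a compact letter display. Letters are the maximal cliques
of the "not significantly different" graph, ordered by first member, so two
groups share a letter iff their Tukey comparison is non-significant, and
the display is invariant to input order.

## Synthetic data

The simulator draws ancestral allele frequencies uniformly on a configured
interval (default [0.1, 0.9]), population frequencies from the
Balding–Nichols beta distribution with per-population drift F, and
genotypes Binomial(2, p). Defaults mirror a within-breed usage-group study:
four groups of 35/66/92/44 individuals with F between 0.03 and 0.06
(weighted pairwise θ of a few percent, with individual markers reaching
≈0.2 in the beta tails), 10 chromosomes × 5,000 SNPs uniformly spaced over
50 Mb (≈1 SNP/10 kb). Planted autozygosity overwrites carrier genotypes
with homozygous haplotype draws — per-carrier draws for individual tracts,
one shared haplotype for sweeps — with carriers sampled per population to
hit a requested fraction. Noise flips calls to heterozygous (default rate
5e−4) or missing (2e−3) independently, thinned inside planted carrier
spans to at most one het and one missing so tracts remain recoverable under
the default run tolerances. Morphometrics are group-structured normal
draws at the published 18-trait means/SDs, optionally with a shared trait
correlation matrix. Every stage draws from an independent sub-stream of
the master seed: changing the noise rate cannot alter the drift draws, and
a seed fully determines the panel.

What the simulator does not emulate: linkage disequilibrium and
recombination-driven haplotype structure, pedigree-consistent autozygosity,
site-frequency spectra of real arrays, batch/cluster genotyping artefacts,
or trait correlations unless supplied. Passing recovery tests therefore
demonstrates algorithmic correctness of the detectors and estimators under
the stated models, not their field performance on real array data.

## Problem sizes and determinism

The test suite validates at deliberately compact sizes chosen to keep the
full run in tens of seconds while preserving the statistical resolution
each check needs: the ROH oracle comparison uses 200 individuals × 1,000
SNPs; the fuzz pass 1,000 random single-individual panels; F_ST calibration
20,000 SNPs × 2×100 individuals × 10 seeds; island/cluster boundary checks
50 individuals × 2,000 SNPs × 20 seeds; the ANOVA null 2,000 replicates;
the Tukey-CLD recovery 100 replicates of 3×100. `scripts/acceptance.py`
recomputes the same quantities at the same scales from a command-line seed.
All randomness flows through numpy Generators seeded from explicit values;
identical inputs give byte-identical outputs everywhere (tables are emitted
in deterministic column and row order).

## Known limitations

- The greedy left-to-right scan is standard for consecutive-runs detection
  but not globally optimal: a closed short candidate can, in contrived
  genotype patterns, pre-empt a longer admissible run that a different
  start would have found. The brute-force oracle applies the same rule, so
  equivalence tests validate the implementation, not global optimality.
- An isolated heterozygous error inside a long tract can split it into two
  runs of which one falls below the emission thresholds; recovery of noisy
  tracts is therefore assessed as span coverage, not run identity.
- The O/E-ratio HWE filter is noisy at small n (see above).
- The association test assumes independent individuals; related samples
  inflate its statistic, and no kinship correction is applied.
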