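# Methods

`recmap` implements the classical mapping workflow for a recessive
congenital defect segregating in a pedigreed livestock population: a
mixed-model genome scan on a quantitative fertility score, autozygosity
mapping of the shared homozygous segment in affected sires, haplotype
statistics around the mapped segment, recessive-compatibility filtering of
a small resequencing panel, and coding-consequence annotation of the
surviving substitutions.  Because the motivating data (array genotypes and
fertility records of thousands of artificial-insemination bulls) are
proprietary, the package ships a gene-drop simulator that reproduces the
statistical structure of such a population, and every stage is tested
against it.

## The simulated population

`simulate_pedigree` builds a discrete-generation pedigree with constant
generation size.  One founder sire is flagged as the mutation founder and
fathers a fraction `4 * target_hap_freq` of the first offspring
generation; since a haplotype's expected frequency is half its carrier's
expected genome share, and that share is preserved when later parents are
drawn at random, the implanted haplotype settles at the target frequency
(default 7.2%) in expectation.  Later generations draw
`ceil(size / offspring_per_sire)` sires at random — heavy sire reuse, the
defining feature of AI breeding — and dams uniformly.  Sexes alternate
within a generation; birth years advance by `years_per_generation`
(default 6) from the founder year 1966.

`gene_drop` transmits haplotypes down this pedigree with a Poisson
crossover count per meiosis (`recomb_rate` Morgans per chromosome, default
1.0 over a 10 Mb chromosome), crossover positions uniform, no
interference.  Founder alleles are drawn per marker from frequencies
uniform on (0.05, 0.95) so markers are informative; the causal marker is
monomorphic except for the single implanted founder copy.  Missing calls
are injected i.i.d. (default 0.8%, matching a ~99.2% call rate) into the
unphased calls only — the phased haplotypes are the simulation truth.
Each transmitted chunk carries a founder-gamete label, so
identity-by-descent is tracked exactly; `implanted_segment` derives from
these labels the maximal marker interval over which all case chromosomes
are IBD, the ground truth for autozygosity mapping.

Phenotypes follow the two-group trait model: the fertility score (MRA, a
percentage deviation from the population mean) is
`base_mean + polygenic + residual`, with the polygenic share
`polygenic_h2` (default 0.2 — fertility traits have low heritability) of
the total variance, correlated through a relationship matrix when one is
supplied.  Haplotype homozygotes are rescaled so their marginal
distribution has the case-group mean and SD (-27.69 +- 4.15, versus
-0.44 +- 3.16 for everyone else); 0- and 1-copy animals are identically
distributed, which is what full recessiveness means.  NRR56 (56-day
non-return rate) is generated with correlation 0.59 to MRA within group;
insemination counts are Poisson (means 1924 normal / 892 subfertile per
bull) and successes binomial with rate `0.30 + 0.0102 * MRA`, constants
chosen so the homozygote group reproduces the observed ~1.74% success and
other bulls ~29.5%.  MRA itself is an adjusted deviation score — the
national evaluation machinery that produces it is not modelled; the
simulator emits the score directly.

The resequencing panel holds 43 samples with six haplotype carriers, one
sequenced at high coverage (HC, error-free calls) and five at low coverage
(LC).  The causal variant is heterozygous in all carriers and homozygous
reference elsewhere; decoys get Hardy-Weinberg genotypes at allele
frequencies uniform on (0.01, 0.5), with 11.4% INDELs.  Every het call of
an LC carrier is independently converted to homozygous reference with
probability `het_miscall_rate`; the default 0.4 is the observed loss of
the causal het call in two of five low-coverage carriers.  The fixture
gene is a 183-codon single-transcript gene with TGC pinned at codon 161
and CAG at codon 66, placed inside the implanted segment so that its CDS
position 483 (a C>A stop-gain, p.Cys161X) is the panel's causal variant.

What the generator does *not* emulate: linkage-disequilibrium structure
beyond one generation-bounded chromosome (no coalescent history),
genotyping batch effects, sequence reads or genotype likelihoods,
imputation error, and selection on the trait.  Tests passing on this
population show the pipeline's statistical machinery behaves as designed
under the study's sampling structure; they do not certify robustness to
real-array artefacts beyond the simple missingness and miscall processes
modelled.

## Quality control

Filters run in a fixed order — individuals by call rate (>= 0.95), then
markers by call rate (>= 0.95), minor allele frequency (>= 0.5%) and
Hardy-Weinberg equilibrium (P >= 1e-6) — so marker statistics are computed
on cleaned samples; the order is part of the contract.  MAF uses
non-missing calls only.  The HWE test is a 1-df chi-square goodness of
fit, no continuity correction, validated against the published cohort
p-values (0.303 and 0.817).  Differential missingness between cases and
controls is a per-marker 2x2 test: Fisher's exact test when any expected
cell is below 5, chi-square otherwise (the source analysis names no test,
only a bound).  The pedigree (numerator) relationship matrix uses the
tabular recursion; the genomic-vs-pedigree concordance check lists pairs
whose absolute discrepancy exceeds a threshold, descending — the
signature of sample swaps.

## Mixed-model association

The model is `y = Xb + u + e`, `u ~ N(0, sigma_a^2 G)`,
`e ~ N(0, sigma_e^2 I)`, with G the VanRaden-style realized relationship
matrix `W W' / (2 sum p(1-p))` from column-centred dosages (missing
imputed to the column mean).  REML estimation is profiled over the single
ratio `delta = sigma_e^2 / sigma_a^2` after one spectral decomposition of
G: a 100-point log grid on [1e-5, 1e5] followed by bounded Brent
refinement, which covers heritabilities from ~1e-5 to ~0.99999.  The
per-marker scan keeps the null covariance *structure* fixed (the EMMAX
approximation), whitens data through the stored decomposition and tests
each marker by a Wald t-test (df = n - rank of design - 1) with the
residual *scale* re-estimated per marker.  Re-estimating the scale makes
the scan collapse exactly to ordinary least squares when G = I, which is
the behaviour the test suite pins; with variance components held entirely
fixed the two would differ by a factor close to one.  Monomorphic markers
are flagged with effect 0 and p = 1.  The case/control scan codes cases 1,
controls 0 and reuses the same machinery — a linear mixed model on the
binary trait, as in the source analysis.

A caveat the acceptance experiment exposes: on a single simulated
chromosome, a GRM built from the scanned markers absorbs the causal signal
(proximal contamination).  The scaled mapping experiment therefore builds
the GRM from a second, effectively unlinked marker set dropped down the
same pedigree — the analogue of the genome-wide GRM the real analysis
used — and runs the case/control scan on extreme-tail homozygotes, the
design under which the published signal was strongest.  At n = 1500 with a
7% haplotype this localises the minimum-p marker inside the implanted
segment in 20/20 seeds with top p-values of order 1e-40 to 1e-65.

## Autozygosity mapping and haplotype statistics

`homozygosity_run` returns the longest contiguous marker window containing
a homozygous anchor with at most `max_het` heterozygous calls (default 0)
and at most `max_missing` missing calls (default unlimited — missing calls
should not break runs on real arrays); ties go to the leftmost window.
`shared_segment` intersects the per-case runs; with the defaults this
equals the per-marker AND of homozygosity indicators, which is how the
tests oracle it.  Segment length is reported as `end - start + 1` from the
coordinates.  Detection overshoots the true IBD boundary by construction:
homozygosity persists past a breakpoint until an informative heterozygous
marker, so boundary resolution is one-marker-accurate only where several
cases share the delimiting ancestral recombination — the test suite checks
exactly that, plus containment of the IBD truth with bounded overshoot in
full populations.

Haplotype copies are called against the consensus haplotype (per-marker
majority allele over case haplotypes, ties toward reference): an
individual's copy count is the number of its phased haplotypes matching
the consensus at `match_threshold` (default 1.0, i.e. exact) of
non-missing segment markers.  Diplotype counts feed the same HWE
chi-square as QC.  The carrier trend is an individual-level OLS regression
of the 0/1 carrier indicator on birth year (the regression unit was left
open in the source; a per-year aggregated table is available as a
companion).  Trait effects of haplotype dosage (copies 0/1/2 as the tested
regressor) reuse the mixed-model machinery.  The CNV screen averages log R
ratios in odd-width sliding windows (default 3 markers) per group.
Fertility summaries report per-diplotype N, mean +- SD of MRA and NRR56,
insemination totals, percent successful to two decimals and inseminations
per bull to the nearest integer — the printed precision of the source
tables.

## Recessive-compatibility filtering

The strict filter keeps variants heterozygous in *all* carriers and
homozygous reference in *all* non-carriers.  The conservative filter,
designed for low-coverage data in which rare heterozygotes are
under-called, keeps variants that (i) have panel non-reference allele
frequency strictly below 10% ("below", not "at most"), (ii) are
heterozygous in the single HC carrier, and (iii) are heterozygous in at
least 3 of the 5 LC carriers.  Missing genotypes fail heterozygosity
requirements and leave the allele-frequency denominator.  Multi-allelic
records must be decomposed upstream (the readers reject them).  Under the
panel's error model, causal-variant retention is the binomial tail
`P(#LC hets >= 3)`, which the tests verify against simulation; an
error-free strict survivor has panel AF = 6/86 ~ 7% < 10% and therefore
always survives the conservative filter too.

## Consequence annotation

Gene models are single transcripts with ordered, non-overlapping CDS exons
(terminal stop included); minus-strand models list exons in descending
genomic order and alleles are complemented onto the coding strand.  The
affected codon is `ceil(cds_pos / 3)`; reference and mutant codons are
translated with the standard genetic code (NCBI table 1; the table is a
parameter in principle but vertebrate nuclear genes need no other).
Premature stops are written HGVS-style with the `X` suffix
(e.g. `p.Cys161X`) and truncation is `protein_length - codon_index`.
Substitutions only: the candidate coding variants this workflow ends with
are substitutions, and frameshift annotation is out of scope.  A declared
reference allele that contradicts the reference sequence raises rather
than silently re-anchors.

## Pipeline

`run_pipeline` executes simulate/ingest -> QC -> GWAS -> autozygosity ->
scan -> annotate from one YAML config with per-stage sections, writing
per-stage artefacts, a markdown + JSON report and a manifest (seed,
package version, input digests).  The anchor for autozygosity mapping is
the top GWAS marker; cases are animals below the MRA case threshold
(default -20) that are homozygous at the anchor.  The scan stage takes its
region from the mapped segment, or an explicit `scan.region`, and fails
with a dependency error naming the stage otherwise.  Reports are
byte-identical under a fixed seed (no timestamps in report or manifest;
timing goes to the log).

## Problem sizes and numerical choices

The shipped tests run the generator at a few hundred founders and a few
hundred markers, the mapping experiment at n = 1500 with 600 scan + 800
GRM markers over 20 seeds, variance-component recovery at n = 1000 over
50 seeds, and the filter properties over 1000 seeded panels — sizes at
which every stochastic tolerance stated in the tests has comfortable
Monte-Carlo margin.  Numerical details: GRM eigenvalues are clipped at
zero and a matrix with eigenvalues materially below zero is rejected with
advice to add a ridge; the REML grid keeps the optimizer off flat tails;
p-values are floored at the smallest positive double; all simulation
randomness flows from `numpy.random.default_rng` seeded with
`(seed, stream)` pairs so stages are independently reproducible.
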