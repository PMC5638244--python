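# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not show. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Diploid read model

A diploid genome is a reference sequence plus a second haplotype in which
every position mutates independently with probability `het_rate` to a
uniformly chosen different base. The model is substitution-only: the
KHR/BHR arithmetic concerns SNP-like k-mer splitting, and the
mapping-route heterozygosity consumes indel *counts* as numbers rather
than simulating indels. The alphabet is strict ACGT (no N), which keeps
the k-mer counting contract simple.

Reads are single-end, of uniform length, placed uniformly over
`[0, L − R]`, drawn from either haplotype with probability 1/2. The read
count is the smallest integer whose total bases reach
`coverage × haploid_length`. Sequencing errors are substitutions at a
per-base rate: implemented by drawing the total error count from a
binomial and placing the flips uniformly, which is equivalent to
independent per-base flips up to position collisions (expected ~15
collisions per 30 Mb read set at rate 0.001, i.e. negligible). There is
no quality model, no PCR duplication, no paired-end fragment model —
qualities are constant Q40.

An important consequence for interpretation: the *k-mer* depth of a
position is the number of reads covering a full k-window, with
expectation `coverage × (R − k + 1)/R`. At coverage 30, R = 100, k = 17
that is ≈ 25.2, not 30. Spectrum peaks therefore sit near 25 and 12.6,
and only approach the base coverage for reads much longer than k.

## k-mer spectrum

k-mers are counted canonically (lexicographic minimum of the window and
its reverse complement); k must be odd so no k-mer is self-complementary,
and at most 31 so a 2-bit packing fits one 64-bit code. Counting is a
single jitted rolling pass over the reads followed by one sort of the
code array; species deeper than 10,000 accumulate in a cap bin (bounded
memory; never reached in the benchmarks). Windows containing non-ACGT
characters are rejected and tallied.

**Error cutoff** — the depth of the first local minimum scanning up from
depth 1: counts are walked while non-increasing, and at the first rise
the leftmost depth holding the prefix minimum is returned (ties break to
the lower depth; a monotone histogram returns 1). The rule is the
package's own choice; survey tools typically take an equivalent
"unique-depth" boundary without printing a definition.

**Peaks** — counts at and above the cutoff are smoothed with a centered
moving average (window 3), and local maxima whose smoothed height reaches
10% of the spectrum maximum qualify as prominent. The homozygous peak is
the qualifying maximum at the highest depth; the heterozygous peak is the
tallest qualifying maximum within [0.35, 0.65] × hom_peak, absent if
none. Each smoothed maximum is snapped to the raw argmax within the
smoothing window, since the moving average can displace a narrow peak by
one bin.

Height-based qualification (instead of topographic prominence) is a
deliberate choice: at ~25× k-mer depth the half-depth and full-depth
components overlap so much that the weaker peak rides the other's flank.
At 4% heterozygosity the homozygous peak's topographic prominence
measures ~1% of the spectrum maximum — below any noise-safe global
prominence threshold — while its height stays above a third of the
maximum. Noise cannot fabricate qualifying maxima because everywhere the
height criterion is met the spectrum's flank slopes are orders of
magnitude above counting noise (√N on bins of 10⁴–10⁵).

A physical limitation follows: at 0.5% heterozygosity under the
benchmark conditions the heterozygous component is a monotone *shoulder*
of the homozygous flank, not a local maximum, so no het peak exists to
detect and the formula route returns 0 there. Peak-ratio checks
therefore run at h ≥ 1%. Separating a 0.5% component would need higher
coverage (peak widths scale as √depth) or a mixture-model fit, which is
deliberately out of scope.

**Genome size** — genomic k-mer instances (depth ≥ cutoff) divided by
the homozygous peak depth. The integer peak depth is refined to the apex
of the parabola through the three bins around the maximum (offset
clamped to ±½ bin; no-op for an isolated bin; `refine=False` restores
plain integer division). The refinement exists because the true mean
depth is rarely integral: at depth ≈ 25.2 the ±1-bin quantization of the
mode alone moves the estimate by ~4%, while the refined estimator
measures 0.9–3.5% error across seeds on the 1 Mb benchmark.

## Heterozygosity estimators

**Formula route.** `a1` is the fraction of genomic k-mer *species*
(distinct k-mers, not instances) below the midpoint of the two peak
depths — species fractions are invariant to sequencing effort, and the
formula `KHR = (a1/2)/(2 − a1/2)`, `BHR = KHR/k` yields per-base rates
on the right scale for species fractions of order 0.5–0.9. The estimator
is exactly 0 when no het peak exists and strictly monotone in the
planted rate (measured means 0 < 0.0047 < 0.0074 < 0.011 at planted
0.005–0.04), but it compresses the scale — roughly 2–3× below the
planted rate at 1–2% heterozygosity — because the overlapping components
misassign species around the midpoint boundary. This is why the package
reports it alongside the other two routes rather than calibrating it.

**Spectrum matching.** For each grid value, one diploid genome and read
set are simulated under fixed conditions (length, coverage, read length,
error rate, k), both spectra are normalized to species-frequency
distributions over depths at or above their own error cutoffs, and the
grid value minimizing L1 distance wins (ties to the lower value;
`replicates` averages several simulations per grid point). L1 on
normalized species frequencies is robust to total-count differences
between observed and simulated runs. The benchmark (20 seed pairs,
planted h cycling {0.005, 0.01, 0.02, 0.04}, grid 0.005…0.04 step 0.005,
1 Mb, 30×, 100 bp, error 0.001) recovers the planted value within one
grid step in 100% of pairs at the seeds exercised.

**Mapping route.** `100 × (SNPs + indels)/assembly_length`, half-up
rounded; indel events count once. The published counts reproduce the
printed 0.73%, an acknowledged underestimate since the most heterozygous
regions assemble worst.

The formula and matching estimates agree within a factor of ~3 at 1–2%
heterozygosity (measured 2.1–2.7); the band widens at 4% where peak
overlap compresses `a1` further. The three estimators are reported
without adjudication.

## Assembly statistics

Nx follows the cumulative-sum convention (sort descending, return the
length where the cumulative sum first reaches x% of the total), verified
against a brute-force scan on 1,000 random lists. Percentages use
half-up decimal rounding in `Decimal` arithmetic — printed tables round
.5 up, not to even. Kosambi: `25 ln((1+2r)/(1−2r))` cM, linear (100r)
within 1% for r ≤ 0.01 and divergent toward r = 0.5. The gene-model
filter applies two independent removal rules — CDS < 150 bp, or
(ab-initio-only AND UniRef-only-hit AND FPKM < 5) — reading the source
procedure's ambiguous conjunction as: the expression rule only ever
removes models with no other evidence. Both thresholds and flags are
configurable.

## Regeneration screen

Stage axis: non-eviscerated control, then 0.5 h, 2 h, 6 h, 3 d, 5 d,
7 d, 14 d, 21 d post evisceration; the early window is 0.5 h–3 d. Fold
change is `(max over window + c)/(baseline + c)` with pseudocount
c = 0.01 (FPKM units), so a zero baseline yields large but finite folds.
The baseline defaults to the control stage; a `--baseline` option covers
the alternative reading (fold versus the first post-evisceration point).

The synthetic benchmark plants 11 genes at fold 10,000 in the early
window among 200 genes with negative-binomial noise
(`variance = mean + 0.1 × mean²`). Two quirks deserve note:

- *The screen threshold is 1,000*, a 10× margin below the planted fold
  and 100× above the ≤ 10 background folds, because baseline noise at
  dispersion 0.1 lets a planted gene's realized fold fluctuate below
  10,000 itself.
- *The benchmark screens counts, not FPKM.* Eleven genes at fold 10⁴
  among 200 dominate the realized library sizes, so FPKM normalization
  would compress the very fold it measures (a composition effect); with
  equal library sizes counts are proportional to FPKM. In a real 30,000-
  gene transcriptome the planted cluster is a small library fraction and
  FPKM screening behaves as intended.
- Baseline means are log-normal (median 50, σ = 0.5): every background
  gene is detectably expressed at control, keeping background folds at
  noise level (measured max 9.4 over 30 seeds) instead of
  pseudocount-inflated.

Recall and precision are 1.0 over 20 seeds (and over a 100-seed
robustness sweep during development). Profile clustering transforms
values to log10(value+1), takes Euclidean distances, and merges by
average linkage (UPGMA); genes are sorted by id before clustering so the
dendrogram is invariant to input row order. The three-gene worked case
(two identical profiles at (1,1), one at (10,10)) merges at heights 0
and √2(log10 11 − log10 2) = 1.0471.

## Tandem clusters

Protein homology is global-alignment identity: match +1, mismatch 0,
linear gap −1, score matrix filled with a vectorized prefix-max
recurrence, traceback deterministic (diagonal over up over left at
ties), identity = matches/alignment length. Random same-length proteins
from the 20-letter alphabet score ~0.11 ± 0.03 under this scheme, so the
0.3 detection threshold sits ~6σ above background — detection measured
zero false clusters over 20 background seeds. The scan greedily extends
a run while the next gene (allowing one intervening non-member by
default) reaches 0.3 identity to *any* current member, and emits maximal
disjoint runs of ≥ 6 members ("more than 5 repeats" read strictly). A
genome-wide cluster census depends entirely on the homology threshold
and intervening-gene tolerance chosen, so no absolute cluster count is a
benchmark quantity here — only recovery of planted clusters and the
false-positive rate on random backgrounds.

The planted-cluster generator substitutes exactly
`round((1 − identity)/2 × length)` residues per copy from a common
ancestor, so any two copies differ at most at `1 − identity` of their
residues — planted identity is a guaranteed floor, not an expectation.
Proximity clustering of point features is single-linkage chaining with a
gap threshold on one scaffold. Conserved-column reporting counts gaps in
the denominator but never the numerator.

## Codon usage

Standard genetic code only. RSCU is count over synonymous-family mean
(0 for unused families). Relative adaptiveness w pools reference counts
and divides by the family maximum, with the Sharp–Li 0.5 guard replacing
zero counts so w never annihilates a CAI. CAI is the geometric mean of w
over a gene's codons excluding methionine, tryptophan and stops (no
synonymous choice). Nc is Wright's statistic: per-family homozygosity
`F̂ = (nΣp² − 1)/(n − 1)` averaged within the 2-, 3-, 4- and 6-fold
degeneracy classes (families with n ≤ 1 or F̂ ≤ 0 excluded; a missing
3-fold class — isoleucine only — is interpolated as the 2-/4-fold mean),
then `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, clamped to [20, 61]. The
limits are exact: one codon per amino acid gives 20; uniform usage gives
E[F̂] = 1/m per m-fold family, hence 61.

Correspondence analysis converts the genes × codons RSCU matrix to a
correspondence matrix, centers by the row/column-mass outer product,
scales by square-root masses, and takes the SVD; row principal
coordinates and inertia shares are returned, with zero-usage codon
columns dropped. Axis signs are arbitrary, so the CAI–axis correlation
is reported as a magnitude, and the CAI-correlated axis is identified by
measurement rather than assumed to be the second-ranked axis. On a
bias gradient 0→1 the best axis correlates with CAI at r ≈ 0.9; on
independent random vectors (n = 1,000) the magnitude stays ≤ 0.1.

The CDS generator emits each amino acid's designated optimal codon with
probability `bias` and a uniform synonymous draw otherwise, so bias 1
forces CAI = 1 under matching reference weights and Nc = 20, and bias 0
approaches Nc = 61 for long genes.

## Problem sizes and determinism

The heterozygosity benchmarks run at 1 Mb genomes, 30× coverage, 100 bp
reads, error 0.001, k = 17 — large enough that spectrum peaks are
resolved and binomial bounds are tight, small enough that the ~220
simulated read sets of the recovery suite complete in minutes on one
core. Smaller unit fixtures (200–300 kb) exercise the same code paths;
at 200 kb the ±1-bin peak quantization alone reaches ~4% of the size
estimate, which is why the strict 5% recovery check runs at 1 Mb.
Monotonicity of the formula route averages 4 seeds per rate in the
benchmark suite and 10 seeds at 200 kb in the unit suite.

Every stochastic component takes an explicit integer seed;
`scripts/acceptance.py` derives all of its seeds from `--seed` via
`numpy` seed sequences. Ties everywhere break deterministically (lower
depth, lower grid value, lexicographic gene id, diagonal traceback).

## What the synthetic benchmarks do not show

The read simulator has no quality-dependent errors, coverage bias, or
repeats; real spectra carry repeat shoulders and GC-coverage coupling
that the error-cutoff/peak logic would face in practice. The annotation
generator plants idealized clusters (uniform-random background, exact
identity floors); real paralog detection contends with domain-level
homology and pseudogenes. The expression generator holds baselines flat
across stages, so it validates fold arithmetic and screening, not
differential-expression inference. Passing these benchmarks shows the
estimators are correct and well-behaved under their stated models, not
that the models capture every property of real survey data.
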