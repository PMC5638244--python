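# genomesurvey

Genome-survey statistics for highly heterozygous invertebrate genomes —
the computational core of a genome-project results section, reimplemented
as a tested, reusable Python library with a `survey` command-line front
end. The motivating system is a marine invertebrate (sea cucumber class)
genome project: a diploid genome around 1.6% heterozygosity, a scaffold
assembly judged by N50/N90 arithmetic, a visceral-regeneration time
course with an extraordinarily up-regulated tandem-duplicated gene
cluster, and codon-usage evidence that the cluster is highly expressed.

Everything runs end to end on synthetic data with known ground truth
generated by the package itself, so every estimator ships with a recovery
benchmark.

## What it computes

**k-mer spectrum heterozygosity** (`kmer_spectrum`, `heterozygosity`).
Reads are decomposed into canonical k-mers (k = 17 by default, odd so no
k-mer equals its own reverse complement) and the depth histogram of
distinct k-mer species is scanned for an error cutoff (first local
minimum) and two peaks: k-mers spanning heterozygous sites appear at
roughly half the depth of shared k-mers. Three estimators are reported
side by side, as survey practice does:

- *formula route*: with a1 the fraction of genomic k-mer species in the
  half-depth component,

      KHR = (a1 / 2) / (2 − a1 / 2),    BHR = KHR / k

  (KHR the k-mer-level heterozygous ratio, BHR the per-base rate,
  assuming each SNP creates k new k-mers);
- *spectrum matching*: simulate diploid read sets over a grid of
  heterozygosity values and pick the grid value whose normalized spectrum
  is closest in L1 distance;
- *mapping route*: 100 × (SNPs + indels) / assembly length from variant
  calls, which underestimates when the most heterozygous regions
  assemble worst.

A spectral genome-size estimate (genomic k-mer instances / homozygous
peak depth, with sub-bin apex refinement) completes the survey.

**Assembly continuity and completeness** (`assembly_stats`): Nx
statistics by the cumulative-sum convention, counts above thresholds,
half-up rounded percentage ratios (the rounding printed tables use), the
Kosambi map function d = 25 ln((1+2r)/(1−2r)) cM, and the standard
post-prediction gene-model filter (CDS < 150 bp, or ab-initio-only models
with FPKM < 5).

**Regeneration expression screen** (`expression`): FPKM conversion,
normalization to a housekeeping gene (tubulin-style), fold change of an
early-regeneration window (0.5 h–3 d post evisceration) against the
non-eviscerated control with a pseudocount, screening for genes above a
fold threshold (the motivating cluster exceeds 10,000-fold), and UPGMA
clustering of log10(FPKM+1) profiles.

**Tandem-duplicated gene clusters** (`tandem_clusters`): global-alignment
identity (match +1, mismatch 0, gap −1, deterministic traceback), greedy
scaffold scans for runs of ≥ 6 adjacent homologous genes tolerating one
intervening gene, proximity clustering of point features (miRNA-style),
and conserved-column reporting (e.g. the cysteines of a small
secreted-protein domain).

**Codon usage** (`codon_usage`): RSCU, CAI against a highly expressed
reference set (geometric mean of relative adaptiveness w, Sharp–Li 0.5
zero-count guard), Wright's effective number of codons
Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ clamped to [20, 61], correspondence
analysis of the genes × codons RSCU matrix, and the correlation between
CAI and the inertia axis that tracks expression-driven bias.

**Synthetic data** (`synthetic_data`): diploid genomes with a controlled
per-base heterozygosity, uniform shotgun reads at set coverage/error,
annotations with planted tandem clusters at a requested protein identity,
nine-stage regeneration count matrices with planted early up-regulation
(negative-binomial noise), and coding sequences with a tunable codon
bias — all seed-deterministic with JSON ground-truth sidecars.

## Worked example

```python
from genomesurvey.synthetic_data import (
    simulate_reference, simulate_diploid, simulate_reads)
from genomesurvey.kmer_spectrum import (
    count_kmers, detect_peaks, estimate_genome_size)
from genomesurvey.heterozygosity import (
    SimParams, estimate_het_formula, match_simulated_spectra,
    mapping_heterozygosity)

ref = simulate_reference(1_000_000, gc=0.37, seed=1)
dg = simulate_diploid(ref, het_rate=0.02, seed=2)
reads = simulate_reads(dg, coverage=30, read_length=100,
                       error_rate=0.001, seed=3)

hist = count_kmers(reads, k=17)
peaks = detect_peaks(hist)
print(peaks)
print("genome size:", estimate_genome_size(hist, peaks))

est = estimate_het_formula(hist)
print(f"formula: a1={est.a1:.3f} khr={est.khr:.4f} bhr={est.bhr:.4f}")

params = SimParams(genome_length=1_000_000, coverage=30,
                   read_length=100, error_rate=0.001)
match = match_simulated_spectra(
    hist, [0.005, 0.01, 0.015, 0.02, 0.025, 0.03], params, seed=4)
print("matching:", match.bhr)
print("mapping:", mapping_heterozygosity(5_379_554, 486_341, 804_993_085))
```

prints

```
SpectrumPeaks(error_cutoff=3, het_peak=12, hom_peak=24)
genome size: 1038466
formula: a1=0.448 khr=0.1261 bhr=0.0074
matching: 0.02
mapping: 0.73
```

Reading: error k-mers die off by depth 3; the heterozygous and
homozygous peaks sit at 12 and 24 — the half-depth signature of a diploid
spectrum (k-mer depth is coverage × (R−k+1)/R ≈ 25, not the base
coverage 30). The spectral genome size recovers the planted 1 Mb within
4%. Spectrum matching recovers the planted 2% heterozygosity exactly on
its grid, while the formula route's 0.74% illustrates why surveys report
several estimators: its a1-based statistic compresses the scale when the
two peaks overlap. The mapping route turns the published variant counts
and assembly length into the printed 0.73%.

The same library drives the `survey` CLI:

```bash
survey simulate genome --length 100000 --het-rate 0.02 --out-dir g
survey simulate reads --genome-dir g --coverage 30 --out-dir r
survey kmer-hist --k 17 --in r/reads.fastq --out hist.tsv
survey peaks --in hist.tsv
survey het formula --hist hist.tsv
survey het mapping --snps 5379554 --indels 486341 --length 804993085
survey ratio --num 28144 --den 30350
```

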