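"""Synthetic-data generators with known ground truth.

Every analysis in this package can be exercised end to end on data produced
here: diploid genomes with a controlled per-base heterozygosity, shotgun
reads at a set coverage and error rate, scaffold annotations with planted
tandem-duplicated gene clusters, a nine-stage regeneration count matrix with
planted early up-regulation, and coding sequences with a controlled codon
bias. All generators are deterministic for a fixed seed.

The diploid model is substitution-only by default: each reference position
mutates independently with probability ``het_rate`` to a uniformly chosen
different base, and the variant list is recorded as ground truth. Reads are
single-end, uniformly placed, drawn from either haplotype with probability
1/2, with independent per-base substitution errors. Counts follow a
negative-binomial model with a gene-level overdispersion parameter
(``variance = mean + dispersion * mean**2``); ``dispersion = 0`` degenerates
to rounded expected means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._encode import decode, encode

__all__ = [
    "DiploidGenome",
    "ReadSet",
    "AnnotationSet",
    "CountMatrix",
    "STAGES",
    "EARLY_WINDOW",
    "AA_ALPHABET",
    "OPTIMAL_CODONS",
    "simulate_reference",
    "simulate_diploid",
    "simulate_reads",
    "simulate_annotation",
    "simulate_expression",
    "simulate_coding_sequences",
]

#: Ordered labels of the intestinal-regeneration time course: a
#: non-eviscerated control followed by samples at 0.5 h, 2 h and 6 h, and at
#: 3, 5, 7, 14 and 21 days post evisceration (dpe).
STAGES = ("control", "0.5h", "2h", "6h", "3d", "5d", "7d", "14d", "21d")

#: The early-regeneration window (0-3 dpe) used by the up-regulation screen.
EARLY_WINDOW = ("0.5h", "2h", "6h", "3d")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DiploidGenome:
    """Two haplotypes of equal length with a recorded substitution list.

    ``variant_positions`` holds ``(position, ref_base, alt_base)`` tuples
    with 0-based positions; every listed position differs between the
    haplotypes and every unlisted position matches.
    """

    reference: str
    alt_haplotype: str
    variant_positions: list[tuple[int, str, str]]
    true_het_rate: float
    seed: int

    def __len__(self) -> int:
        return len(self.reference)

    @property
    def realized_het_rate(self) -> float:
        return len(self.variant_positions) / len(self.reference)


@dataclass
class ReadSet:
    """Simulated single-end shotgun reads of uniform length.

    Sequences are stored internally as a 2-bit code matrix (one row per
    read); the ``reads`` property materializes ``(id, sequence, quality)``
    tuples on demand. Qualities are constant Sanger+33 'I' (Q40) —
    quality-score models are deliberately out of scope.
    """

    read_length: int
    target_coverage: float
    error_rate: float
    seed: int
    matrix: np.ndarray = field(repr=False)  # (n_reads, read_length) uint8
    ids: list[str] = field(repr=False)

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    @property
    def total_bases(self) -> int:
        return int(self.matrix.size)

    @property
    def reads(self) -> list[tuple[str, str, str]]:
        qual = "I" * self.read_length
        return [
            (self.ids[i], decode(self.matrix[i]), qual)
            for i in range(self.n_reads)
        ]

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, str, str]],
        *,
        target_coverage: float = 0.0,
        error_rate: float = 0.0,
        seed: int = 0,
    ) -> "ReadSet":
        if not records:
            raise ValueError("empty read set")
        length = len(records[0][1])
        if any(len(seq) != length for _, seq, _ in records):
            raise ValueError("ReadSet requires uniform read length")
        matrix = np.vstack([encode(seq) for _, seq, _ in records])
        return cls(
            read_length=length,
            target_coverage=target_coverage,
            error_rate=error_rate,
            seed=seed,
            matrix=matrix,
            ids=[rid for rid, _, _ in records],
        )


@dataclass
class AnnotationSet:
    """Gene models on scaffolds plus their protein products.

    ``genes`` rows are ``(gene_id, scaffold_id, start, end, strand)`` with
    1-based inclusive coordinates (GFF3 convention); genes on a scaffold are
    non-overlapping and sorted by start. ``planted_clusters`` lists the
    ground-truth tandem-duplicated runs by gene id.
    """

    genes: list[tuple[str, str, int, int, str]]
    proteins: dict[str, str]
    planted_clusters: list[list[str]]

    def scaffold_genes(self, scaffold: str) -> list[tuple[str, str, int, int, str]]:
        return [g for g in self.genes if g[1] == scaffold]

    @property
    def scaffolds(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g[1], None)
        return list(seen)


@dataclass
class CountMatrix:
    """Genes x stages read counts for the regeneration time course.

    ``library_sizes`` are the realized per-stage column sums, so the
    FPKM conversion is exactly consistent with the stored counts.
    ``planted`` records the ground truth of the up-regulation screen:
    gene ids, the planted fold, and the stage window it applies to.
    """

    counts: pd.DataFrame  # genes x stages, integer
    gene_lengths: pd.Series  # bp per gene
    library_sizes: pd.Series  # per-stage totals (column sums)
    planted: dict
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random genome with the requested GC fraction.

    Bases are drawn independently with P(G) + P(C) = ``gc`` (split evenly
    within each pair); the alphabet is strictly ACGT.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return decode(codes)


def simulate_diploid(reference: str, het_rate: float, seed: int = 0) -> DiploidGenome:
    """Derive a second haplotype by independent per-base substitution.

    Each position mutates with probability ``het_rate`` to a uniformly
    chosen different base; the realized substitutions are recorded as the
    variant list (ground truth for recovery tests).
    """
    if not 0.0 <= het_rate <= 0.1:
        raise ValueError("het_rate must be within [0, 0.1]")
    ref = encode(reference)
    if (ref > 3).any():
        raise ValueError("reference must be ACGT-only")
    rng = np.random.default_rng(seed)
    hits = np.flatnonzero(rng.random(ref.size) < het_rate)
    alt = ref.copy()
    if hits.size:
        offsets = rng.integers(1, 4, size=hits.size).astype(np.uint8)
        alt[hits] = (ref[hits] + offsets) % 4
    bases = "ACGT"
    variants = [
        (int(i), bases[ref[i]], bases[alt[i]]) for i in hits
    ]
    return DiploidGenome(
        reference=reference,
        alt_haplotype=decode(alt),
        variant_positions=variants,
        true_het_rate=het_rate,
        seed=seed,
    )


def simulate_reads(
    dg: DiploidGenome,
    coverage: float,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniformly placed single-end reads from a diploid genome.

    The haplotype of each read is chosen with probability 1/2; each base is
    then flipped to a different base with probability ``error_rate``. The
    read count is the smallest number whose total bases reach
    ``coverage x haploid length`` (the last read counts in full).
    """
    length = len(dg)
    if read_length > length:
        raise ValueError("read length exceeds genome length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be within [0, 1)")
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(coverage * length / read_length)
    genome = np.concatenate([encode(dg.reference), encode(dg.alt_haplotype)])
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    hap = rng.integers(0, 2, size=n_reads)
    offset = starts + hap * length
    matrix = genome[offset[:, None] + np.arange(read_length)]
    if error_rate > 0:
        # binomial error count with uniform placement: equivalent to
        # independent per-base flips up to negligible position collisions
        n_err = rng.binomial(matrix.size, error_rate)
        if n_err:
            flat = matrix.reshape(-1)
            pos = rng.integers(0, flat.size, size=n_err)
            shifts = rng.integers(1, 4, size=n_err).astype(np.uint8)
            flat[pos] = (flat[pos] + shifts) % 4
    ids = [f"read_{i}" for i in range(n_reads)]
    return ReadSet(
        read_length=read_length,
        target_coverage=coverage,
        error_rate=error_rate,
        seed=seed,
        matrix=matrix,
        ids=ids,
    )


def _mutate_protein(base: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_subs`` distinct positions of ``base``."""
    if n_subs == 0:
        return base
    chars = list(base)
    positions = rng.choice(len(chars), size=n_subs, replace=False)
    for pos in positions:
        choices = [a for a in AA_ALPHABET if a != chars[pos]]
        chars[pos] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def simulate_annotation(
    n_scaffolds: int,
    genes_per_scaffold: int,
    cluster_specs: list[tuple[int, float]] = (),
    seed: int = 0,
    protein_length: int = 100,
) -> AnnotationSet:
    """Scaffold gene annotations with planted tandem-duplicated clusters.

    Each ``(size, identity)`` spec plants one run of ``size`` adjacent gene
    copies on its own scaffold (spec *i* goes to scaffold *i*), built by
    substituting a fixed number of residues — ``(1 - identity)/2`` of the
    protein length — in each copy of a common ancestor, so any two copies
    differ at no more than ``1 - identity`` of their residues. Background
    proteins are i.i.d. random amino acids. Gene coordinates are 1-based,
    non-overlapping and sorted, with random intergenic gaps.
    """
    if n_scaffolds <= 0 or genes_per_scaffold <= 0:
        raise ValueError("need at least one scaffold and one gene")
    cluster_specs = list(cluster_specs)
    if len(cluster_specs) > n_scaffolds:
        raise ValueError("more cluster specs than scaffolds")
    for size, identity in cluster_specs:
        if size < 2:
            raise ValueError("cluster size must be >= 2")
        if size > genes_per_scaffold:
            raise ValueError("cluster larger than genes_per_scaffold")
        if not 0.0 <= identity <= 1.0:
            raise ValueError("identity must be within [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))
    genes: list[tuple[str, str, int, int, str]] = []
    proteins: dict[str, str] = {}
    planted: list[list[str]] = []
    for s in range(n_scaffolds):
        scaffold = f"scaffold{s + 1}"
        # decide which gene indices form the planted run on this scaffold
        cluster_ids: list[str] = []
        cluster_range: range = range(0)
        if s < len(cluster_specs):
            size, identity = cluster_specs[s]
            offset = int(rng.integers(0, genes_per_scaffold - size + 1))
            cluster_range = range(offset, offset + size)
            n_subs = round((1.0 - identity) / 2.0 * protein_length)
            ancestor = "".join(aa[rng.integers(0, len(aa), size=protein_length)])
        pos = 1
        for g in range(genes_per_scaffold):
            gene_id = f"g{s + 1:02d}_{g + 1:03d}"
            if g in cluster_range:
                proteins[gene_id] = _mutate_protein(ancestor, n_subs, rng)
                cluster_ids.append(gene_id)
            else:
                proteins[gene_id] = "".join(
                    aa[rng.integers(0, len(aa), size=protein_length)]
                )
            span = 3 * protein_length + 3  # CDS plus stop
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            genes.append((gene_id, scaffold, pos, pos + span - 1, strand))
            pos += span + int(rng.integers(50, 500))
        if cluster_ids:
            planted.append(cluster_ids)
    return AnnotationSet(genes=genes, proteins=proteins, planted_clusters=planted)


def simulate_expression(
    annotation,
    stages: tuple[str, ...] = STAGES,
    upregulated: set[str] | list[str] = (),
    fold: float = 1.0,
    dispersion: float = 0.1,
    seed: int = 0,
    window: tuple[str, ...] = EARLY_WINDOW,
    baseline_mean: float = 50.0,
    baseline_sigma: float = 0.5,
) -> CountMatrix:
    """Time-course count matrix with planted early up-regulation.

    ``annotation`` may be an :class:`AnnotationSet` or a plain list of gene
    ids. Baseline expected counts are gene-specific log-normal means held
    flat across stages; genes in ``upregulated`` have their mean multiplied
    by ``fold`` within the ``window`` stages. Counts are negative-binomial
    with ``variance = mean + dispersion * mean**2``; ``dispersion = 0``
    yields rounded expected means exactly.

    The default log-normal spread (sigma 0.5 around mean 50) keeps every
    background gene detectably expressed at the control stage, so
    background fold changes stay at noise level (<= ~10) instead of being
    inflated by the pseudocount when a silent gene draws a zero control
    count.
    """
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    if dispersion < 0.0:
        raise ValueError("dispersion must be >= 0")
    gene_ids = (
        [g[0] for g in annotation.genes]
        if isinstance(annotation, AnnotationSet)
        else list(annotation)
    )
    upregulated = set(upregulated)
    unknown = upregulated - set(gene_ids)
    if unknown:
        raise ValueError(f"unknown gene ids in upregulated set: {sorted(unknown)}")
    bad_stages = set(window) - set(stages)
    if bad_stages:
        raise ValueError(f"window stages not in stage list: {sorted(bad_stages)}")
    rng = np.random.default_rng(seed)
    n_genes, n_stages = len(gene_ids), len(stages)
    base_mean = rng.lognormal(np.log(baseline_mean), baseline_sigma, size=n_genes)
    mean = np.tile(base_mean[:, None], (1, n_stages))
    up_rows = np.array([g in upregulated for g in gene_ids])
    win_cols = np.array([s in window for s in stages])
    mean[np.ix_(up_rows, win_cols)] *= fold
    if dispersion == 0.0:
        counts = np.rint(mean).astype(np.int64)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p).astype(np.int64)
    df = pd.DataFrame(counts, index=gene_ids, columns=list(stages))
    lengths = pd.Series(
        rng.integers(500, 3001, size=n_genes), index=gene_ids, name="length"
    )
    lib = df.sum(axis=0)
    return CountMatrix(
        counts=df,
        gene_lengths=lengths,
        library_sizes=lib,
        planted={
            "genes": sorted(upregulated),
            "fold": fold,
            "window": list(window),
        },
        seed=seed,
    )


# one designated "optimal" codon per amino acid (alphabetically first of the
# synonymous family under the standard code); the bias=1 limit uses these only
OPTIMAL_CODONS = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}

_SYNONYMOUS = {
    "A": ["GCA", "GCC", "GCG", "GCT"],
    "C": ["TGC", "TGT"],
    "D": ["GAC", "GAT"],
    "E": ["GAA", "GAG"],
    "F": ["TTC", "TTT"],
    "G": ["GGA", "GGC", "GGG", "GGT"],
    "H": ["CAC", "CAT"],
    "I": ["ATA", "ATC", "ATT"],
    "K": ["AAA", "AAG"],
    "L": ["CTA", "CTC", "CTG", "CTT", "TTA", "TTG"],
    "M": ["ATG"],
    "N": ["AAC", "AAT"],
    "P": ["CCA", "CCC", "CCG", "CCT"],
    "Q": ["CAA", "CAG"],
    "R": ["AGA", "AGG", "CGA", "CGC", "CGG", "CGT"],
    "S": ["AGC", "AGT", "TCA", "TCC", "TCG", "TCT"],
    "T": ["ACA", "ACC", "ACG", "ACT"],
    "V": ["GTA", "GTC", "GTG", "GTT"],
    "W": ["TGG"],
    "Y": ["TAC", "TAT"],
}


def simulate_coding_sequences(
    n: int,
    bias,
    seed: int = 0,
    n_codons: int = 300,
) -> dict[str, str]:
    """Coding sequences with a controlled synonymous codon bias.

    ``bias`` is a fraction in [0, 1], scalar or one value per sequence: each
    codon is the amino acid's designated optimal codon with probability
    ``bias`` and a uniform draw from the synonymous family otherwise, so
    ``bias = 1`` uses only optimal codons and ``bias = 0`` is uniform
    synonymous usage. Every CDS begins ATG, ends TAA, and contains no
    internal stop.
    """
    if n <= 0:
        raise ValueError("need at least one sequence")
    if n_codons < 3:
        raise ValueError("n_codons must be >= 3 (start, one codon, stop)")
    bias_arr = np.broadcast_to(np.asarray(bias, dtype=float), (n,))
    if ((bias_arr < 0) | (bias_arr > 1)).any():
        raise ValueError("bias must be within [0, 1]")
    rng = np.random.default_rng(seed)
    aa = list(AA_ALPHABET)
    out: dict[str, str] = {}
    for i in range(n):
        b = float(bias_arr[i])
        body_len = n_codons - 2
        residues = rng.integers(0, len(aa), size=body_len)
        use_opt = rng.random(body_len) < b
        codons = ["ATG"]
        for j, r in enumerate(residues):
            letter = aa[r]
            fam = _SYNONYMOUS[letter]
            if use_opt[j]:
                codons.append(OPTIMAL_CODONS[letter])
            else:
                codons.append(fam[rng.integers(0, len(fam))])
        codons.append("TAA")
        out[f"cds_{i + 1:04d}"] = "".join(codons)
    return out
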