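"""Three routes to a per-base heterozygosity estimate, reconciled in one report.

1. **Formula route** — from the k-mer spectrum: the fraction ``a1`` of
   genomic k-mer species falling in the heterozygous (half-depth) peak
   component is converted to a k-mer heterozygous ratio

       KHR = (a1 / 2) / (2 - a1 / 2)

   and then to a base heterozygous ratio BHR = KHR / k, on the assumption
   that each SNP creates k new k-mers.
2. **Spectrum matching** — simulate diploid read sets over a grid of
   heterozygosity values, build their spectra, and pick the grid value whose
   normalized species-frequency distribution is closest (L1) to the
   observed spectrum.
3. **Mapping route** — variants called against the assembly: 100 x
   (SNPs + indels) / assembly length, with half-up decimal rounding. This
   route typically underestimates when the most heterozygous regions
   assemble worst, so the three estimates are reported side by side without
   adjudication.

``a1`` here is a *species* fraction (distinct k-mers, not instances),
delimited by the midpoint between the heterozygous and homozygous peak
depths; species fractions are invariant to the total sequencing effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._round import round_half_up
from .kmer_spectrum import (
    KmerHistogram,
    SpectrumPeaks,
    count_kmers,
    detect_peaks,
    find_error_cutoff,
)
from .synthetic_data import simulate_diploid, simulate_reads, simulate_reference

__all__ = [
    "HetEstimate",
    "SimParams",
    "khr_from_a1",
    "bhr_from_khr",
    "estimate_a1",
    "estimate_het_formula",
    "match_simulated_spectra",
    "mapping_heterozygosity",
]


@dataclass
class SimParams:
    """Fixed simulation conditions for spectrum matching."""

    genome_length: int
    coverage: float
    read_length: int
    error_rate: float = 0.0
    gc: float = 0.5
    k: int = 17


@dataclass
class HetEstimate:
    """One heterozygosity estimate with its intermediate quantities.

    ``bhr`` is the per-base heterozygous fraction. ``a1``, ``khr``, ``k``
    and ``grid_step`` are populated only by the routes that define them;
    the mapping route carries none of them. ``extras`` holds the report
    payload (error cutoff, peaks, seeds, grid distances, warnings).
    """

    method: str  # "matching" | "formula" | "mapping"
    bhr: float
    a1: float | None = None
    khr: float | None = None
    k: int | None = None
    grid_step: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in {"matching", "formula", "mapping"}:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 <= self.bhr <= 1.0:
            raise ValueError("bhr must be within [0, 1]")
        if self.a1 is not None and not 0.0 <= self.a1 <= 1.0:
            raise ValueError("a1 must be within [0, 1]")


def khr_from_a1(a1: float) -> float:
    """k-mer heterozygous ratio KHR = (a1/2) / (2 - a1/2)."""
    if not 0.0 <= a1 <= 1.0:
        raise ValueError("a1 must be within [0, 1]")
    return (a1 / 2) / (2 - a1 / 2)


def bhr_from_khr(khr: float, k: int) -> float:
    """Base heterozygous ratio BHR = KHR / k (each SNP spawns k k-mers)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if khr < 0:
        raise ValueError("khr must be non-negative")
    return khr / k


def estimate_a1(hist: KmerHistogram, peaks: SpectrumPeaks) -> float:
    """Fraction of genomic k-mer species in the heterozygous component.

    Species with ``error_cutoff <= depth < boundary`` count as
    heterozygous, where the boundary is the midpoint of the two peak
    depths rounded down. Returns 0 when no heterozygous peak was found.
    """
    if peaks.het_peak is None:
        return 0.0
    boundary = (peaks.het_peak + peaks.hom_peak) // 2
    het = genomic = 0
    for depth, count in hist.bins.items():
        if depth >= peaks.error_cutoff:
            genomic += count
            if depth < boundary:
                het += count
    if genomic == 0:
        raise ValueError("no genomic k-mer species above the error cutoff")
    return het / genomic


def estimate_het_formula(hist: KmerHistogram, k: int | None = None) -> HetEstimate:
    """Full formula route: cutoff -> peaks -> a1 -> KHR -> BHR."""
    if k is None:
        k = hist.k
    cutoff = find_error_cutoff(hist)
    peaks = detect_peaks(hist, cutoff)
    a1 = estimate_a1(hist, peaks)
    khr = khr_from_a1(a1)
    bhr = bhr_from_khr(khr, k)
    return HetEstimate(
        method="formula",
        bhr=bhr,
        a1=a1,
        khr=khr,
        k=k,
        extras={
            "error_cutoff": cutoff,
            "het_peak": peaks.het_peak,
            "hom_peak": peaks.hom_peak,
            "het_peak_absent": peaks.het_peak is None,
        },
    )


def _normalized_spectrum(hist: KmerHistogram) -> np.ndarray:
    """Species-frequency distribution over depths >= the error cutoff."""
    cutoff = find_error_cutoff(hist)
    dense = hist.dense().astype(float)
    dense[:cutoff] = 0.0
    total = dense.sum()
    if total == 0:
        raise ValueError("no genomic k-mer species above the error cutoff")
    return dense / total


def _spectrum_distance(a: KmerHistogram, b: KmerHistogram) -> float:
    """L1 distance between normalized species-frequency distributions."""
    pa = _normalized_spectrum(a)
    pb = _normalized_spectrum(b)
    size = max(pa.size, pb.size)
    pa = np.pad(pa, (0, size - pa.size))
    pb = np.pad(pb, (0, size - pb.size))
    return float(np.abs(pa - pb).sum())


def match_simulated_spectra(
    observed: KmerHistogram,
    h_grid: list[float],
    sim_params: SimParams,
    seed: int = 0,
    replicates: int = 1,
) -> HetEstimate:
    """Best-fitting heterozygosity by simulated-spectrum matching.

    For each grid value h, simulates a diploid genome and shotgun reads
    under ``sim_params``, builds the k-mer histogram, and measures the L1
    distance between the normalized species-frequency distributions of the
    simulated and observed spectra. Returns the grid h with the smallest
    mean distance over ``replicates`` simulations; ties break toward the
    lower h. All simulation seeds derive from ``seed`` and are recorded.
    """
    h_grid = list(h_grid)
    if not h_grid:
        raise ValueError("empty heterozygosity grid")
    if sorted(h_grid) != h_grid:
        raise ValueError("heterozygosity grid must be sorted ascending")
    for h in h_grid:
        if not 0.0 <= h <= 0.1:
            raise ValueError("grid values must be within [0, 0.1]")
    n_sims = len(h_grid) * replicates
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_sims + 1) % (2**31)
    ref = simulate_reference(sim_params.genome_length, sim_params.gc, int(seeds[0]))
    distances = []
    for i, h in enumerate(h_grid):
        reps = []
        for r in range(replicates):
            j = i * replicates + r
            dg = simulate_diploid(ref, h, int(seeds[1 + 2 * j]))
            reads = simulate_reads(
                dg,
                sim_params.coverage,
                sim_params.read_length,
                sim_params.error_rate,
                int(seeds[2 + 2 * j]),
            )
            sim_hist = count_kmers(reads, sim_params.k)
            reps.append(_spectrum_distance(observed, sim_hist))
        distances.append(float(np.mean(reps)))
    best = int(np.argmin(distances))  # argmin ties -> lower h
    steps = np.diff(h_grid)
    return HetEstimate(
        method="matching",
        bhr=float(h_grid[best]),
        grid_step=float(steps.min()) if steps.size else None,
        extras={
            "grid": h_grid,
            "distances": distances,
            "seed": seed,
            "replicates": replicates,
        },
    )


def mapping_heterozygosity(
    n_snp: int, n_indel: int, assembly_length: int, decimals: int = 2
) -> float:
    """Percent heterozygosity from mapped-variant counts.

    100 x (SNPs + indels) / assembly length, half-up rounded to
    ``decimals``; indel events count as single variants.
    """
    if n_snp < 0 or n_indel < 0:
        raise ValueError("variant counts must be non-negative")
    if assembly_length <= 0:
        raise ValueError("assembly length must be positive")
    return round_half_up(100 * (n_snp + n_indel), assembly_length, decimals)
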