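"""Codon-usage bias: RSCU, CAI, effective number of codons, correspondence
analysis, and the CAI-axis correlation.

- RSCU (relative synonymous codon usage) is the observed codon count over
  the mean count of its synonymous family.
- CAI (codon adaptation index) is the geometric mean of per-codon relative
  adaptiveness w, where w is each codon's pooled count over the maximum in
  its family across a highly expressed reference set (typically ribosomal
  protein genes); methionine, tryptophan and stops are excluded.
- Nc (effective number of codons) is Wright's statistic: per-family
  homozygosity F = (n * sum(p_i^2) - 1) / (n - 1), averaged within
  degeneracy classes, then Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, ranging
  from 20 (one codon per amino acid) to 61 (uniform synonymous usage).
- Correspondence analysis decomposes the genes x codons RSCU matrix into
  inertia-ranked orthogonal axes; in survey practice the axis correlated
  with CAI separates highly expressed genes. Because axis rank is
  data-dependent, the CAI-correlated axis is identified explicitly rather
  than assumed to be the second.

Standard genetic code only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import pearsonr

__all__ = [
    "CodonUsageStats",
    "SYNONYMOUS_FAMILIES",
    "codon_counts",
    "rscu",
    "relative_adaptiveness",
    "cai",
    "enc",
    "correspondence_axes",
    "axis_cai_correlation",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: amino acid -> sorted synonymous codon family (standard code, DNA alphabet)
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)
for _fam in SYNONYMOUS_FAMILIES.values():
    _fam.sort()

SENSE_CODONS = sorted(c for fam in SYNONYMOUS_FAMILIES.values() for c in fam)
_SINGLE_CODONS = {fam[0] for fam in SYNONYMOUS_FAMILIES.values() if len(fam) == 1}


def _split_codons(cds: str) -> list[str]:
    """Validate a CDS and return its sense codons (trailing stop dropped)."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError("internal stop codon")
        if c not in _TABLE.forward_table:
            raise ValueError(f"invalid codon {c!r}")
    return codons


def codon_counts(cds: str) -> dict[str, int]:
    """Counts of every sense codon in one CDS (absent codons count 0)."""
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for c in _split_codons(cds):
        counts[c] += 1
    return counts


def rscu(cds: str) -> dict[str, float]:
    """Relative synonymous codon usage for every sense codon.

    Each codon's count is divided by the mean count of its synonymous
    family; families never used in the gene get 0 for all members.
    """
    counts = codon_counts(cds)
    out: dict[str, float] = {}
    for fam in SYNONYMOUS_FAMILIES.values():
        total = sum(counts[c] for c in fam)
        if total == 0:
            for c in fam:
                out[c] = 0.0
        else:
            mean = total / len(fam)
            for c in fam:
                out[c] = counts[c] / mean
    return out


def relative_adaptiveness(reference_cds_set) -> dict[str, float]:
    """Per-codon w from a pooled highly expressed reference set.

    Counts are pooled over the reference CDSs; within each synonymous
    family w = count / max count. Zero counts are replaced by 0.5 before
    division (small-sample guard), so w is always positive.
    """
    reference = list(reference_cds_set)
    if not reference:
        raise ValueError("empty reference set")
    pooled = dict.fromkeys(SENSE_CODONS, 0)
    for cds in reference:
        for codon, count in codon_counts(cds).items():
            pooled[codon] += count
    w: dict[str, float] = {}
    for fam in SYNONYMOUS_FAMILIES.values():
        guarded = {c: (pooled[c] if pooled[c] > 0 else 0.5) for c in fam}
        top = max(guarded.values())
        for c in fam:
            w[c] = guarded[c] / top
    return w


def cai(cds: str, w: dict[str, float]) -> float:
    """Geometric mean of w over the gene's codons.

    Methionine, tryptophan (single-codon families) and stops are excluded
    from the mean, as their usage carries no synonymous choice.
    """
    codons = [c for c in _split_codons(cds) if c not in _SINGLE_CODONS]
    if not codons:
        raise ValueError("no countable codons (only Met/Trp/stops)")
    logs = [np.log(w[c]) for c in codons]
    return float(np.exp(np.mean(logs)))


def enc(cds: str) -> float | None:
    """Wright's effective number of codons, clamped to [20, 61].

    Per synonymous family with n >= 2 codons observed, homozygosity
    F = (n * sum(p_i^2) - 1) / (n - 1); F values are averaged within the
    2-, 3-, 4- and 6-fold degeneracy classes (families with n <= 1, or
    with F <= 0, are excluded from their class mean), and
    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6. A missing 3-fold class is
    interpolated as the mean of the 2- and 4-fold classes; if any other
    class is missing the gene is too short to score and None is returned.
    """
    counts = codon_counts(cds)
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for fam in SYNONYMOUS_FAMILIES.values():
        size = len(fam)
        if size == 1:
            continue
        n = sum(counts[c] for c in fam)
        if n <= 1:
            continue
        p = np.array([counts[c] / n for c in fam])
        F = (n * float(np.sum(p**2)) - 1) / (n - 1)
        if F > 0:
            class_F[size].append(F)
    means = {size: np.mean(vals) for size, vals in class_F.items() if vals}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if not all(size in means for size in (2, 3, 4, 6)):
        return None
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return float(min(max(nc, 20.0), 61.0))


@dataclass
class CodonUsageStats:
    """Per-gene codon-usage summary."""

    gene_id: str
    counts: dict[str, int]
    rscu: dict[str, float]
    cai: float | None = None
    nc: float | None = None


def correspondence_axes(
    rscu_matrix: pd.DataFrame, n_axes: int = 4
) -> tuple[pd.DataFrame, np.ndarray]:
    """Correspondence analysis of a genes x codons RSCU matrix.

    The matrix is converted to a correspondence matrix, centered by the
    outer product of row and column masses, scaled by the square-root
    masses, and decomposed by SVD. Returns the first ``n_axes`` principal
    row (gene) coordinates and each retained axis's share of the total
    inertia. Columns (codons) with zero total usage are dropped; a
    rank-0 centered matrix yields zero axes.
    """
    if rscu_matrix.shape[0] < 2:
        raise ValueError("correspondence analysis needs at least two genes")
    values = rscu_matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("matrix must be non-negative")
    keep_cols = values.sum(axis=0) > 0
    values = values[:, keep_cols]
    if (values.sum(axis=1) <= 0).any():
        raise ValueError("every gene needs positive total usage")
    P = values / values.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, s, _Vt = np.linalg.svd(S, full_matrices=False)
    significant = s > 1e-12
    s = s[significant]
    U = U[:, significant]
    n_axes = min(n_axes, s.size)
    inertia = s**2
    shares = inertia[:n_axes] / inertia.sum() if inertia.size else np.empty(0)
    coords = (U[:, :n_axes] * s[:n_axes]) / np.sqrt(r)[:, None]
    frame = pd.DataFrame(
        coords,
        index=rscu_matrix.index,
        columns=[f"axis{i + 1}" for i in range(n_axes)],
    )
    return frame, shares


def axis_cai_correlation(axis_coordinates, cai_values) -> float:
    """Pearson correlation between one CA axis and CAI.

    The decomposition leaves each axis's sign arbitrary, so the axis is
    oriented to make the correlation non-negative; the returned value is
    therefore the magnitude of the Pearson coefficient.
    """
    x = np.asarray(axis_coordinates, dtype=float)
    y = np.asarray(cai_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    return float(abs(pearsonr(x, y).statistic))
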