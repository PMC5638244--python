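"""Tandem-duplicated gene clusters, proximity clusters, conserved columns.

A tandem cluster is a run of adjacent genes on one scaffold whose protein
products are mutually homologous; here homology is global-alignment
identity (match +1, mismatch 0, linear gap -1) against any current member,
with a configurable tolerance for intervening non-members. Proximity
clustering chains point features (miRNA loci and the like) whose
consecutive gaps stay within a window. Conserved-column reporting scans a
provided alignment for residues (canonically the cysteines of a small
secreted-protein domain) present in at least a given fraction of rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .synthetic_data import AnnotationSet

__all__ = [
    "TandemCluster",
    "pairwise_identity",
    "detect_tandem_clusters",
    "cluster_features_by_proximity",
    "conserved_columns",
]


@dataclass
class TandemCluster:
    """A detected run of adjacent homologous genes on one scaffold."""

    scaffold: str
    members: list[str]  # gene ids in genomic order
    repeat_count: int
    mean_pairwise_identity: float


def _align_matrix(a: str, b: str) -> np.ndarray:
    """Needleman-Wunsch score matrix (match +1, mismatch 0, gap -1).

    Rows are filled with a prefix-max scan so the quadratic table costs a
    handful of vector operations per row.
    """
    n, m = len(a), len(b)
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    a_arr = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0] = -np.arange(m + 1)
    offsets = np.arange(m + 1)
    for i in range(1, n + 1):
        match = (b_arr == a_arr[i - 1]).astype(np.int64)  # mismatch scores 0
        D = np.empty(m + 1, dtype=np.int64)
        D[0] = -i
        D[1:] = np.maximum(H[i - 1, :-1] + match, H[i - 1, 1:] - 1)
        # H[i, j] = max_{t <= j} (D[t] - (j - t)) via a running maximum
        H[i] = np.maximum.accumulate(D + offsets) - offsets
    return H


def pairwise_identity(protein_a: str, protein_b: str) -> float:
    """Global-alignment identity: matches / alignment length.

    Traceback is deterministic, preferring diagonal over up over left at
    score ties, so identical inputs always yield identical identities.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty sequence")
    H = _align_matrix(protein_a, protein_b)
    i, j = len(protein_a), len(protein_b)
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            is_match = protein_a[i - 1] == protein_b[j - 1]
            if H[i, j] == H[i - 1, j - 1] + (1 if is_match else 0):
                matches += is_match
                i, j = i - 1, j - 1
                columns += 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


def detect_tandem_clusters(
    annotation: AnnotationSet,
    min_repeats: int = 6,
    min_identity: float = 0.3,
    max_intervening: int = 1,
) -> list[TandemCluster]:
    """Scan each scaffold's gene order for runs of duplicated genes.

    A run greedily extends while the next gene — allowing up to
    ``max_intervening`` consecutively skipped non-members — reaches
    ``min_identity`` to any current member. Maximal runs with at least
    ``min_repeats`` members are emitted; emitted clusters are disjoint and
    members are listed in genomic order. The default ``min_repeats = 6``
    targets clusters of more than five repeats.
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    clusters: list[TandemCluster] = []
    cache: dict[tuple[str, str], float] = {}

    def ident(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = pairwise_identity(annotation.proteins[key[0]], annotation.proteins[key[1]])
        return cache[key]

    for scaffold in annotation.scaffolds:
        genes = sorted(annotation.scaffold_genes(scaffold), key=lambda g: g[2])
        ids = [g[0] for g in genes]
        pos = 0
        n = len(ids)
        while pos < n:
            members = [pos]
            skipped = 0
            q = pos + 1
            while q < n:
                if any(ident(ids[q], ids[m]) >= min_identity for m in members):
                    members.append(q)
                    skipped = 0
                else:
                    skipped += 1
                    if skipped > max_intervening:
                        break
                q += 1
            if len(members) >= min_repeats:
                member_ids = [ids[m] for m in members]
                idents = [
                    ident(x, y) for x, y in combinations(member_ids, 2)
                ]
                clusters.append(
                    TandemCluster(
                        scaffold=scaffold,
                        members=member_ids,
                        repeat_count=len(member_ids),
                        mean_pairwise_identity=float(np.mean(idents)),
                    )
                )
                pos = members[-1] + 1
            else:
                pos += 1
    return clusters


def cluster_features_by_proximity(
    positions: list[tuple[str, int]],
    max_gap: int,
    min_size: int = 2,
) -> list[list[tuple[str, int]]]:
    """Single-linkage chains of nearby point features on one scaffold.

    Features on the same scaffold whose consecutive coordinate gaps are at
    most ``max_gap`` join one chain; chains with at least ``min_size``
    members are returned, members sorted by coordinate.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    ordered = sorted(positions, key=lambda p: (p[0], p[1]))
    clusters: list[list[tuple[str, int]]] = []
    chain: list[tuple[str, int]] = []
    for feat in ordered:
        if chain and feat[0] == chain[-1][0] and feat[1] - chain[-1][1] <= max_gap:
            chain.append(feat)
        else:
            if len(chain) >= min_size:
                clusters.append(chain)
            chain = [feat]
    if len(chain) >= min_size:
        clusters.append(chain)
    return clusters


def conserved_columns(
    alignment: list[str],
    residue: str = "C",
    min_fraction: float = 1.0,
) -> list[int]:
    """Alignment columns where ``residue`` reaches ``min_fraction`` of rows.

    Gaps count in the denominator (total rows) but never in the numerator,
    so a column must carry the residue in at least ``min_fraction`` of all
    sequences, gapped or not. Returns 0-based column indices.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    if not alignment:
        return []
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("ragged alignment")
    n_rows = len(alignment)
    hits = []
    for col in range(width):
        count = sum(1 for row in alignment if row[col] == residue)
        if count / n_rows >= min_fraction:
            hits.append(col)
    return hits
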