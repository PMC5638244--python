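"""FPKM conversion, housekeeping normalization, the early-regeneration
up-regulation screen, and average-linkage profile clustering.

The screen mirrors a time-course analysis of visceral regeneration: fold
change of each gene is the maximum expression over an early-stage window
(0-3 days post evisceration by default) against the non-eviscerated
control baseline, with a small pseudocount guarding zero baselines.
Profiles are clustered on Euclidean distance of log10(FPKM + 1) with
average linkage (UPGMA), exactly the transform used for regeneration
heatmaps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .synthetic_data import EARLY_WINDOW, STAGES, CountMatrix

__all__ = [
    "STAGES",
    "EARLY_WINDOW",
    "fpkm",
    "fpkm_matrix",
    "relative_to_housekeeping",
    "fold_change",
    "screen_upregulated",
    "hcluster_profiles",
]


def fpkm(count: float, gene_length: int, library_size: int) -> float:
    """Fragments per kilobase per million mapped fragments:
    count x 1e9 / (gene_length x library_size)."""
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count * 1e9 / (gene_length * library_size)


def fpkm_matrix(counts: CountMatrix | pd.DataFrame, gene_lengths=None, library_sizes=None) -> pd.DataFrame:
    """Convert a count matrix (genes x stages) to FPKM.

    Accepts a :class:`~genomesurvey.synthetic_data.CountMatrix` (lengths
    and library sizes taken from the object) or a plain DataFrame with
    explicit ``gene_lengths`` (bp per gene) and ``library_sizes`` (total
    fragments per stage).
    """
    if isinstance(counts, CountMatrix):
        df = counts.counts
        gene_lengths = counts.gene_lengths
        library_sizes = counts.library_sizes
    else:
        df = counts
        if gene_lengths is None or library_sizes is None:
            raise ValueError("plain DataFrames need gene_lengths and library_sizes")
    lengths = pd.Series(gene_lengths).reindex(df.index)
    libs = pd.Series(library_sizes).reindex(df.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("every stage needs a positive library size")
    return df.mul(1e9).div(lengths, axis=0).div(libs, axis=1)


def relative_to_housekeeping(matrix: pd.DataFrame, housekeeping_id: str) -> pd.DataFrame:
    """Divide every gene's value at each stage by the housekeeping gene's
    value at that stage."""
    if housekeeping_id not in matrix.index:
        raise KeyError(f"housekeeping gene {housekeeping_id!r} not in matrix")
    reference = matrix.loc[housekeeping_id]
    if (reference <= 0).any():
        raise ValueError("housekeeping gene must be positive at every stage")
    return matrix.div(reference, axis=1)


def fold_change(
    matrix: pd.DataFrame,
    baseline_stage: str = "control",
    window_stages=EARLY_WINDOW,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Per-gene fold: (max over window + pseudocount) / (baseline + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if baseline_stage not in matrix.columns:
        raise KeyError(f"unknown baseline stage {baseline_stage!r}")
    missing = [s for s in window_stages if s not in matrix.columns]
    if missing:
        raise KeyError(f"unknown window stages: {missing}")
    window_max = matrix[list(window_stages)].max(axis=1)
    baseline = matrix[baseline_stage]
    result = (window_max + pseudocount) / (baseline + pseudocount)
    result.name = "fold"
    return result


def screen_upregulated(
    matrix: pd.DataFrame,
    threshold_fold: float = 10_000.0,
    baseline_stage: str = "control",
    window_stages=EARLY_WINDOW,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Genes whose early-window fold change reaches the threshold.

    Returns the qualifying genes as a Series of folds sorted descending
    (gene id as index); empty input yields an empty Series.
    """
    if matrix.empty:
        return pd.Series(dtype=float, name="fold")
    folds = fold_change(matrix, baseline_stage, window_stages, pseudocount)
    hits = folds[folds >= threshold_fold]
    return hits.sort_values(ascending=False, kind="stable")


def hcluster_profiles(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """UPGMA dendrogram of expression profiles.

    Values are transformed to log10(value + 1); pairwise Euclidean
    distances feed average-linkage agglomeration. Genes are ordered
    lexicographically by id before clustering so the merge list and leaf
    order are invariant to the input row order (ties resolved by gene id).

    Returns ``(merges, leaf_order)`` where ``merges`` is the (n-1) x 4
    linkage matrix (members merged, height, cluster size) over gene
    indices in the sorted order, and ``leaf_order`` lists gene ids left to
    right.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least two genes")
    ordered = matrix.sort_index(kind="stable")
    values = np.log10(ordered.to_numpy(dtype=float) + 1.0)
    merges = linkage(pdist(values, metric="euclidean"), method="average")
    order = [ordered.index[i] for i in leaves_list(merges)]
    return merges, order
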