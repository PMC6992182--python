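"""Hierarchical clustering of species on the five-index matrix.

Species are agglomerated on Euclidean distance over the five nutritional
quality indices (n-6/n-3, P/S, IA, IT, HH).  Because the indices live on
different scales (n-6/n-3 around 0.1-0.5, HH around 0.6-1.4), columns are
z-scored by default before clustering; the flag is recorded on the matrix.

A k-group cut labels groups 1..k in order of increasing composite quality
(mean z-score of HH and P/S minus mean z-score of IA, IT and n-6/n-3), so
group k is always the nutritionally most desirable — the ordering used when
reading the study's four-group partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .indices import INDEX_COLUMNS

__all__ = [
    "IndexMatrix",
    "ClusterResult",
    "DegenerateScalingError",
    "build_index_matrix",
    "cluster",
    "cut_groups",
    "export_heatmap",
    "LINKAGES",
]

LINKAGES = ("complete", "average", "ward")

#: indices where larger is nutritionally better / worse
_GOOD = ("hh", "ps_ratio")
_BAD = ("ia", "it", "n6_n3_ratio")


class DegenerateScalingError(ValueError):
    """A column has zero variance and cannot be z-scored."""


@dataclass(frozen=True)
class IndexMatrix:
    """Species-by-index matrix, optionally column z-scored (sample SD)."""

    species: list[str]
    columns: list[str]
    values: np.ndarray
    scaled: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.columns)


@dataclass(frozen=True)
class ClusterResult:
    """Agglomeration output: merge tree, display leaf order, k-cuts."""

    merge_tree: np.ndarray  # scipy linkage matrix, rows (a, b, height, size)
    leaf_order: list[int]
    assignment_at_k: dict[int, dict[str, int]] = field(default_factory=dict)


def build_index_matrix(indices_table: pd.DataFrame, scale: bool = True) -> IndexMatrix:
    """Index table (species rows, five index columns) -> clustering matrix.

    With ``scale`` on, each column is z-scored with the sample (n-1) SD;
    a zero-variance column raises :class:`DegenerateScalingError`.
    """
    df = indices_table[INDEX_COLUMNS].astype(float)
    if len(df) < 2:
        raise ValueError("need at least two species")
    values = df.to_numpy(copy=True)
    if scale:
        sd = values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [c for c, s in zip(INDEX_COLUMNS, sd) if s == 0]
            raise DegenerateScalingError(f"zero-variance columns: {bad}")
        values = (values - values.mean(axis=0)) / sd
    return IndexMatrix(
        species=list(df.index), columns=list(df.columns), values=values, scaled=scale
    )


def cluster(
    matrix: IndexMatrix, linkage: str = "complete", metric: str = "euclidean"
) -> ClusterResult:
    """Agglomerative clustering of the matrix rows.

    SciPy's agglomeration breaks distance ties by the lowest pair index, so
    the merge tree is deterministic for a fixed input ordering.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(matrix.species) < 2:
        raise ValueError("need at least two species")
    dist = pdist(matrix.values, metric=metric)
    tree = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(tree).tolist()
    return ClusterResult(merge_tree=tree, leaf_order=order)


def cut_groups(matrix: IndexMatrix, result: ClusterResult, k: int) -> dict[str, int]:
    """Cut the tree into k groups, numbered 1..k by increasing quality.

    The composite quality of a group is the mean z-score of HH and P/S
    minus the mean z-score of IA, IT and n-6/n-3 over its members (z-scores
    recomputed here if the matrix is unscaled).
    """
    if not 1 <= k <= len(matrix.species):
        raise ValueError(f"k={k} outside [1, {len(matrix.species)}]")
    raw = hierarchy.fcluster(result.merge_tree, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise ValueError(f"cut produced {len(set(raw))} groups, wanted {k}")

    z = matrix.values
    if not matrix.scaled:
        sd = z.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=0)) / sd
    col = {c: i for i, c in enumerate(matrix.columns)}
    good = z[:, [col[c] for c in _GOOD]].mean(axis=1)
    bad = z[:, [col[c] for c in _BAD]].mean(axis=1)
    quality = good - bad

    scores = {g: float(quality[raw == g].mean()) for g in set(raw)}
    ranking = {g: rank + 1 for rank, g in enumerate(sorted(scores, key=scores.get))}
    assignment = {sp: ranking[g] for sp, g in zip(matrix.species, raw)}
    result.assignment_at_k[k] = assignment
    return assignment


def export_heatmap(
    matrix: IndexMatrix,
    result: ClusterResult,
    path: Union[str, Path, IO[str]],
    image_path: Union[str, Path, None] = None,
) -> None:
    """Write the leaf-ordered matrix as TSV; optionally render a heatmap PNG.

    The TSV (species rows in dendrogram leaf order, the five index columns)
    is the testable artifact; the raster image is a convenience.
    """
    ordered = matrix.to_frame().iloc[result.leaf_order]
    ordered.to_csv(path, sep="\t", index_label="species")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import seaborn as sns

        grid = sns.clustermap(
            matrix.to_frame(),
            row_linkage=result.merge_tree,
            col_cluster=False,
            cmap="vlag",
            center=0 if matrix.scaled else None,
        )
        grid.savefig(image_path, dpi=150)
        import matplotlib.pyplot as plt

        plt.close(grid.figure)
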