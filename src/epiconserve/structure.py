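"""Sample-level exploratory structure: correlation clustering, PCA, QC.

These are the routine "does the dataset hang together" analyses run before
any cross-species statistics: a Pearson correlation heatmap with
average-linkage clustering of the samples, a PCA variance decomposition,
and a correlation-based replicate QC that flags samples which do not agree
with their own group (the situation that forces dropping a poor-quality
embryo sample from DE analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .expression import ExpressionMatrix


@dataclass
class StructureResult:
    """Correlation/clustering and PCA summaries of one matrix."""

    correlation: pd.DataFrame | None = None
    linkage: np.ndarray | None = None          # scipy linkage matrix
    leaf_order: list[str] = field(default_factory=list)
    variance_fractions: np.ndarray | None = None
    scores: pd.DataFrame | None = None         # samples x PCs
    excluded: list[tuple[str, str]] = field(default_factory=list)


def correlation_cluster(matrix: ExpressionMatrix) -> StructureResult:
    """Pairwise Pearson correlation of samples + average-linkage dendrogram.

    Correlations use pairwise-complete genes (a gene missing in one sample is
    dropped only from pairs involving that sample).  Clustering is
    average-linkage agglomeration on the distance 1 - r.
    """
    if matrix.data.shape[1] < 2:
        raise ValidationError("need >= 2 samples to correlate")
    sds = matrix.data.std(axis=0, ddof=0)
    flat = sds.index[(sds == 0) | sds.isna()].tolist()
    if flat:
        raise ValidationError(f"zero-variance sample(s): {flat}")
    corr = matrix.data.corr(method="pearson")  # pairwise complete
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    return StructureResult(
        correlation=corr, linkage=link,
        leaf_order=[matrix.data.columns[i] for i in order])


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string.

    Branch lengths are the height differences between a node and its
    parent merge, so cophenetic distances are preserved.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    heights.update({n + k: float(linkage[k][2]) for k in range(len(linkage))})

    def node(i: int, parent_height: float) -> str:
        branch = max(parent_height - heights[i], 0.0)
        if i < n:
            return f"{labels[i]}:{branch:.6g}"
        row = linkage[i - n]
        left = node(int(row[0]), heights[i])
        right = node(int(row[1]), heights[i])
        return f"({left},{right}):{branch:.6g}"

    root_id = n + len(linkage) - 1
    return node(root_id, heights[root_id]) + ";"


def pca(matrix: ExpressionMatrix, center: bool = True,
        scale: bool = False) -> StructureResult:
    """SVD-based PCA of samples in gene space.

    Rows of the decomposed array are samples, columns genes (complete-case).
    Variance fractions are singular values squared over their total, so they
    sum to one over all retained components.
    """
    cc = matrix.complete_cases()
    if cc.data.shape[0] < 1:
        raise ValidationError("no complete-case genes for PCA")
    if cc.data.shape[1] < 2:
        raise ValidationError("need >= 2 samples for PCA")
    x = cc.data.to_numpy(dtype=float).T  # samples x genes
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=0, keepdims=True)
        x = x / np.where(sd == 0, 1.0, sd)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s ** 2))
    frac = s ** 2 / total if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        u * s, index=cc.data.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))])
    return StructureResult(variance_fractions=frac, scores=scores)


def flag_outliers(matrix: ExpressionMatrix,
                  min_median_r: float = 0.7) -> StructureResult:
    """Flag samples whose median within-group correlation is poor.

    Groups are (species, stage_or_condition).  A sample is excluded iff the
    median of its Pearson correlations with same-group peers falls below
    ``min_median_r``.  Singleton groups are never excluded (no peers); they
    are reported with reason ``"singleton group"`` but not flagged.
    """
    res = correlation_cluster(matrix)
    corr = res.correlation
    excluded: list[tuple[str, str]] = []
    meta = matrix.samples
    for sid in matrix.sample_ids:
        grp = meta[(meta["species"] == meta.loc[sid, "species"])
                   & (meta["stage_or_condition"]
                      == meta.loc[sid, "stage_or_condition"])].index
        peers = [s for s in grp if s != sid]
        if not peers:
            continue
        med = float(np.median(corr.loc[sid, peers]))
        if med < min_median_r:
            excluded.append(
                (sid, f"median within-group r {med:.3f} < {min_median_r}"))
    res.excluded = excluded
    return res
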