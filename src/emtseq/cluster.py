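"""Hierarchical clustering with permutation significance.

Two analyses share this machinery: clustering of a signed TF–target
association matrix (genes × TFs, entries +1/−1/0 for up-/down-regulated
targets) and clustering of row-standardized time-course expression.
Agglomeration uses Euclidean distances with either Ward.D2 linkage
(squared-distance updates, square-root heights) or average linkage.

Significance of the observed dendrogram is assessed by comparing the
variance, skewness and kurtosis of its merge heights with those from
``B`` column-wise permutations of the matrix (each column shuffled
independently, destroying row structure while preserving marginals).
Empirical p-values are ``(r + 1)/(B + 1)`` where ``r`` counts null
statistics at least as extreme in the upper tail, so the minimum
attainable p is ``1/(B + 1)``.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterSignificance",
    "zscore_rows",
    "hcluster",
    "cut_dendrogram",
    "permutation_significance",
    "tf_target_matrix",
]

_LINKAGES = {"ward.d2": "ward", "average": "average"}


@dataclass
class Dendrogram:
    """An agglomeration result: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass
class ClusterSignificance:
    """Observed merge-height statistics and their permutation p-values."""

    observed: dict[str, float]
    null_distributions: dict[str, np.ndarray]
    p_values: dict[str, float]
    n_permutations: int


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, population sd 1; constant rows are
    dropped with a warning."""
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 columns")
    values = matrix.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd (ddof=0)
    constant = sd[:, 0] < 1e-12
    if constant.any():
        log.warning("dropping %d constant rows before z-scoring",
                    int(constant.sum()))
    z = (values[~constant] - mean[~constant]) / sd[~constant]
    return pd.DataFrame(
        z, index=matrix.index[~constant], columns=matrix.columns
    )


def hcluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    metric: str = "euclidean",
    linkage: str = "ward.d2",
) -> Dendrogram:
    """Agglomerative clustering of rows or columns.

    ``ward.d2`` follows the convention in which the Lance-Williams
    recursion runs on squared Euclidean distances and reported heights
    are their square roots; ``average`` is UPGMA.
    """
    if linkage not in _LINKAGES:
        raise ValueError(
            f"unknown linkage {linkage!r}; expected one of {sorted(_LINKAGES)}"
        )
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix.to_numpy(float)
    labels = list(matrix.index if axis == "rows" else matrix.columns)
    if axis == "columns":
        data = data.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(data), method=_LINKAGES[linkage])
    return Dendrogram(linkage=Z, labels=[str(x) for x in labels],
                      method=linkage)


def _letter_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def cut_dendrogram(d: Dendrogram, k: int) -> pd.Series:
    """Cut into exactly ``k`` flat clusters; labels A, B, C… assigned in
    leaf order so the first leaf always belongs to cluster A."""
    if not 1 <= k <= d.n_leaves:
        raise ValueError(f"k={k} out of range 1..{d.n_leaves}")
    raw = hierarchy.fcluster(d.linkage, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(d.linkage)
    relabel: dict[int, str] = {}
    letters = _letter_labels(k)
    for leaf in order:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = letters[len(relabel)]
    return pd.Series([relabel[c] for c in raw], index=d.labels)


def _height_stats(heights: np.ndarray) -> dict[str, float]:
    """Variance, skewness, kurtosis of merge heights, bias-uncorrected
    moment definitions (kurtosis is the raw m4/m2^2, not excess)."""
    m = heights.mean()
    dev = heights - m
    m2 = np.mean(dev**2)
    if m2 < 1e-300:
        return {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    return {
        "variance": float(m2),
        "skewness": float(np.mean(dev**3) / m2**1.5),
        "kurtosis": float(np.mean(dev**4) / m2**2),
    }


def permutation_significance(
    matrix: pd.DataFrame,
    axis: str = "rows",
    linkage: str = "ward.d2",
    B: int = 1000,
    seed: int = 0,
) -> ClusterSignificance:
    """Upper-tail permutation test of clustering structure.

    Each of the ``B`` null matrices permutes every column independently;
    the merge-height variance, skewness and kurtosis of the null
    dendrograms form the reference distributions.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = _height_stats(hcluster(matrix, axis, "euclidean", linkage).heights)
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(float)
    nulls = {name: np.empty(B) for name in observed}
    perm = pd.DataFrame(
        np.empty_like(values), index=matrix.index, columns=matrix.columns
    )
    for b in range(B):
        shuffled = values.copy()
        for j in range(values.shape[1]):
            rng.shuffle(shuffled[:, j])
        perm.iloc[:, :] = shuffled
        stats_b = _height_stats(
            hcluster(perm, axis, "euclidean", linkage).heights
        )
        for name, value in stats_b.items():
            nulls[name][b] = value
    p_values = {
        name: float(
            (np.sum(nulls[name] >= observed[name] - 1e-12) + 1) / (B + 1)
        )
        for name in observed
    }
    return ClusterSignificance(
        observed=observed,
        null_distributions=nulls,
        p_values=p_values,
        n_permutations=B,
    )


def tf_target_matrix(
    up_genes: set[str],
    down_genes: set[str],
    experiment_targets: dict[str, set[str]],
) -> pd.DataFrame:
    """Signed TF–target association matrix for topology clustering.

    Rows are DEGs, columns TF experiments; entry +1 if the gene is an
    up-regulated target of the experiment, −1 if a down-regulated
    target, 0 otherwise.  Genes targeted by no experiment are dropped.
    """
    overlap = up_genes & down_genes
    if overlap:
        raise ValueError(f"{len(overlap)} genes in both up and down sets")
    genes = sorted(up_genes | down_genes)
    cols = sorted(experiment_targets)
    M = np.zeros((len(genes), len(cols)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, exp in enumerate(cols):
        for g in experiment_targets[exp]:
            i = gene_pos.get(g)
            if i is None:
                continue
            M[i, j] = 1.0 if genes[i] in up_genes else -1.0
    df = pd.DataFrame(M, index=genes, columns=cols)
    nonzero = (df != 0).any(axis=1)
    return df.loc[nonzero]
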