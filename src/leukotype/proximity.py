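"""Expression proximity analysis for double-driver samples.

When one sample carries two subtype-defining drivers, which expression
program dominates?  The sample is analyzed together with all members of the
two candidate subtypes: PCA is fit on the top 600 variable genes of that
sample set (centred, unscaled), each subtype's centroid is the mean
(PC1, PC2) of its members excluding the query sample, and the query's
Euclidean distance to each centroid quantifies proximity — the nearer
subtype is the dominant program.  Ward-criterion hierarchical clustering
(Ward.D2 on Euclidean distances) of the same submatrix provides the
unsupervised cross-check.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

DEFAULT_N_VARIABLE_GENES = 600
TIE_TOLERANCE = 1e-12


class ProximityError(ValueError):
    """Invalid proximity-analysis request."""


@dataclass
class ProximityResult:
    sample_id: str
    subtype_a: str
    subtype_b: str
    distance_to_a: float
    distance_to_b: float
    dominant: str  # subtype label or "indeterminate" on a tie
    sample_pc: tuple[float, float]
    centroid_a: tuple[float, float]
    centroid_b: tuple[float, float]


def top_variable_genes(matrix: pd.DataFrame,
                       n: int = DEFAULT_N_VARIABLE_GENES,
                       log_transform: bool = True) -> list[str]:
    """The n most variable genes (rows) across samples (columns).

    Variance is computed on log1p-transformed values by default (expression
    dispersion is scale-dependent); ties break deterministically by gene
    identifier.  Constant genes rank last by construction.
    """
    if n > len(matrix):
        raise ProximityError(f"requested {n} genes from a {len(matrix)}-gene matrix")
    values = matrix.to_numpy(dtype=float)
    if log_transform:
        values = np.log1p(np.maximum(values, 0.0))
    var = pd.Series(values.var(axis=1, ddof=1), index=matrix.index)
    order = sorted(matrix.index, key=lambda g: (-var[g], str(g)))
    return list(order[:n])


def subtype_proximity(sample_id: str, matrix: pd.DataFrame,
                      annotations: pd.Series | pd.DataFrame,
                      subtype_a: str, subtype_b: str,
                      n_genes: int = DEFAULT_N_VARIABLE_GENES,
                      log_transform: bool = True) -> ProximityResult:
    """Distance of one sample to two subtype centroids in PC1/PC2 space.

    ``matrix`` is genes x samples; ``annotations`` maps sample id ->
    subtype.  The involved set is the query plus all annotated members of
    the two subtypes; PCA (2 components, centred, unscaled) is fit on the
    involved samples' top-variable-gene submatrix.  The query is excluded
    from its own subtype's centroid to avoid self-attraction.  Distance
    ties within machine precision are reported as "indeterminate".
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = annotations.set_index("sample")["subtype"]
    if sample_id not in matrix.columns:
        raise ProximityError(f"sample {sample_id!r} absent from matrix")
    members = {s: [c for c in annotations.index
                   if annotations[c] == s and c != sample_id
                   and c in matrix.columns]
               for s in (subtype_a, subtype_b)}
    for s, m in members.items():
        if len(m) < 2:
            raise ProximityError(f"subtype {s!r} has fewer than 2 members")
    involved = [sample_id] + members[subtype_a] + members[subtype_b]
    if len(involved) < 3:
        raise ProximityError("need at least 3 samples for PCA")
    genes = top_variable_genes(matrix[involved],
                               min(n_genes, len(matrix)),
                               log_transform=log_transform)
    sub = matrix.loc[genes, involved].to_numpy(dtype=float).T
    if log_transform:
        sub = np.log1p(np.maximum(sub, 0.0))
    n_comp = min(2, sub.shape[0] - 1, sub.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(sub)
    if pcs.shape[1] < 2:  # degenerate: pad PC2 with zeros
        pcs = np.hstack([pcs, np.zeros((pcs.shape[0], 2 - pcs.shape[1]))])
    coords = pd.DataFrame(pcs[:, :2], index=involved, columns=["PC1", "PC2"])
    sample_pc = coords.loc[sample_id].to_numpy()
    cent_a = coords.loc[members[subtype_a]].mean().to_numpy()
    cent_b = coords.loc[members[subtype_b]].mean().to_numpy()
    d_a = float(np.linalg.norm(sample_pc - cent_a))
    d_b = float(np.linalg.norm(sample_pc - cent_b))
    if abs(d_a - d_b) <= TIE_TOLERANCE * max(1.0, d_a, d_b):
        dominant = "indeterminate"
    else:
        dominant = subtype_a if d_a < d_b else subtype_b
    return ProximityResult(sample_id=sample_id, subtype_a=subtype_a,
                           subtype_b=subtype_b, distance_to_a=d_a,
                           distance_to_b=d_b, dominant=dominant,
                           sample_pc=tuple(sample_pc),
                           centroid_a=tuple(cent_a), centroid_b=tuple(cent_b))


def ward_cluster(matrix: pd.DataFrame,
                 n_genes: int | None = DEFAULT_N_VARIABLE_GENES,
                 log_transform: bool = True
                 ) -> tuple[np.ndarray, list[str]]:
    """Ward-criterion agglomerative clustering of samples.

    Operates on the top-variable-gene submatrix with Euclidean distances
    between raw observations — the Ward.D2 convention, under which merge
    heights are non-decreasing.  Returns (linkage matrix, sample labels).
    """
    if matrix.shape[1] < 2:
        raise ProximityError("clustering requires at least 2 samples")
    genes = (top_variable_genes(matrix, min(n_genes, len(matrix)),
                                log_transform=log_transform)
             if n_genes else list(matrix.index))
    sub = matrix.loc[genes].to_numpy(dtype=float).T
    if log_transform:
        sub = np.log1p(np.maximum(sub, 0.0))
    Z = linkage(sub, method="ward", metric="euclidean")
    return Z, list(matrix.columns)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage tree to a Newick string (heights as branch lengths)."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
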