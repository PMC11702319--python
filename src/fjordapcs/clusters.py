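"""Ward clustering of parameters in rotated loading space.

Parameters sharing a dominant physicochemical process sit close together in
loading space; an agglomerative Ward tree cut at a fixed number of clusters
groups them.  Loadings that failed the broken-stick screen can optionally be
zeroed first, so that grouping reflects only process affinities that exceed
random expectation — with the published Kongsfjorden loading pattern this
masking is what separates the benthic-process metals from the conservative
mixing group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = ["ClusterAssignment", "cluster_loadings"]


@dataclass
class ClusterAssignment:
    """Parameter -> cluster label plus the merge tree that produced it."""

    labels: pd.Series          # parameter -> int label (1-based)
    linkage_matrix: np.ndarray
    n_clusters: int

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for param, lab in self.labels.items():
            out.setdefault(int(lab), []).append(param)
        return out

    def partition(self) -> set[frozenset]:
        """Label-free view of the clustering, for comparisons."""
        return {frozenset(v) for v in self.members().values()}

    def to_newick(self) -> str:
        """Merge tree as a newick string with merge heights as branch sets."""
        names = list(self.labels.index)
        n = len(names)
        nodes = {i: (names[i], 0.0) for i in range(n)}
        for step, (a, b, height, _count) in enumerate(self.linkage_matrix):
            la, ha = nodes.pop(int(a))
            lb, hb = nodes.pop(int(b))
            h = float(height)
            node = f"({la}:{h - ha:.6g},{lb}:{h - hb:.6g})"
            nodes[n + step] = (node, h)
        (tree, _h), = nodes.values()
        return tree + ";"


def cluster_loadings(loadings: pd.DataFrame, n_clusters: int = 5,
                     significance=None) -> ClusterAssignment:
    """Ward clustering of parameter loading vectors.

    The linkage minimizes the increase in within-cluster sum of squared
    Euclidean distances (the Ward criterion as applied by the mainstream R
    and scipy implementations, equivalent to Ward.D2 on Euclidean input).
    When a significance mask is given (boolean p x k frame or a
    ``LoadingSignificance``), non-significant loadings are zeroed before
    clustering.

    Labels are deterministic: clusters are numbered by size (largest first)
    with ties broken by first-member order, so relabelled input yields the
    same partition.
    """
    if not isinstance(loadings, pd.DataFrame):
        loadings = pd.DataFrame(np.asarray(loadings, dtype=float))
    p = loadings.shape[0]
    if not 1 <= n_clusters <= p:
        raise ValueError(f"n_clusters must be in [1, {p}], got {n_clusters}")

    mat = loadings.to_numpy(dtype=float)
    if significance is not None:
        mask = getattr(significance, "significant", significance)
        mask = pd.DataFrame(mask).to_numpy(dtype=bool)
        if mask.shape != mat.shape:
            raise ValueError("significance mask shape does not match loadings")
        mat = np.where(mask, mat, 0.0)

    lm = linkage(mat, method="ward")
    raw = fcluster(lm, t=n_clusters, criterion="maxclust")

    # relabel: by size descending, ties by first appearance
    order = {}
    sizes = pd.Series(raw).value_counts()
    first_pos = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    ranked = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_pos[lab]))
    order = {lab: i + 1 for i, lab in enumerate(ranked)}
    labels = pd.Series([order[lab] for lab in raw], index=loadings.index,
                       name="cluster")
    return ClusterAssignment(labels=labels, linkage_matrix=lm,
                             n_clusters=n_clusters)
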