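"""Signaling clusters: complete-linkage clustering of patients on 1 - Pearson r.

Patients are clustered on their harmonized analyte profiles with distance
``d(i, j) = 1 - r(i, j)`` (Pearson correlation over the analytes the two
patients share) and complete linkage.  The dendrogram is cut at a fixed
height (default 1.54 on the [0, 2] distance scale); one cluster may be
further partitioned into sub-clusters ("7a"/"7b"-style) by cutting its
subtree into its top-level branches.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .core import ValidationError

logger = logging.getLogger("rppasig")

__all__ = [
    "ClusterModel",
    "SignalingClusterer",
    "pearson_distance",
    "complete_linkage",
    "cut_tree_labels",
    "split_cluster",
    "cluster_means",
    "cluster_summary",
]


@dataclasses.dataclass
class ClusterModel:
    """Merge tree, cut labels and optional sub-split of one clustering run."""

    linkage: np.ndarray          # scipy (n-1) x 4 merge matrix
    cut_height: float
    labels: pd.Series            # patient -> label (int, or "7a"-style after split)
    split: dict                  # parent label -> list of sub-labels
    patients: list

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "linkage": self.linkage.tolist(),
            "cut_height": self.cut_height,
            "labels": {k: str(v) for k, v in self.labels.items()},
            "split": {str(k): list(map(str, v)) for k, v in self.split.items()},
            "patients": list(self.patients),
        }))


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Patient x patient ``1 - Pearson r`` distance, pairwise-complete on masks."""
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValidationError("need >= 2 analytes for correlation distance")
    sd = np.nanstd(X, axis=1)
    flat = np.flatnonzero(~(sd > 0))
    if len(flat):
        raise ValidationError(
            f"zero-variance profile for patient(s): {list(matrix.index[flat])[:5]}")
    if np.isnan(X).any():
        corr = matrix.T.corr(method="pearson", min_periods=2)
        r = corr.to_numpy()
    else:
        r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def complete_linkage(distance) -> np.ndarray:
    """Agglomerative complete-linkage merge tree from a square distance matrix."""
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance must be square")
    if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0):
        raise ValidationError("distance must be symmetric with a zero diagonal")
    condensed = squareform(d, checks=False)
    return hierarchy.linkage(condensed, method="complete")


def cut_tree_labels(Z: np.ndarray, h: float) -> np.ndarray:
    """Cluster labels from cutting the tree strictly below height ``h``.

    Clusters are the connected components of merges with height < h,
    numbered 1..K by dendrogram (leaf-order) appearance.
    """
    n = Z.shape[0] + 1
    parent = np.arange(2 * n - 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for step, (a, b, height, _size) in enumerate(Z):
        if height < h:
            node = n + step
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots = np.array([find(i) for i in range(n)])
    labels = np.zeros(n, dtype=int)
    next_label = 1
    seen = {}
    for leaf in hierarchy.leaves_list(Z):
        r = roots[leaf]
        if r not in seen:
            seen[r] = next_label
            next_label += 1
        labels[leaf] = seen[r]
    return labels


def _node_for_members(Z: np.ndarray, members: np.ndarray):
    """The dendrogram node whose leaf set equals ``members`` exactly."""
    root = hierarchy.to_tree(Z)
    target = set(int(m) for m in members)
    if len(target) == 1:
        (leaf,) = target

        def find_leaf(node):
            if node.is_leaf():
                return node if node.id == leaf else None
            return find_leaf(node.left) or find_leaf(node.right)

        return find_leaf(root)

    stack = [root]
    while stack:
        node = stack.pop()
        leaves = set(node.pre_order(lambda x: x.id))
        if leaves == target:
            return node
        if target < leaves and not node.is_leaf():
            stack.extend([node.left, node.right])
    raise ValidationError("cluster members do not form a dendrogram subtree")


def split_cluster(Z: np.ndarray, labels, target_cluster, k: int = 2,
                  patients=None):
    """Refine one cluster into its ``k`` top-level subtree branches.

    Sub-labels are ``"<id>a"``, ``"<id>b"``, ... ordered by dendrogram leaf
    position.  Returns the refined label vector (object dtype).
    """
    labels = np.asarray(labels, dtype=object)
    members = np.flatnonzero(labels == target_cluster)
    if len(members) < k:
        raise ValidationError(
            f"cannot split cluster {target_cluster!r} of size {len(members)} into {k}")
    node = _node_for_members(Z, members)
    branches = [node]
    while len(branches) < k:
        top = max(branches, key=lambda nd: nd.dist)
        if top.is_leaf():
            raise ValidationError("cluster too shallow for requested k")
        branches.remove(top)
        branches.extend([top.left, top.right])
    leaf_pos = {leaf: i for i, leaf in enumerate(hierarchy.leaves_list(Z))}
    branches.sort(key=lambda nd: min(leaf_pos[i] for i in nd.pre_order(lambda x: x.id)))
    refined = labels.copy()
    for letter, branch in zip("abcdefghij", branches):
        for leaf in branch.pre_order(lambda x: x.id):
            refined[leaf] = f"{target_cluster}{letter}"
    return refined


def cluster_means(matrix: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster mean of each analyte (mask-aware)."""
    g = pd.Series(np.asarray(labels, dtype=object), index=matrix.index)
    return matrix.groupby(g).mean()


def cluster_summary(labels, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster size, pCR rate, and subtype/arm composition (Sankey-ready)."""
    clin = clinical.set_index("patient_id")
    g = pd.Series(np.asarray(labels, dtype=object))
    if len(g) != len(clinical):
        raise ValidationError("labels and clinical table differ in length")
    g.index = clinical["patient_id"].to_numpy()
    rows = []
    for level in pd.unique(g.dropna()):
        members = g.index[g == level]
        sub = clin.loc[members]
        row = {"cluster": level, "n": len(sub), "n_pcr": int(sub["pcr"].sum()),
               "pcr_rate": float(sub["pcr"].mean())}
        for s, cnt in sub["subtype"].value_counts().items():
            row[f"subtype_{s}"] = int(cnt)
        for a, cnt in sub["arm"].value_counts().items():
            row[f"arm_{a}"] = int(cnt)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


class SignalingClusterer(ClusterMixin, BaseEstimator):
    """Complete-linkage clustering of patients on 1 - Pearson r profiles.

    Parameters
    ----------
    cut_height : float
        Dendrogram cut on the [0, 2] correlation-distance scale.
    split : label or None
        Primary cluster to refine into sub-clusters after the cut.
    k_split : int
        Number of subtree branches for the refinement.
    min_shared : int
        A patient must share at least this many unmasked analytes with every
        other patient, or is excluded with a warning.

    Attributes
    ----------
    linkage_ : ndarray
        scipy merge matrix over the retained patients.
    labels_ : pandas.Series
        patient -> cluster label (int, or "<id><letter>" within the split).
    model_ : ClusterModel
    excluded_ : list of patient ids dropped for insufficient shared analytes.
    """

    def __init__(self, cut_height: float = 1.54, split=None, k_split: int = 2,
                 min_shared: int = 30):
        self.cut_height = cut_height
        self.split = split
        self.k_split = k_split
        self.min_shared = min_shared

    def fit(self, X: pd.DataFrame, y=None) -> "SignalingClusterer":
        obs = X.notna().to_numpy()
        shared = obs.astype(int) @ obs.astype(int).T
        np.fill_diagonal(shared, self.min_shared)
        ok = (shared.min(axis=1) >= min(self.min_shared, X.shape[1]))
        self.excluded_ = list(X.index[~ok])
        if self.excluded_:
            logger.warning("excluded %d patient(s) sharing < %d analytes: %s",
                           len(self.excluded_), self.min_shared, self.excluded_[:5])
        Xr = X.loc[ok]
        d = pearson_distance(Xr)
        self.linkage_ = complete_linkage(d.to_numpy())
        raw = cut_tree_labels(self.linkage_, self.cut_height).astype(object)
        split_map = {}
        if self.split is not None:
            raw = split_cluster(self.linkage_, raw, self.split, k=self.k_split)
            split_map[self.split] = sorted(
                {v for v in raw if isinstance(v, str) and v.startswith(str(self.split))})
        self.labels_ = pd.Series(raw, index=Xr.index, name="cluster")
        self.model_ = ClusterModel(
            linkage=self.linkage_, cut_height=self.cut_height,
            labels=self.labels_, split=split_map, patients=list(Xr.index),
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()
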