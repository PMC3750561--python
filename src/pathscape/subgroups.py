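"""Aberration calling, frequency profiles, and subgroup discovery.

Per-sample calls discretise the confidence scores at a significance
threshold into ENRICHED / DEPLETED / NEUTRAL.  Group frequency profiles
count, per pathway, the fraction of the group's samples called each way.
Subgroups are discovered by agglomerative clustering (Euclidean distance,
Ward linkage) of the combined signed profiles, extracting dendrogram
branches within a target size band; subgroups from different cohorts are
compared by clustering their frequency-profile feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree

from .scoring import AberrationProfiles

ENRICHED = "E"
DEPLETED = "D"
NEUTRAL = "N"


def call_aberrations(profiles: AberrationProfiles, alpha: float = 0.05) -> pd.DataFrame:
    """Discretise confidences into an E/D/N call matrix (pathways x samples).

    ENRICHED iff p_enrichment < alpha and p_enrichment <= p_depletion;
    DEPLETED iff p_depletion < alpha and p_depletion < p_enrichment;
    otherwise NEUTRAL.  Calls are mutually exclusive; the significance
    threshold defaults to 0.05 and no multiple-testing correction is made.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    pe = profiles.p_enrichment.to_numpy()
    pd_ = profiles.p_depletion.to_numpy()
    calls = np.full(pe.shape, NEUTRAL, dtype=object)
    calls[(pe < alpha) & (pe <= pd_)] = ENRICHED
    calls[(pd_ < alpha) & (pd_ < pe)] = DEPLETED
    return pd.DataFrame(calls, index=profiles.pathway_names, columns=profiles.sample_ids)


def aberration_frequencies(
    calls: pd.DataFrame, grouping: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-group enrichment and depletion frequencies per pathway.

    Returns a long-format DataFrame (group, pathway, enr_freq, dep_freq,
    group_size).  Every sample column of ``calls`` must be mapped to a
    group; empty groups cannot arise but an unmapped sample is an error.
    """
    grouping = dict(grouping.items()) if isinstance(grouping, pd.Series) else dict(grouping)
    unmapped = [s for s in calls.columns if s not in grouping]
    if unmapped:
        raise ValueError(f"samples without a group: {unmapped[:5]}")
    rows = []
    groups: dict[str, list[str]] = {}
    for s in calls.columns:
        groups.setdefault(str(grouping[s]), []).append(s)
    for g, sids in groups.items():
        sub = calls[sids].to_numpy()
        size = len(sids)
        enr = (sub == ENRICHED).sum(axis=1) / size
        dep = (sub == DEPLETED).sum(axis=1) / size
        for p, e, d in zip(calls.index, enr, dep):
            rows.append({"group": g, "pathway": p, "enr_freq": float(e),
                         "dep_freq": float(d), "group_size": size})
    return pd.DataFrame(rows)


@dataclass
class ClusterTree:
    """Agglomerative merge history (scipy linkage matrix) with leaf labels.

    Ward linkage on Euclidean distances guarantees monotone merge heights.
    """

    linkage: np.ndarray
    leaf_labels: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cut(self, k: int) -> np.ndarray:
        """Standard k-cluster cut; labels in {0..k-1}."""
        return cut_tree(self.linkage, n_clusters=k).ravel()

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        root = to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{length:.6g}"
            return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

        return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def hierarchical_cluster(
    features: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None
) -> ClusterTree:
    """Ward/Euclidean agglomerative clustering of an items x features matrix."""
    if isinstance(features, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in features.index]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if np.isnan(X).any():
        raise ValueError("features must not contain missing values")
    Z = linkage(X, method="ward")
    return ClusterTree(linkage=Z, leaf_labels=list(labels))


@dataclass
class SubgroupAssignment:
    """Partition of a cohort's samples into subgroups, with provenance."""

    cohort: str
    labels: pd.Series  # sample_id -> subgroup integer (1-based)
    tree: ClusterTree
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ValueError("every sample must be assigned a subgroup")

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def n_subgroups(self) -> int:
        return int(self.labels.nunique())

    def members(self, subgroup: int) -> list[str]:
        return self.labels.index[self.labels == subgroup].tolist()


def _counts(Z: np.ndarray, n: int) -> dict[int, int]:
    counts = {i: 1 for i in range(n)}
    for i, (a, b, _, _) in enumerate(Z):
        counts[n + i] = counts[int(a)] + counts[int(b)]
    return counts


def _leaves(Z: np.ndarray, n: int, node: int) -> list[int]:
    stack, out = [node], []
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            a, b = int(Z[v - n, 0]), int(Z[v - n, 1])
            stack.extend((a, b))
    return out


def extract_subgroups(
    tree: ClusterTree,
    cohort: str = "",
    min_size: int = 20,
    max_size: int = 30,
    k_override: int | None = None,
    features: pd.DataFrame | np.ndarray | None = None,
) -> SubgroupAssignment:
    """Extract dendrogram branches as subgroups.

    With ``k_override`` the standard k-cluster cut is returned.  Otherwise
    the tree is descended from the root, splitting every cluster larger than
    ``max_size``; clusters that come out smaller than ``min_size`` are then
    merged into the nearest remaining cluster by centroid distance
    (requires ``features``; without features, into the smallest sibling).
    Subgroup labels are 1-based integers in dendrogram leaf order.
    """
    n = tree.n_leaves
    if min_size > n:
        raise ValueError(f"min_size {min_size} exceeds cohort size {n}")
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    Z = tree.linkage

    if k_override is not None:
        if not (1 <= k_override <= n):
            raise ValueError("k_override out of range")
        flat = tree.cut(k_override)
        groups = [list(np.where(flat == g)[0]) for g in sorted(set(flat))]
    else:
        counts = _counts(Z, n)
        root = n + len(Z) - 1
        clusters: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if counts[node] <= max_size or node < n:
                clusters.append(node)
            else:
                a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
                stack.extend((b, a))
        groups = [_leaves(Z, n, c) for c in clusters]
        # merge undersized branches into the nearest surviving cluster
        if features is not None:
            X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
        else:
            X = None
        groups.sort(key=len)
        merged = True
        while merged and len(groups) > 1:
            merged = False
            for gi, g in enumerate(groups):
                if len(g) < min_size:
                    others = [h for hi, h in enumerate(groups) if hi != gi]
                    if X is not None:
                        cg = X[g].mean(axis=0)
                        dists = [float(np.linalg.norm(X[h].mean(axis=0) - cg)) for h in others]
                        target = int(np.argmin(dists))
                    else:
                        target = int(np.argmin([len(h) for h in others]))
                    others[target] = sorted(others[target] + g)
                    groups = sorted(others, key=len)
                    merged = True
                    break

    # deterministic numbering: by smallest leaf index within each group
    groups = sorted((sorted(g) for g in groups), key=lambda g: g[0])
    lab = np.empty(n, dtype=int)
    for num, g in enumerate(groups, start=1):
        lab[g] = num
    labels = pd.Series(lab, index=tree.leaf_labels, name="subgroup")
    return SubgroupAssignment(
        cohort=cohort,
        labels=labels,
        tree=tree,
        params={"min_size": min_size, "max_size": max_size, "k_override": k_override},
    )


def cross_group_features(profiles: Sequence[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Stack subgroup frequency profiles into a clusterable feature matrix.

    Input: long-format frequency table(s) from :func:`aberration_frequencies`.
    Output: one row per group, feature vector = enrichment frequencies over
    all pathways followed by depletion frequencies (2P features).  All
    groups must cover the same pathway list.
    """
    if isinstance(profiles, pd.DataFrame):
        table = profiles
    else:
        table = pd.concat(list(profiles), ignore_index=True)
    pathways = None
    rows = {}
    for g, sub in table.groupby("group", sort=True):
        sub = sub.sort_values("pathway")
        plist = sub["pathway"].tolist()
        if pathways is None:
            pathways = plist
        elif plist != pathways:
            raise ValueError(f"group {g!r} covers a different pathway list")
        rows[g] = np.concatenate([sub["enr_freq"].to_numpy(), sub["dep_freq"].to_numpy()])
    cols = [f"enr:{p}" for p in pathways] + [f"dep:{p}" for p in pathways]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


class PathwaySubgrouper:
    """Ward/Euclidean subgroup discovery over aberration profiles.

    scikit-learn style clusterer: ``fit(X)`` on a samples x pathways matrix
    of combined signed scores builds the dendrogram and extracts branch
    subgroups; ``labels_`` holds the 1-based subgroup of each sample and
    ``tree_`` the dendrogram.

    Parameters
    ----------
    min_size, max_size : int
        Target branch size band for subgroup extraction.
    k_override : int or None
        Cut to exactly k clusters instead of the size-band descent.
    """

    def __init__(self, min_size: int = 20, max_size: int = 30, k_override: int | None = None):
        self.min_size = min_size
        self.max_size = max_size
        self.k_override = k_override

    def get_params(self, deep: bool = True) -> dict:
        return {"min_size": self.min_size, "max_size": self.max_size,
                "k_override": self.k_override}

    def set_params(self, **params) -> "PathwaySubgrouper":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "PathwaySubgrouper":
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = np.asarray(X, dtype=float)
            frame = pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])])
        self.tree_ = hierarchical_cluster(frame)
        self.assignment_ = extract_subgroups(
            self.tree_, min_size=self.min_size, max_size=self.max_size,
            k_override=self.k_override, features=frame)
        self.labels_ = self.assignment_.labels.to_numpy()
        self.n_features_in_ = frame.shape[1]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
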