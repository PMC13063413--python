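"""Chemical grouping by agglomerative hierarchical clustering.

Two families of groupings feed group-specific benchmarking:

* data-dependent ("optimized") — each chemical is represented by the vector
  of Pearson correlation coefficients of its log10 k profile against every
  other chemical's, computed on pairwise-complete sites; chemicals whose
  spatiotemporal patterns co-vary end up close in this feature space;
* data-independent — each chemical is represented by a structural or
  biotransformation descriptor vector (166-bit MACCS fingerprint, 208 binary
  biotransformation-rule triggers, or 65 rule probabilities).

Both are clustered with Ward's minimum-variance criterion under Euclidean
distance (the Ward.D2 convention: linkage heights on the distance scale).
For optimized benchmarking the tree cut is repaired so every group keeps at
least two chemicals — a singleton cannot contain both a benchmark and a
benchmarked chemical — by merging undersized clusters into their nearest
cluster under the Ward distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ConfigurationError, DomainError, UsageError
from .io import DescriptorMatrix, RateMatrix, _sep_for

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 5
DEFAULT_MIN_SIZE = 2


# ---------------------------------------------------------------------------
# pairwise correlation features
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients of log10 k profiles.

    ``r`` is symmetric with unit diagonal (where defined) and NaN where the
    pairwise-complete overlap is below ``min_overlap`` or either profile has
    zero variance on the shared sites; ``n_overlap`` records the shared-site
    counts.
    """

    r: pd.DataFrame
    n_overlap: pd.DataFrame
    min_overlap: int


def pairwise_pearson(
    matrix: RateMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between chemicals' log k rows."""
    chems = matrix.chemicals
    if len(chems) < 2:
        raise UsageError("pairwise correlations need at least 2 chemicals")
    X = matrix.values
    n = len(chems)
    finite = np.isfinite(X)
    r = np.full((n, n), np.nan)
    n_ov = np.zeros((n, n), dtype=int)
    for i in range(n):
        n_ov[i, i] = int(finite[i].sum())
        r[i, i] = 1.0 if n_ov[i, i] > 0 else np.nan
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            m = int(both.sum())
            n_ov[i, j] = n_ov[j, i] = m
            if m < min_overlap:
                continue
            xi = X[i, both]
            xj = X[j, both]
            sx = xi.std()
            sy = xj.std()
            if sx == 0 or sy == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            r[i, j] = r[j, i] = rij
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=chems, columns=chems),
        n_overlap=pd.DataFrame(n_ov, index=chems, columns=chems),
        min_overlap=min_overlap,
    )


def correlation_features(corr: CorrelationMatrix) -> pd.DataFrame:
    """Feature vectors for clustering: each chemical's row of r.

    Missing correlations are imputed with 0 (no information about
    co-variation); the unit diagonal is kept so all vectors have equal
    length — a shared constant column that does not affect between-chemical
    Euclidean distances.
    """
    feats = corr.r.copy()
    np.fill_diagonal(feats.values, 1.0)
    return feats.fillna(0.0)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------


@dataclass
class MergeTree:
    """Agglomerative merge sequence (scipy linkage matrix) with leaf labels."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]
    features: np.ndarray  # items x dims, kept for min-size repair

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class GroupAssignment:
    """Mapping chemical -> cluster label (contiguous small integers from 1)."""

    labels: dict  # chemical_id -> int
    method: str  # pearson | maccs | btrules | btrules_prob | file | custom
    k_groups: int  # requested number of groups
    effective_k: int = 0  # after any min-size repair

    def __post_init__(self) -> None:
        if self.effective_k == 0:
            self.effective_k = len(set(self.labels.values()))

    def sizes(self) -> dict:
        out: dict[int, int] = {}
        for g in self.labels.values():
            out[g] = out.get(g, 0) + 1
        return out


def ward_tree(features, labels: Sequence[str] | None = None) -> MergeTree:
    """Ward/Euclidean agglomerative clustering of feature vectors.

    Heights follow the Ward.D2 convention (distance scale): merging singleton
    clusters at Euclidean distance d yields height d. Deterministic given the
    input order.
    """
    if isinstance(features, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in features.index]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise UsageError("ward_tree needs at least 2 items with vector features")
    if not np.isfinite(X).all():
        raise DomainError("ward_tree requires finite features")
    Z = hierarchy.linkage(X, method="ward")
    return MergeTree(linkage=Z, labels=list(labels), features=X)


def cut_tree(tree: MergeTree, k_groups: int) -> np.ndarray:
    """Plain cut into ``k_groups`` flat clusters (labels 1..k, leaf order)."""
    if not (1 <= k_groups <= tree.n_leaves):
        raise UsageError(
            f"k_groups must be in [1, {tree.n_leaves}], got {k_groups}"
        )
    if k_groups == tree.n_leaves:
        return np.arange(1, tree.n_leaves + 1)
    return hierarchy.fcluster(tree.linkage, t=k_groups, criterion="maxclust")


def _ward_cluster_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Ward.D2 distance between clusters: sqrt(2|A||B|/(|A|+|B|)) * ||cA-cB||."""
    na, nb = len(A), len(B)
    d = np.linalg.norm(A.mean(axis=0) - B.mean(axis=0))
    return math.sqrt(2.0 * na * nb / (na + nb)) * float(d)


def _relabel(labels: np.ndarray) -> dict:
    """Relabel cluster ids to contiguous integers 1..K (sorted original order)."""
    mapping = {g: i + 1 for i, g in enumerate(sorted(set(labels.tolist())))}
    return mapping


def cut_tree_min_size(
    tree: MergeTree,
    k_groups: int,
    min_size: int = DEFAULT_MIN_SIZE,
    method: str = "custom",
) -> GroupAssignment:
    """Cut into ``k_groups`` clusters, then repair undersized clusters.

    While any cluster has fewer than ``min_size`` members, the smallest such
    cluster (ties by smallest label) is merged into the cluster nearest to it
    under the Ward distance, reducing the effective group count. Both the
    requested and effective counts are reported on the assignment.
    """
    flat = np.asarray(cut_tree(tree, k_groups))
    X = tree.features
    while True:
        sizes: dict[int, int] = {}
        for g in flat:
            sizes[int(g)] = sizes.get(int(g), 0) + 1
        small = [g for g, s in sizes.items() if s < min_size]
        if not small or len(sizes) <= 1:
            break
        # smallest cluster first; ties by smallest label
        g0 = min(small, key=lambda g: (sizes[g], g))
        members = flat == g0
        best_g, best_d = None, math.inf
        for g in sorted(sizes):
            if g == g0:
                continue
            d = _ward_cluster_distance(X[members], X[flat == g])
            if d < best_d - 1e-15:
                best_g, best_d = g, d
        flat = np.where(members, best_g, flat)
        logger.debug("min-size repair: merged cluster %s into %s", g0, best_g)
    mapping = _relabel(flat)
    labels = {cid: mapping[int(g)] for cid, g in zip(tree.labels, flat)}
    return GroupAssignment(
        labels=labels,
        method=method,
        k_groups=k_groups,
        effective_k=len(mapping),
    )


# ---------------------------------------------------------------------------
# high-level groupings
# ---------------------------------------------------------------------------


def pearson_grouping(
    matrix: RateMatrix,
    k_groups: int,
    min_size: int = DEFAULT_MIN_SIZE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> GroupAssignment:
    """Data-dependent ("optimized") grouping from log k correlation profiles."""
    corr = pairwise_pearson(matrix, min_overlap=min_overlap)
    feats = correlation_features(corr)
    tree = ward_tree(feats)
    return cut_tree_min_size(tree, k_groups, min_size=min_size, method="pearson")


def descriptor_grouping(
    desc: DescriptorMatrix,
    k_groups: int,
    chemicals: Sequence[str] | None = None,
) -> GroupAssignment:
    """Data-independent grouping from structural/biotransformation descriptors.

    Binary fingerprints are treated as 0/1 reals under Euclidean distance
    (the square root of the Hamming distance). The cut is plain — no minimum
    group size is enforced for descriptor-based groupings.
    """
    if chemicals is not None:
        missing = [c for c in chemicals if c not in set(desc.chemicals)]
        if missing:
            raise ConfigurationError(
                "descriptor matrix lacks chemicals: " + ", ".join(sorted(missing))
            )
        values = desc.values.loc[list(chemicals)]
    else:
        values = desc.values
    tree = ward_tree(values)
    flat = np.asarray(cut_tree(tree, k_groups))
    mapping = _relabel(flat)
    return GroupAssignment(
        labels={cid: mapping[int(g)] for cid, g in zip(tree.labels, flat)},
        method=desc.kind,
        k_groups=k_groups,
        effective_k=len(mapping),
    )


def grouping_accuracy(assignment: GroupAssignment, truth: GroupAssignment) -> float:
    """Adjusted Rand index between two assignments over their shared chemicals."""
    from sklearn.metrics import adjusted_rand_score

    shared = sorted(set(assignment.labels) & set(truth.labels))
    if not shared:
        raise UsageError("assignments share no chemicals")
    a = [assignment.labels[c] for c in shared]
    b = [truth.labels[c] for c in shared]
    return float(adjusted_rand_score(b, a))


# ---------------------------------------------------------------------------
# grouping files
# ---------------------------------------------------------------------------


def write_grouping(assignment: GroupAssignment, path: str | Path) -> None:
    """Write a two-column (chemical_id, group) delimited grouping file."""
    rows = sorted(assignment.labels.items())
    pd.DataFrame(rows, columns=["chemical_id", "group"]).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_grouping(path: str | Path) -> GroupAssignment:
    """Read a two-column grouping file written by :func:`write_grouping`."""
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("chemical_id", "group"):
        if col not in df.columns:
            raise ConfigurationError(f"grouping file {path}: missing column {col!r}")
    labels = {str(r.chemical_id): int(r.group) for r in df.itertuples()}
    return GroupAssignment(labels=labels, method="file", k_groups=len(set(labels.values())))
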