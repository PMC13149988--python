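"""Kinematic clustering of unit sequences (Ward linkage, Euclidean metric).

Sequences are clustered on three structural kinematic parameters — presses
per sequence, press frequency, and inter-sequence interval — with
agglomerative hierarchical clustering under Ward's minimum-variance
criterion, then the three clusters are mapped to the semantic classes:

* C1 — fast, temporally confined pressing (highest mean frequency),
* C3 — slow, temporally elongated pressing (highest mean press count among
  the remaining clusters),
* C2 — the rest.

The Ward merge sequence is computed with the Lance–Williams update on
squared Euclidean distances; ties are broken toward the smallest index
pair, making the result deterministic given input order. Heights follow
the scipy convention (square root of the Lance–Williams squared distance),
so the merge tree is directly comparable to
``scipy.cluster.hierarchy.linkage(X, method="ward")``.

Euclidean distance across a count, a rate in Hz and an interval in seconds
is unit-inconsistent, so features are z-scored per column by default; raw
mode is retained for literal replication of unscaled clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple
import warnings

import numpy as np

from .sequences import SequenceTrial

__all__ = ["ClusterModel", "feature_matrix", "ward_cluster", "order_classes", "FEATURE_NAMES"]

FEATURE_NAMES = ("n_presses", "frequency_hz", "inter_seq_interval_s")


@dataclass
class ClusterModel:
    k: int
    merge_tree: List[Tuple[int, int, float]]  # (left, right, height), scipy node ids
    labels: np.ndarray
    linkage: str = "ward"
    metric: str = "euclidean"
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    standardization: Optional[dict] = None
    class_map: Optional[dict] = None  # cluster label -> C1/C2/C3

    def linkage_matrix(self) -> np.ndarray:
        """Merge tree as a scipy-style (N-1) x 4 linkage matrix."""
        n = len(self.merge_tree) + 1
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for step, (a, b, h) in enumerate(self.merge_tree):
            size = sizes[a] + sizes[b]
            sizes[n + step] = size
            Z[step] = [a, b, h, size]
        return Z


def feature_matrix(
    seqs: Sequence[SequenceTrial],
    standardize: bool = True,
    fill_first_interval: str = "median",
) -> Tuple[np.ndarray, dict, List[int]]:
    """Build the N x 3 kinematic feature matrix.

    Sequences with undefined frequency (single presses) are excluded; their
    indices are reported so callers can keep bookkeeping straight. The
    first sequence of a session has no inter-sequence interval and receives
    the session median interval (configurable off with
    ``fill_first_interval="zero"``). Returns (matrix, transform record,
    indices of the retained sequences).

    Zero-variance columns are left unscaled (guarded with a warning) so the
    transform stays invertible.
    """
    kept = [i for i, s in enumerate(seqs) if np.isfinite(s.frequency_hz)]
    if not kept:
        raise ValueError("no sequences with defined frequency")
    intervals = [seqs[i].inter_seq_interval_s for i in kept]
    known = [v for v in intervals if v is not None]
    if fill_first_interval == "median":
        fill = float(np.median(known)) if known else 0.0
    elif fill_first_interval == "zero":
        fill = 0.0
    else:
        raise ValueError(f"unknown fill_first_interval {fill_first_interval!r}")
    X = np.array(
        [
            [
                seqs[i].n_presses,
                seqs[i].frequency_hz,
                seqs[i].inter_seq_interval_s if seqs[i].inter_seq_interval_s is not None else fill,
            ]
            for i in kept
        ],
        dtype=float,
    )
    transform = {"standardize": standardize, "mean": None, "std": None}
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        flat = std == 0
        if flat.any():
            names = [FEATURE_NAMES[j] for j in np.flatnonzero(flat)]
            warnings.warn(f"zero-variance feature(s) left unscaled: {names}")
            std = np.where(flat, 1.0, std)
        X = (X - mean) / std
        transform["mean"], transform["std"] = mean, std
    return X, transform, kept


def ward_cluster(features: np.ndarray, k: int) -> Tuple[np.ndarray, ClusterModel]:
    """Agglomerative Ward clustering; labels from cutting the tree at k.

    Each merge picks the pair of clusters whose union minimally increases
    the within-cluster sum of squares; with squared Euclidean distances
    this is the Lance–Williams recurrence

        d2(u, i+j) = [(n_i + n_u) d2(u,i) + (n_j + n_u) d2(u,j)
                      - n_u d2(i,j)] / (n_i + n_j + n_u).

    Ties go to the lexicographically smallest active-cluster pair. Labels
    are 0..k-1 in order of first appearance.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= {n}, got k={k}")

    # squared Euclidean distance matrix over all 2n-1 (current + future) nodes
    total = 2 * n - 1
    D2 = np.full((total, total), np.inf)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    D2[:n, :n] = sq
    np.fill_diagonal(D2, np.inf)
    sizes = np.ones(total)
    alive = np.zeros(total, dtype=bool)
    alive[:n] = True
    merge_tree: List[Tuple[int, int, float]] = []
    members = {i: [i] for i in range(n)}

    for step in range(n - 1):
        act = np.flatnonzero(alive)
        sub = D2[np.ix_(act, act)]
        sub[np.tril_indices(len(act))] = np.inf
        # first row-major minimum = smallest-index pair on ties
        flat = int(np.argmin(sub))
        ai, bi = divmod(flat, len(act))
        a, b = int(act[ai]), int(act[bi])
        d_min = float(sub[ai, bi])
        new = n + step
        merge_tree.append((a, b, float(np.sqrt(d_min))))
        others = act[(act != a) & (act != b)]
        if others.size:
            nu, na, nb = sizes[others], sizes[a], sizes[b]
            upd = ((na + nu) * D2[a, others] + (nb + nu) * D2[b, others] - nu * d_min) / (
                na + nb + nu
            )
            D2[new, others] = upd
            D2[others, new] = upd
        sizes[new] = sizes[a] + sizes[b]
        members[new] = members[a] + members[b]
        alive[a] = alive[b] = False
        alive[new] = True

    # cut the tree at k clusters: undo the last k-1 merges
    cluster_roots = list(range(n)) if k == n else None
    if cluster_roots is None:
        roots = [n + (n - 2)] if n > 1 else [0]
        # peel off merges from the top until k roots remain
        for step in range(n - 2, -1, -1):
            if len(roots) == k:
                break
            node = n + step
            if node in roots:
                roots.remove(node)
                roots.extend(merge_tree[step][:2])
        cluster_roots = roots
    labels = np.empty(n, dtype=int)
    # order-of-first-appearance labeling for determinism
    roots_sorted = sorted(cluster_roots, key=lambda r: min(members[r]))
    for lab, root in enumerate(roots_sorted):
        labels[members[root]] = lab
    model = ClusterModel(k=k, merge_tree=merge_tree, labels=labels)
    return labels, model


def order_classes(
    labels: np.ndarray, seqs: Sequence[SequenceTrial], kept: Optional[Sequence[int]] = None
) -> dict:
    """Map k=3 cluster labels to the semantic classes C1/C2/C3.

    C1 is the cluster with the highest mean press frequency; among the
    remaining two, C3 has the higher mean press count; C2 is the other.
    Writes ``class_label`` onto the sequences and returns the mapping.
    An exact tie in either ordering statistic raises — mapping must then
    be done manually, never silently.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 3:
        raise ValueError(f"expected 3 clusters, got {uniq.size}")
    if kept is None:
        kept = list(range(len(seqs)))
    if len(kept) != labels.size:
        raise ValueError("labels and sequence indices disagree in length")
    freq = {u: np.mean([seqs[kept[i]].frequency_hz for i in np.flatnonzero(labels == u)]) for u in uniq}
    count = {u: np.mean([seqs[kept[i]].n_presses for i in np.flatnonzero(labels == u)]) for u in uniq}
    f_sorted = sorted(uniq, key=lambda u: -freq[u])
    if freq[f_sorted[0]] == freq[f_sorted[1]]:
        raise ValueError("tie in mean frequency between clusters; manual class mapping required")
    c1 = f_sorted[0]
    rest = [u for u in uniq if u != c1]
    if count[rest[0]] == count[rest[1]]:
        raise ValueError("tie in mean press count between clusters; manual class mapping required")
    c3 = max(rest, key=lambda u: count[u])
    c2 = next(u for u in rest if u != c3)
    mapping = {int(c1): "C1", int(c2): "C2", int(c3): "C3"}
    for i, lab in zip(kept, labels):
        seqs[i].class_label = mapping[int(lab)]
    return mapping
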