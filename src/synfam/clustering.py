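"""Identity-threshold clustering of family candidates into subgroups.

The subgroup-defining step of the classification: an all-vs-all percent
sequence identity (PSI) matrix, agglomerative clustering cut at a PSI
threshold (60% by default), selection of large clusters as subgroups, and
deterministic group/subgroup labelling supported by a neighbor-joining
tree of subgroup medoids.

Minimum linkage ("a member shares >= threshold PSI with ANY member of
its cluster") is exactly the connected components of the thresholded
identity graph; maximum linkage requires the threshold against EVERY
member and is computed by naive complete-linkage agglomeration with a
fixed tie-break so results are stable under input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .align import AlignmentParams, global_align_identity
from .records import ConfigError, DataError, ProteinRecord


@dataclass
class IdentityMatrix:
    """Symmetric pairwise PSI matrix over an ordered id list.

    ``psi`` entries are percentages in [0, 100] with 100 on the diagonal;
    distance is defined as ``1 - psi/100``.
    """

    ids: list[str]
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        n = len(self.ids)
        if self.psi.shape != (n, n):
            raise DataError("psi matrix shape does not match id list")
        if not np.allclose(self.psi, self.psi.T, atol=1e-9):
            raise DataError("psi matrix must be symmetric")
        if self.psi.min() < -1e-9 or self.psi.max() > 100 + 1e-9:
            raise DataError("psi entries must lie in [0, 100]")
        if not np.allclose(np.diag(self.psi), 100.0):
            raise DataError("psi diagonal must be 100")

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.psi / 100.0

    def submatrix(self, ids: Sequence[str]) -> "IdentityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return IdentityMatrix(list(ids), self.psi[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.psi, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.4f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())


@dataclass
class ClusterSet:
    """A partition of gene ids produced at a given linkage and threshold."""

    clusters: dict[str, list[str]]
    linkage: str
    threshold_psi: float

    def sizes(self) -> dict[str, int]:
        return {cid: len(m) for cid, m in self.clusters.items()}

    def membership(self) -> dict[str, str]:
        return {g: cid for cid, members in self.clusters.items() for g in members}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#gene_id\tcluster_id\n")
            for cid in sorted(self.clusters):
                for g in self.clusters[cid]:
                    fh.write(f"{g}\t{cid}\n")


@dataclass
class SubgroupDefinition:
    """A subgroup-defining cluster (size above the selection floor)."""

    label: str
    group: str | None
    member_ids: list[str]
    medoid_id: str

    @property
    def size(self) -> int:
        return len(self.member_ids)


def build_distance_matrix(records: Sequence[ProteinRecord],
                          params: AlignmentParams = AlignmentParams()) -> IdentityMatrix:
    """All-vs-all global PSI over the candidate set (exact, no k-mer
    approximation; quadratic in the number of candidates)."""
    if len(records) < 2:
        raise DataError("need at least two records for a distance matrix")
    seen = set()
    for r in records:
        if r.gene_id in seen:
            raise DataError(f"duplicate gene id {r.gene_id} in candidate set")
        seen.add(r.gene_id)
    n = len(records)
    psi = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                value = global_align_identity(records[i], records[j], params)
            except DataError as exc:
                raise DataError(
                    f"alignment failed for pair "
                    f"({records[i].gene_id}, {records[j].gene_id}): {exc}") from exc
            psi[i, j] = psi[j, i] = value
    return IdentityMatrix([r.gene_id for r in records], psi)


class PsiLinkageClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative PSI-threshold clustering (sklearn-style estimator).

    Parameters
    ----------
    threshold_psi : float, default 60.0
        Members must share at least this percent identity (with any
        member under ``"minimum"`` linkage, with every member under
        ``"maximum"``) to co-cluster.
    linkage : {"minimum", "maximum"}, default "minimum"

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Integer cluster label per input id, ordered as the input matrix.
    cluster_set_ : ClusterSet
        Named clusters (``C001``...) ordered by decreasing size, ties by
        lexicographically smallest member id.
    """

    def __init__(self, threshold_psi: float = 60.0, linkage: str = "minimum"):
        self.threshold_psi = threshold_psi
        self.linkage = linkage

    def fit(self, X: IdentityMatrix | np.ndarray, y=None):
        if self.linkage not in {"minimum", "maximum"}:
            raise ConfigError(f"unknown linkage {self.linkage!r}")
        if isinstance(X, IdentityMatrix):
            matrix = X
        else:
            X = np.asarray(X, dtype=float)
            matrix = IdentityMatrix([str(i) for i in range(len(X))], X)
        if self.linkage == "minimum":
            groups = _connected_components(matrix, self.threshold_psi)
        else:
            groups = _complete_linkage(matrix, self.threshold_psi)
        groups = sorted(groups, key=lambda g: (-len(g), min(g)))
        width = max(3, len(str(len(groups))))
        self.cluster_set_ = ClusterSet(
            {f"C{k + 1:0{width}d}": sorted(g) for k, g in enumerate(groups)},
            self.linkage, self.threshold_psi)
        membership = self.cluster_set_.membership()
        order = {cid: k for k, cid in enumerate(self.cluster_set_.clusters)}
        self.labels_ = np.array([order[membership[g]] for g in matrix.ids])
        self.n_clusters_ = len(groups)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _connected_components(matrix: IdentityMatrix, threshold: float) -> list[set[str]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    idx = np.argwhere(matrix.psi >= threshold)
    for i, j in idx:
        if i < j:
            g.add_edge(matrix.ids[i], matrix.ids[j])
    return [set(c) for c in nx.connected_components(g)]


def _complete_linkage(matrix: IdentityMatrix, threshold: float) -> list[set[str]]:
    """Naive complete-linkage agglomeration cut at the PSI threshold.

    Cluster-pair similarity is the minimum pairwise PSI between members;
    the best pair merges first, ties broken by the lexicographically
    smallest member id of the combined cluster (then the next id), so
    the result is invariant to input order.
    """
    ids = matrix.ids
    pos = {g: i for i, g in enumerate(ids)}
    clusters: list[set[str]] = [{g} for g in ids]

    def linkage_psi(a: set[str], b: set[str]) -> float:
        ia = [pos[g] for g in a]
        ib = [pos[g] for g in b]
        return float(matrix.psi[np.ix_(ia, ib)].min())

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                s = linkage_psi(clusters[i], clusters[j])
                if s < threshold:
                    continue
                key = (-s, sorted(clusters[i] | clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def cluster_min_linkage(matrix: IdentityMatrix,
                        threshold_psi: float = 60.0) -> ClusterSet:
    return PsiLinkageClusterer(threshold_psi, "minimum").fit(matrix).cluster_set_


def cluster_max_linkage(matrix: IdentityMatrix,
                        threshold_psi: float = 60.0) -> ClusterSet:
    return PsiLinkageClusterer(threshold_psi, "maximum").fit(matrix).cluster_set_


def medoid(matrix: IdentityMatrix, member_ids: Sequence[str]) -> str:
    """Member maximising summed PSI to the others (ties: smallest id)."""
    sub = matrix.submatrix(sorted(member_ids))
    totals = sub.psi.sum(axis=1)
    return sub.ids[int(np.lexsort((sub.ids, -totals))[0])]


def select_subgroup_clusters(
    clusters: ClusterSet, matrix: IdentityMatrix, min_size: int = 50,
) -> tuple[list[SubgroupDefinition], list[str]]:
    """Clusters with >= ``min_size`` members become subgroup definitions;
    all other members join the unclassified pool for the rescue steps."""
    subgroups: list[SubgroupDefinition] = []
    leftover: list[str] = []
    for cid in sorted(clusters.clusters):
        members = clusters.clusters[cid]
        if len(members) >= min_size:
            subgroups.append(SubgroupDefinition(
                label=cid, group=None, member_ids=sorted(members),
                medoid_id=medoid(matrix, members)))
        else:
            leftover.extend(members)
    subgroups.sort(key=lambda s: (-s.size, s.medoid_id))
    return subgroups, sorted(leftover)


def neighbor_joining(ids: Sequence[str], distances: np.ndarray) -> str:
    """Unrooted NJ tree over a symmetric distance matrix, as newick.

    Fewer than three taxa yield a degenerate (star/cherry) tree rather
    than an error.
    """
    distances = np.asarray(distances, dtype=float)
    if len(ids) < 3:
        if len(ids) == 1:
            return f"{ids[0]};"
        d = distances[0, 1]
        return f"({ids[0]}:{d / 2:.6f},{ids[1]}:{d / 2:.6f});"
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(distances, ids=list(ids)))
    return str(tree).strip()


def assign_labels(
    subgroups: Sequence[SubgroupDefinition],
    matrix: IdentityMatrix,
    group_anchors: Mapping[str, str] | None = None,
    group_threshold_psi: float = 40.0,
) -> tuple[list[SubgroupDefinition], str]:
    """Assign group (Roman) and subgroup (letter) labels deterministically.

    Groups come from ``group_anchors`` (a map of known exemplar gene id →
    group name) when given; otherwise subgroup medoids are grouped by
    single-linkage at the relaxed group threshold (>= 40% PSI by default,
    the same currency as the relaxed group rule). Unanchored groups are
    named I, II, ... by decreasing total member count (ties by smallest
    medoid id); subgroup letters run A, B, ... within each group by
    decreasing size (ties by smallest medoid id). Returns the relabelled
    subgroups together with the medoid NJ tree (newick) used for
    reporting.
    """
    subgroups = [SubgroupDefinition(s.label, s.group, list(s.member_ids),
                                    s.medoid_id) for s in subgroups]
    medoids = [s.medoid_id for s in subgroups]
    sub = matrix.submatrix(medoids)
    newick = neighbor_joining(sub.ids, sub.distance) if len(medoids) >= 2 else f"{medoids[0]};"

    if group_anchors:
        member_to_sub = {g: s for s in subgroups for g in s.member_ids}
        group_of: dict[int, str] = {}
        for exemplar, group in group_anchors.items():
            if exemplar not in member_to_sub:
                raise ConfigError(f"anchor id {exemplar!r} not found in any subgroup")
            group_of[id(member_to_sub[exemplar])] = group
        groups: dict[str, list[SubgroupDefinition]] = {}
        unanchored = []
        for s in subgroups:
            g = group_of.get(id(s))
            if g is None:
                unanchored.append(s)
            else:
                groups.setdefault(g, []).append(s)
        if unanchored:
            raise ConfigError(
                "anchor config does not cover subgroups with medoids "
                + ", ".join(s.medoid_id for s in unanchored))
        ordered = sorted(groups.items(), key=lambda kv: kv[0])
    else:
        clusterer = PsiLinkageClusterer(group_threshold_psi, "minimum")
        clusterer.fit(sub)
        parts = clusterer.cluster_set_.clusters
        by_medoid = {s.medoid_id: s for s in subgroups}
        blocks = [[by_medoid[m] for m in members] for members in parts.values()]
        blocks.sort(key=lambda b: (-sum(s.size for s in b),
                                   min(s.medoid_id for s in b)))
        ordered = [(_roman(k + 1), block) for k, block in enumerate(blocks)]

    labelled: list[SubgroupDefinition] = []
    for group_name, block in ordered:
        block = sorted(block, key=lambda s: (-s.size, s.medoid_id))
        for k, s in enumerate(block):
            letter = _letters(k)
            labelled.append(SubgroupDefinition(
                f"{group_name}{letter}", group_name, sorted(s.member_ids),
                s.medoid_id))
    labelled.sort(key=lambda s: (s.group, s.label))
    return labelled, newick


def _roman(n: int) -> str:
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
                (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
                (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def _letters(k: int) -> str:
    out = ""
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        out = chr(ord("A") + rem) + out
    return out
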