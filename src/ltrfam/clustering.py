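"""Single-linkage clustering of feature sequences and candidate signatures.

Within each feature class, the filtered matches define an undirected graph on
feature-sequence uids; single-linkage clusters are exactly its connected
components (the linkage criterion is the existence of a kept match).
Clusters whose members all come from one candidate carry no classification
evidence (a candidate's two near-identical LTRs matching only each other)
and are discarded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .matching import FeatureSequence, Match
from .model import LtrfamError


@dataclass
class ClusterAssignment:
    """Dense, deterministically numbered clusters of one feature class."""

    class_key: str
    clusters: list[frozenset[str]]  # index = cluster_id

    def cluster_of(self, uid: str) -> int | None:
        for i, members in enumerate(self.clusters):
            if uid in members:
                return i
        return None


@dataclass
class Signature:
    """A candidate's per-class cluster memberships.

    Candidates with no entries are singletons: they carry no clustering
    evidence and cannot be classified automatically.
    """

    candidate_id: str
    entries: dict[str, frozenset[int]] = field(default_factory=dict)

    @property
    def labels(self) -> set[tuple[str, int]]:
        return {
            (class_key, cid)
            for class_key, ids in self.entries.items()
            for cid in ids
        }

    @property
    def is_singleton(self) -> bool:
        return not self.entries


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def single_linkage(
    seqs: list[FeatureSequence],
    matches: list[Match],
    keep_private_clusters: bool = False,
) -> list[ClusterAssignment]:
    """Connected components of the (span-filtered) match graph, per class.

    Cluster ids are dense from 0 within each class, ordered by the
    lexicographically smallest member uid, so the numbering is invariant
    under permutation of the match list.  Unmatched uids form singleton
    components; these — and by default any cluster covering < 2 distinct
    candidates — are dropped from the assignment.
    """
    by_uid = {fs.uid: fs for fs in seqs}
    for m in matches:
        for uid in (m.query_uid, m.subject_uid):
            if uid not in by_uid:
                raise LtrfamError(f"match references unknown uid {uid!r}")

    by_class: dict[str, list[FeatureSequence]] = {}
    for fs in seqs:
        by_class.setdefault(fs.class_key, []).append(fs)

    out: list[ClusterAssignment] = []
    for class_key in sorted(by_class):
        group = by_class[class_key]
        uf = _UnionFind(fs.uid for fs in group)
        for m in matches:
            if by_uid[m.query_uid].class_key == class_key:
                uf.union(m.query_uid, m.subject_uid)
        components: dict[str, set[str]] = {}
        for fs in group:
            components.setdefault(uf.find(fs.uid), set()).add(fs.uid)
        clusters = []
        for members in components.values():
            n_candidates = len({by_uid[u].candidate_id for u in members})
            if n_candidates >= 2 or (keep_private_clusters and len(members) >= 2):
                clusters.append(frozenset(members))
        clusters.sort(key=lambda c: min(c))
        if clusters:
            out.append(ClusterAssignment(class_key=class_key, clusters=clusters))
    return out


def build_signatures(
    assignments: list[ClusterAssignment],
    candidate_ids: Iterable[str],
    seqs: list[FeatureSequence],
) -> list[Signature]:
    """Per-candidate signature: every clustered feature contributes its
    (class, cluster_id) label; features in dropped clusters contribute
    nothing."""
    by_uid = {fs.uid: fs for fs in seqs}
    entries: dict[str, dict[str, set[int]]] = {cid: {} for cid in candidate_ids}
    for assignment in assignments:
        for cluster_id, members in enumerate(assignment.clusters):
            for uid in members:
                cid = by_uid[uid].candidate_id
                if cid in entries:
                    entries[cid].setdefault(assignment.class_key, set()).add(
                        cluster_id
                    )
    return [
        Signature(
            candidate_id=cid,
            entries={k: frozenset(v) for k, v in sorted(entries[cid].items())},
        )
        for cid in sorted(entries)
    ]
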