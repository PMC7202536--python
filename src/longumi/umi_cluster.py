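"""Paired-UMI network clustering, metric-LCS pruning, chimera removal.

Reads are grouped into per-molecule clusters using the two UMIs jointly.
Each side (5' and 3') is clustered greedily: distinct UMI sequences are
sorted by read support (most-repeated first, ties lexicographic) and each
joins the first centroid within a metric-LCS distance of 0.125 — the
threshold that tolerates at most three differences on a 24-mer — or founds
a new centroid. Because at long-read error rates an error-free UMI copy is
rare, centroids are then refined to the cluster medoid and members
reassigned (the greedy seed is usually itself an errored copy; the medoid
recentres the 0.125 ball on the consensus of the evidence).

The two sides are then linked through the bipartite graph of (5' centroid,
3' centroid) co-occurrences on reads. Mutually dominant pairings define
molecules; a read whose two sides link two *different* molecules is a
PCR-jumping chimera and is removed, clusters that are mostly chimeric are
dropped, and surviving clusters below the minimum depth (default 20 reads)
are discarded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .preprocess import UmiPair

DEFAULT_LCS_THRESHOLD = 0.125
DEFAULT_MIN_DEPTH = 20


@dataclass(frozen=True)
class UmiSequence:
    """A distinct UMI string observed on one side, with its read support."""

    sequence: str
    side: str  # "five_prime" | "three_prime"
    read_support: int = 1

    def __post_init__(self):
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")


@dataclass
class MoleculeCluster:
    """A set of reads sharing a (5', 3') centroid UMI pair."""

    cluster_id: str
    centroid5: str
    centroid3: str
    read_ids: list[str]
    chimera_flag: bool = False

    @property
    def depth(self) -> int:
        return len(self.read_ids)


@dataclass
class ClusterResult:
    clusters: list[MoleculeCluster]
    chimeric_read_ids: list[str]
    unassigned_read_ids: list[str]
    below_depth_read_ids: list[str] = field(default_factory=list)
    graph: nx.Graph | None = None


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of `a` and `b` (DP)."""
    if not a or not b:
        return 0
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(bb) + 1, dtype=np.int32)
    for ch in aa:
        cur = np.empty_like(prev)
        cur[0] = 0
        take = prev[:-1] + (bb == ch)
        np.maximum(take, prev[1:], out=cur[1:])
        np.maximum.accumulate(cur, out=cur)
        prev = cur
    return int(prev[-1])


def metric_lcs_distance(a: str, b: str) -> float:
    """Metric LCS distance: 1 - |LCS(a, b)| / max(|a|, |b|).

    A true string metric in [0, 1]; 0 iff the strings are equal. On 24-mers
    the 0.125 pruning threshold corresponds to tolerating at most three
    differences between a UMI and its cluster centroid.
    """
    if not a and not b:
        raise ValueError("metric LCS distance is undefined for two empty strings")
    return 1.0 - lcs_length(a, b) / max(len(a), len(b))


def _encode_padded(seqs: Sequence[str], pad: int, fill: int) -> np.ndarray:
    arr = np.full((len(seqs), pad), fill, dtype=np.int16)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
    return arr


def _lcs_lengths_batch(query: str, targets: np.ndarray, target_lengths: np.ndarray) -> np.ndarray:
    """|LCS(query, t)| for every padded row t of `targets` at once.

    Rows are padded with -1 and the query with -2 so padding never matches.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8).astype(np.int16)
    k, width = targets.shape
    prev = np.zeros((k, width + 1), dtype=np.int16)
    for ch in q:
        cur = np.zeros_like(prev)
        take = prev[:, :-1] + (targets == ch)
        np.maximum(take, prev[:, 1:], out=cur[:, 1:])
        np.maximum.accumulate(cur, axis=1, out=cur)
        prev = cur
    return prev[np.arange(k), target_lengths]


def _batch_distances(query: str, centroids: list[str], pad: int, cache: dict) -> np.ndarray:
    """Metric-LCS distance from `query` to every centroid (vectorised)."""
    key = (len(centroids), pad)
    if cache.get("key") != key:
        cache["arr"] = _encode_padded(centroids, pad, -1)
        cache["len"] = np.array([len(c) for c in centroids], dtype=np.int64)
        cache["key"] = key
    lcs = _lcs_lengths_batch(query, cache["arr"], cache["len"])
    denom = np.maximum(cache["len"], len(query))
    return 1.0 - lcs / denom


def cluster_side(
    umis: Iterable[UmiSequence] | dict[str, int],
    threshold: float = DEFAULT_LCS_THRESHOLD,
) -> dict[str, str]:
    """Greedy centroid clustering of one side's UMIs.

    UMIs are processed by read support descending (ties lexicographic);
    each joins the first existing centroid within `threshold` metric-LCS
    distance, otherwise it founds its own centroid. Returns a map
    UMI sequence -> centroid sequence; UMIs beyond `threshold` of every
    centroid end up as their own centroid (the pruning rule: members
    farther than the threshold from the cluster's largest UMI never join).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(umis, dict):
        support = dict(umis)
    else:
        support = {}
        for u in umis:
            support[u.sequence] = support.get(u.sequence, 0) + u.read_support
    ordered = sorted(support, key=lambda s: (-support[s], s))
    if not ordered:
        return {}
    pad = max(len(s) for s in ordered)
    assignment: dict[str, str] = {}
    centroids: list[str] = []
    cache: dict = {}
    for seq in ordered:
        if centroids:
            d = _batch_distances(seq, centroids, pad, cache)
            hits = np.nonzero(d <= threshold)[0]
            if hits.size:
                assignment[seq] = centroids[int(hits[0])]
                continue
        centroids.append(seq)
        assignment[seq] = seq
    return assignment


def _medoid(members: list[str], weights: list[int]) -> str:
    """Support-weighted medoid under metric-LCS (ties lexicographic)."""
    if len(members) == 1:
        return members[0]
    pad = max(len(m) for m in members)
    arr = _encode_padded(members, pad, -1)
    lengths = np.array([len(m) for m in members], dtype=np.int64)
    w = np.asarray(weights, dtype=float)
    best, best_cost = None, None
    for i, m in enumerate(members):
        lcs = _lcs_lengths_batch(m, arr, lengths)
        d = 1.0 - lcs / np.maximum(lengths, len(m))
        cost = float(np.dot(w, d))
        if best_cost is None or cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and m < best
        ):
            best, best_cost = m, cost
    return best


def _refine_side(
    support: dict[str, int],
    assignment: dict[str, str],
    threshold: float,
    min_cluster_support: int = 3,
    n_iter: int = 2,
) -> dict[str, str]:
    """Replace centroids by cluster medoids and reassign all UMIs.

    Only clusters with aggregate read support >= `min_cluster_support` act
    as attractors; UMIs that fall outside the threshold of every refined
    centroid revert to singletons.
    """
    seqs = sorted(support, key=lambda s: (-support[s], s))
    pad = max(len(s) for s in seqs)
    for _ in range(n_iter):
        members: dict[str, list[str]] = defaultdict(list)
        for seq, cen in assignment.items():
            members[cen].append(seq)
        scored = []
        for cen, mem in members.items():
            tot = sum(support[m] for m in mem)
            if tot >= min_cluster_support:
                scored.append((tot, _medoid(mem, [support[m] for m in mem])))
        centroids = [c for _, c in sorted(scored, key=lambda t: (-t[0], t[1]))]
        if not centroids:
            return assignment
        # merge attractors that sit within the threshold of a stronger one
        # (fragments of the same molecule recombine around its medoid)
        merged: dict[str, str] = {}
        accepted: list[str] = []
        mcache: dict = {}
        mpad = max(len(c) for c in centroids)
        for cen in centroids:
            target = cen
            if accepted:
                d = _batch_distances(cen, accepted, mpad, mcache)
                hits = np.nonzero(d <= threshold)[0]
                if hits.size:
                    target = accepted[int(hits[0])]
            if target == cen:
                accepted.append(cen)
            merged[cen] = target
        new_assignment: dict[str, str] = {}
        cache: dict = {}
        cpad = max(pad, mpad)
        for seq in seqs:
            d = _batch_distances(seq, centroids, cpad, cache)
            i = int(np.argmin(d))
            if d[i] <= threshold:
                new_assignment[seq] = merged[centroids[i]]
            else:
                new_assignment[seq] = seq
        if new_assignment == assignment:
            break
        assignment = new_assignment
    return assignment


def build_umi_graph(
    pairs: Iterable[UmiPair],
    assignment5: dict[str, str],
    assignment3: dict[str, str],
) -> nx.Graph:
    """Bipartite graph linking 5' and 3' centroids through read co-occurrence."""
    g = nx.Graph()
    for p in pairs:
        c5 = ("5", assignment5.get(p.umi5, p.umi5))
        c3 = ("3", assignment3.get(p.umi3, p.umi3))
        if not g.has_node(c5):
            g.add_node(c5, side="five_prime")
        if not g.has_node(c3):
            g.add_node(c3, side="three_prime")
        if g.has_edge(c5, c3):
            g[c5][c3]["read_ids"].append(p.read_id)
        else:
            g.add_edge(c5, c3, read_ids=[p.read_id])
    return g


def build_molecule_clusters(
    umi_pairs: Iterable[UmiPair],
    threshold: float = DEFAULT_LCS_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    refine_centroids: bool = True,
) -> ClusterResult:
    """Cluster reads into molecules by their UMI pair; flag chimeras.

    Each side is clustered independently; the dominant pairing (most reads)
    of each centroid defines candidate molecules as mutually dominant
    (5', 3') centroid pairs. A read whose sides belong to two different
    candidate molecules links two real molecules and is flagged chimeric; a
    read with one clustered side joins that side's molecule; a read with
    neither side near a molecule stays unassigned. Candidate clusters with
    > 50% chimera-flagged reads are dropped entirely, then clusters below
    `min_depth` are discarded.
    """
    pairs = list(umi_pairs)
    if not pairs:
        raise ValueError("umi_pairs must be nonempty")
    support5: dict[str, int] = Counter(p.umi5 for p in pairs)
    support3: dict[str, int] = Counter(p.umi3 for p in pairs)
    a5 = cluster_side(dict(support5), threshold)
    a3 = cluster_side(dict(support3), threshold)
    if refine_centroids:
        a5 = _refine_side(support5, a5, threshold)
        a3 = _refine_side(support3, a3, threshold)

    graph = build_umi_graph(pairs, a5, a3)

    # dominant partner of each centroid = the edge carrying the most reads
    dominant: dict[tuple[str, str], tuple[str, str]] = {}
    for node in graph.nodes:
        best = max(
            graph[node].items(),
            key=lambda kv: (len(kv[1]["read_ids"]), kv[0]),
        )
        dominant[node] = best[0]
    # mutually dominant pairs are molecules; any other centroid inherits the
    # molecule of its dominant partner (linkage: its reads overwhelmingly
    # co-occur with that partner)
    molecule_of: dict[tuple[str, str], tuple] = {}
    for n in graph.nodes:
        if n[0] == "5" and dominant.get(dominant[n]) == n:
            molecule_of[n] = (n, dominant[n])
            molecule_of[dominant[n]] = (n, dominant[n])
    for _ in range(3):  # short dominant-partner chains resolve in <= 3 hops
        changed = False
        for n in graph.nodes:
            if n not in molecule_of:
                m = molecule_of.get(dominant[n])
                if m is not None:
                    molecule_of[n] = m
                    changed = True
        if not changed:
            break

    members: dict[tuple, list[str]] = defaultdict(list)
    chimeric: list[str] = []
    unassigned: list[str] = []
    for p in pairs:
        c5 = ("5", a5.get(p.umi5, p.umi5))
        c3 = ("3", a3.get(p.umi3, p.umi3))
        m5 = molecule_of.get(c5)
        m3 = molecule_of.get(c3)
        if m5 is not None and m3 is not None:
            if m5 == m3:
                members[m5].append(p.read_id)
            else:
                chimeric.append(p.read_id)  # links two distinct molecules
        elif m5 is not None:
            members[m5].append(p.read_id)
        elif m3 is not None:
            members[m3].append(p.read_id)
        else:
            unassigned.append(p.read_id)

    # order clusters by depth (desc), then centroid pair, for stable ids
    ordered = sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    chimeric_set = set(chimeric)
    clusters: list[MoleculeCluster] = []
    below_depth: list[str] = []
    for k, ((c5, c3), read_ids) in enumerate(ordered):
        flagged = sum(rid in chimeric_set for rid in read_ids)
        cluster = MoleculeCluster(
            cluster_id=f"M{k:04d}",
            centroid5=c5[1],
            centroid3=c3[1],
            read_ids=read_ids,
            chimera_flag=flagged > len(read_ids) / 2,
        )
        if cluster.chimera_flag:
            chimeric.extend(rid for rid in read_ids if rid not in chimeric_set)
        elif cluster.depth < min_depth:
            below_depth.extend(read_ids)
        else:
            clusters.append(cluster)
    return ClusterResult(
        clusters=clusters,
        chimeric_read_ids=chimeric,
        unassigned_read_ids=unassigned,
        below_depth_read_ids=below_depth,
        graph=graph,
    )
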