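"""Molecular aggregates under periodic boundaries: adjacency, connected
components with image-offset tracking, and percolation detection.

A cluster percolates along an axis when offset propagation around a cycle
is inconsistent on that axis — i.e. some molecule would have to sit at two
distinct periodic images at once, so the aggregate connects to its own
image and spans the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory
from .hbonds import HBondCriteria, detect_hbonds

__all__ = [
    "SiteDistanceCriterion",
    "HBondAdjacency",
    "Edge",
    "Cluster",
    "ClusterSet",
    "build_adjacency",
    "find_clusters",
    "clusters_for_trajectory",
    "cluster_statistics",
]


@dataclass(frozen=True)
class SiteDistanceCriterion:
    """Adjacent when the two molecules' labelled sites are within cutoff."""

    site_label: str = "Ob"
    cutoff: float = 6.0


@dataclass(frozen=True)
class HBondAdjacency:
    """Adjacent when the two molecules share at least one hydrogen bond."""

    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    include_ring_oxygens: bool = False


@dataclass(frozen=True)
class Edge:
    i: int                       # molecule list positions (0-based)
    j: int
    shift: tuple[int, int, int]  # image translation: pos_i ~ pos_j + shift * L


@dataclass
class Cluster:
    members: list[int]                      # molecule ids
    offsets: dict[int, tuple[int, int, int]]  # lattice offset per member vs root
    percolating: tuple[bool, bool, bool]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_percolating(self) -> bool:
        return any(self.percolating)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    molecule_ids: list[int]

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    @property
    def largest(self) -> int:
        return max(self.sizes) if self.clusters else 0

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes)) if self.clusters else 0.0

    @property
    def any_percolating(self) -> bool:
        return any(c.is_percolating for c in self.clusters)


def build_adjacency(
    frame: Frame,
    top: Topology,
    criterion: SiteDistanceCriterion | HBondAdjacency = SiteDistanceCriterion(),
    molecule_type: str = "THAL",
) -> tuple[list[Edge], list[int]]:
    """Edge list with image shifts plus the ordered molecule-id list."""
    if isinstance(criterion, SiteDistanceCriterion):
        return _site_distance_adjacency(frame, top, criterion, molecule_type)
    if isinstance(criterion, HBondAdjacency):
        return _hbond_adjacency(frame, top, criterion, molecule_type)
    raise TypeError(f"unsupported adjacency criterion {criterion!r}")


def _site_positions(frame: Frame, top: Topology, label: str,
                    molecule_type: str) -> tuple[np.ndarray, list[int]]:
    labels = top.site_label.astype(str)
    mols: list[int] = []
    pos: list[np.ndarray] = []
    for mol, idx in top.atoms_by_molecule().items():
        if top.molecule_type[idx[0]] != molecule_type:
            continue
        match = [i for i in idx if labels[i] == label]
        if not match:
            raise ValueError(
                f"molecule {mol} ({molecule_type}) has no site {label!r}")
        mols.append(mol)
        pos.append(frame.coordinates[match[0]])
    return np.asarray(pos).reshape(-1, 3), mols


def _site_distance_adjacency(frame, top, criterion, molecule_type):
    pos, mols = _site_positions(frame, top, criterion.site_label, molecule_type)
    edges: list[Edge] = []
    lengths = frame.box.array
    n = len(mols)
    for i in range(n):
        d = pos[i] - pos[i + 1:]
        shift = -np.floor(d / lengths + 0.5).astype(int)   # pos_i ~ pos_j + shift*L
        mic = d + shift * lengths
        r = np.linalg.norm(mic, axis=1)
        for k in np.flatnonzero(r <= criterion.cutoff):
            edges.append(Edge(i, i + 1 + k, tuple(int(s) for s in shift[k])))
    return edges, mols


def _hbond_adjacency(frame, top, criterion, molecule_type):
    mols = sorted(m for m, t in top.molecule_types().items() if t == molecule_type)
    pos_index = {m: k for k, m in enumerate(mols)}
    recs = detect_hbonds(frame, top, criterion.criteria,
                         include_ring_oxygens=criterion.include_ring_oxygens)
    lengths = frame.box.array
    seen: dict[tuple[int, int], tuple[int, int, int]] = {}
    for r in recs:
        mi = int(top.molecule_id[r.donor])
        mj = int(top.molecule_id[r.acceptor])
        if mi not in pos_index or mj not in pos_index:
            continue
        i, j = pos_index[mi], pos_index[mj]
        if i == j:
            continue
        d = frame.coordinates[r.donor] - frame.coordinates[r.acceptor]
        shift = tuple(int(s) for s in -np.floor(d / lengths + 0.5).astype(int))
        key = (i, j) if i < j else (j, i)
        if key not in seen:
            seen[key] = shift if i < j else tuple(-s for s in shift)
    edges = [Edge(i, j, s) for (i, j), s in sorted(seen.items())]
    return edges, mols


class _OffsetUnionFind:
    """Union-find with per-node integer lattice offsets relative to the root."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n
        self.offset = np.zeros((n, 3), dtype=int)
        self.mismatch: dict[int, np.ndarray] = {}

    def find(self, x: int) -> int:
        if self.parent[x] == x:
            return x
        root = self.find(self.parent[x])
        self.offset[x] = self.offset[x] + self.offset[self.parent[x]]
        self.parent[x] = root
        return root

    def union(self, i: int, j: int, shift: np.ndarray) -> None:
        """Impose r_i = r_j + shift (lattice units)."""
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            gap = self.offset[j] + shift - self.offset[i]
            if np.any(gap != 0):
                axes = self.mismatch.setdefault(ri, np.zeros(3, dtype=bool))
                axes |= gap != 0
            return
        flags = self.mismatch.pop(ri, None)
        flags_j = self.mismatch.pop(rj, None)
        if self.rank[ri] < self.rank[rj]:
            self.parent[ri] = rj
            self.offset[ri] = self.offset[j] + shift - self.offset[i]
            new_root = rj
        else:
            self.parent[rj] = ri
            self.offset[rj] = self.offset[i] - shift - self.offset[j]
            new_root = ri
            if self.rank[ri] == self.rank[rj]:
                self.rank[ri] += 1
        combined = np.zeros(3, dtype=bool)
        for f in (flags, flags_j):
            if f is not None:
                combined |= f
        if np.any(combined):
            self.mismatch[new_root] = combined


def find_clusters(edges: Iterable[Edge], molecule_ids: list[int]) -> ClusterSet:
    """Connected components with offset propagation and percolation flags."""
    n = len(molecule_ids)
    uf = _OffsetUnionFind(n)
    for e in edges:
        if not (0 <= e.i < n and 0 <= e.j < n):
            raise ValueError(f"edge {e} references an unknown molecule position")
        uf.union(e.i, e.j, np.asarray(e.shift, dtype=int))
    groups: dict[int, list[int]] = {}
    for x in range(n):
        groups.setdefault(uf.find(x), []).append(x)
    clusters = []
    for root, members in sorted(groups.items()):
        flags = uf.mismatch.get(root, np.zeros(3, dtype=bool))
        clusters.append(Cluster(
            members=[molecule_ids[m] for m in members],
            offsets={molecule_ids[m]: tuple(int(v) for v in uf.offset[m])
                     for m in members},
            percolating=tuple(bool(v) for v in flags),
        ))
    return ClusterSet(clusters=clusters, molecule_ids=list(molecule_ids))


def clusters_for_trajectory(
    traj: Trajectory,
    criterion: SiteDistanceCriterion | HBondAdjacency = SiteDistanceCriterion(),
    molecule_type: str = "THAL",
) -> list[ClusterSet]:
    out = []
    for fr in traj.frames:
        edges, mols = build_adjacency(fr, traj.topology, criterion, molecule_type)
        out.append(find_clusters(edges, mols))
    return out


def cluster_statistics(cluster_sets: list[ClusterSet]) -> pd.DataFrame:
    """Per-frame cluster summary; the trajectory mean sits in ``df.attrs``."""
    if not cluster_sets:
        raise ValueError("need at least one frame of clusters")
    rows = []
    for i, cs in enumerate(cluster_sets):
        n_mol = len(cs.molecule_ids)
        rows.append({
            "frame": i,
            "n_clusters": len(cs.clusters),
            "mean_size": cs.mean_size,
            "largest_size": cs.largest,
            "fraction_in_largest": cs.largest / n_mol if n_mol else 0.0,
            "percolating": cs.any_percolating,
        })
    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        "n_clusters": float(df["n_clusters"].mean()),
        "mean_size": float(df["mean_size"].mean()),
        "largest_size": float(df["largest_size"].mean()),
        "fraction_in_largest": float(df["fraction_in_largest"].mean()),
        "percolation_frequency": float(df["percolating"].mean()),
    }
    return df
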