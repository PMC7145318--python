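"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's vectorized code paths: minimum image
by explicit 27-image enumeration, hydrogen bonds by a triple loop, clusters
by flood fill on a 3x3x3 replicated supercell, MSD by a double loop.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

IMAGE_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def min_image_distance_27(a, b, lengths):
    """Minimum distance over the 27 periodic images, by enumeration."""
    return float(np.linalg.norm(min_image_vector_27(a, b, lengths)))


def min_image_vector_27(a, b, lengths):
    lengths = np.asarray(lengths, float)
    # reduce into one cell first so 27 images always suffice
    d = np.mod(np.asarray(a, float) - np.asarray(b, float), lengths)
    cands = d[None, :] + IMAGE_SHIFTS * lengths[None, :]
    return cands[int(np.argmin(np.linalg.norm(cands, axis=1)))]


def brute_force_hbonds(frame, top, d_max=3.5, angle_max=60.0,
                       include_ring_oxygens=False,
                       one_acceptor_per_hydrogen=True):
    """Triple loop over donors x hydrogens x acceptors.

    Returns a set of (donor, hydrogen, acceptor) index triples.
    """
    lengths = frame.box.array
    labels = top.site_label.astype(str)
    coords = frame.coordinates
    donor_labels = {"Ow", "O1", "O2", "O3", "O4"}
    acceptor_labels = {"Ow", "O1", "O2", "O3", "O4"}
    if include_ring_oxygens:
        acceptor_labels |= {"Ob", "Oe"}
    # attach hydrogens: nearest same-molecule donor oxygen within 1.2 Å
    h_of: dict[int, list[int]] = {}
    for h in range(top.n_atoms):
        if top.element[h] != "H":
            continue
        best, best_d = None, np.inf
        for o in range(top.n_atoms):
            if top.molecule_id[o] != top.molecule_id[h]:
                continue
            if labels[o] not in donor_labels:
                continue
            d = min_image_distance_27(coords[h], coords[o], lengths)
            if d < best_d:
                best, best_d = o, d
        if best is not None and best_d < 1.2:
            h_of.setdefault(best, []).append(h)

    acceptors = [a for a in range(top.n_atoms) if labels[a] in acceptor_labels]
    triples = set()
    for donor, hydrogens in h_of.items():
        for h in hydrogens:
            oh = min_image_vector_27(coords[h], coords[donor], lengths)
            candidates = []
            for a in acceptors:
                if top.molecule_id[a] == top.molecule_id[donor]:
                    continue
                r = min_image_distance_27(coords[donor], coords[a], lengths)
                if r > d_max:
                    continue
                oa = min_image_vector_27(coords[a], coords[donor], lengths)
                cosang = float(oh @ oa / (np.linalg.norm(oh) * np.linalg.norm(oa)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang <= angle_max + 1e-9:
                    candidates.append((r, a))
            if not candidates:
                continue
            if one_acceptor_per_hydrogen:
                candidates = [min(candidates)]
            for _, a in candidates:
                triples.add((donor, h, a))
    return triples


def supercell_clusters(frame, top, site_label, cutoff, molecule_type="THAL"):
    """Cluster partition + percolation by flood fill on a 3x3x3 supercell.

    Returns (partition, percolating) where partition is a frozenset of
    frozensets of molecule ids and percolating maps molecule id -> bool.
    """
    labels = top.site_label.astype(str)
    lengths = frame.box.array
    mols, pos = [], []
    for mol in sorted(set(int(m) for m in top.molecule_id)):
        idx = np.flatnonzero(top.molecule_id == mol)
        if top.molecule_type[idx[0]] != molecule_type:
            continue
        site = [i for i in idx if labels[i] == site_label]
        mols.append(mol)
        pos.append(frame.coordinates[site[0]])
    pos = np.asarray(pos)

    g = nx.Graph()
    nodes = []
    for m, p in zip(mols, pos):
        for shift in IMAGE_SHIFTS:
            node = (m, tuple(int(s) for s in shift))
            g.add_node(node)
            nodes.append((node, p + shift * lengths))
    for k in range(len(nodes)):
        nk, pk = nodes[k]
        for l in range(k + 1, len(nodes)):
            nl, pl = nodes[l]
            if nk[0] == nl[0] and nk[1] == nl[1]:
                continue
            if np.linalg.norm(pk - pl) <= cutoff:
                g.add_edge(nk, nl)

    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = ci
    centre = (0, 0, 0)
    parts = nx.utils.UnionFind(mols)
    for m in mols:
        for m2 in mols:
            if m < m2 and comp_of[(m, centre)] == comp_of[(m2, centre)]:
                parts.union(m, m2)
    # molecules connected through images also cluster together
    for m in mols:
        for m2 in mols:
            if m >= m2:
                continue
            for shift in IMAGE_SHIFTS:
                node = (m2, tuple(int(s) for s in shift))
                if comp_of[(m, centre)] == comp_of[node]:
                    parts.union(m, m2)
    partition = frozenset(frozenset(s) for s in parts.to_sets())
    percolating = {}
    for m in mols:
        perc = False
        for shift in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            if comp_of[(m, centre)] == comp_of[(m, shift)]:
                perc = True
        percolating[m] = perc
    return partition, percolating


def msd_double_loop(tracks):
    """Naive time-origin-averaged MSD of (T, M, 3) tracks."""
    n, m, _ = tracks.shape
    out = np.zeros(n)
    for tau in range(n):
        acc, cnt = 0.0, 0
        for t in range(n - tau):
            acc += np.sum((tracks[t + tau] - tracks[t]) ** 2)
            cnt += m
        out[tau] = acc / cnt
    return out


def dihedral_textbook(p1, p2, p3, p4):
    """IUPAC-convention dihedral via the atan2 formulation, degrees."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    return math.degrees(math.atan2(y, x))
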