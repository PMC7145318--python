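"""Geometric hydrogen-bond detection and the per-class census.

A bond is an intermolecular (donor O, its H, acceptor O) triple with
minimum-image donor-acceptor oxygen separation <= d_max and donor-centred
angle H-O(donor)-O(acceptor) <= angle_max, both inclusive.  The angle
convention is the donor-centred one: a 60° cut is only geometrically
sensible for the angle at the donor oxygen between the O-H bond vector and
the O···O vector (the common D-H···A alternative is cut near 120-180°).
Both the thresholds and the convention are configurable.

Ring oxygens (Ob, Oe) are excluded as acceptors by default; bonds through
them can be re-enabled with ``include_ring_oxygens``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Topology, Trajectory, minimum_image

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "HBondCensus",
    "attached_hydrogens",
    "detect_hbonds",
    "census",
    "DONOR_LABELS",
    "ACCEPTOR_LABELS",
    "RING_OXYGEN_LABELS",
]

DONOR_LABELS = frozenset({"Ow", "O1", "O2", "O3", "O4"})
ACCEPTOR_LABELS = frozenset({"Ow", "O1", "O2", "O3", "O4"})
RING_OXYGEN_LABELS = frozenset({"Ob", "Oe"})

_COVALENT_OH = 1.2  # Å; O-H pairs closer than this count as bonded

CLASS_TOKENS = ("WW", "WT", "TW", "TT")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: donor-acceptor O separation and donor-centred angle."""

    d_max: float = 3.5          # Å
    angle_max: float = 60.0     # degrees

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be > 0")
        if not 0.0 < self.angle_max <= 180.0:
            raise ValueError("angle_max must lie in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float
    bond_class: str


@dataclass
class HBondCensus:
    """Per-class totals (frame mean ± sd) and per-molecule averages."""

    totals_mean: dict[str, float]
    totals_sd: dict[str, float]
    per_molecule: dict[str, float | None]
    n_frames: int
    n_thal: int
    n_water: int
    criteria: HBondCriteria = field(default_factory=HBondCriteria)


def _pair_class(donor_type: str, acceptor_type: str) -> str:
    d = "W" if donor_type == "WATER" else ("T" if donor_type == "THAL" else "?")
    a = "W" if acceptor_type == "WATER" else ("T" if acceptor_type == "THAL" else "?")
    return d + a


def attached_hydrogens(frame: Frame, top: Topology) -> dict[int, list[int]]:
    """Map donor-capable oxygen index -> covalently attached hydrogen indices.

    Attachment is distance based (same molecule, O-H < 1.2 Å).  Raises if a
    hydroxyl oxygen (O1-O4) carries no hydrogen.
    """
    out: dict[int, list[int]] = {}
    labels = top.site_label.astype(str)
    is_donor_o = np.isin(labels, sorted(DONOR_LABELS))
    is_h = top.element.astype(str) == "H"
    coords = frame.coordinates
    for mol, idx in top.atoms_by_molecule().items():
        o_idx = idx[is_donor_o[idx]]
        h_idx = idx[is_h[idx]]
        if len(o_idx) == 0:
            continue
        if len(h_idx) == 0:
            bad = [i for i in o_idx if labels[i] != "Ow"]
            if bad:
                raise ValueError(
                    f"hydroxyl oxygen atom {bad[0]} (molecule {mol}) has no "
                    "attached hydrogen in the topology")
            continue
        d = np.linalg.norm(
            minimum_image(coords[h_idx][:, None, :] - coords[o_idx][None, :, :],
                          frame.box), axis=-1)
        nearest = np.argmin(d, axis=1)
        for k, h in enumerate(h_idx):
            if d[k, nearest[k]] < _COVALENT_OH:
                out.setdefault(int(o_idx[nearest[k]]), []).append(int(h))
        for i in o_idx:
            if labels[i] in ("O1", "O2", "O3", "O4") and int(i) not in out:
                raise ValueError(
                    f"hydroxyl oxygen atom {int(i)} (molecule {mol}) has no "
                    "attached hydrogen in the topology")
    return out


def detect_hbonds(
    frame: Frame,
    top: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    *,
    include_ring_oxygens: bool = False,
    one_acceptor_per_hydrogen: bool = True,
    frame_index: int = 0,
    hydrogen_map: dict[int, list[int]] | None = None,
) -> list[HBondRecord]:
    """All intermolecular hydrogen bonds in one frame.

    With ``one_acceptor_per_hydrogen`` each donor hydrogen is assigned at
    most its nearest qualifying acceptor (prevents double counting in dense
    systems); switch it off to enumerate every qualifying triple.
    """
    labels = top.site_label.astype(str)
    if hydrogen_map is None:
        hydrogen_map = attached_hydrogens(frame, top)
    acceptor_labels = set(ACCEPTOR_LABELS)
    if include_ring_oxygens:
        acceptor_labels |= RING_OXYGEN_LABELS
    acc_idx = np.flatnonzero(np.isin(labels, sorted(acceptor_labels)))
    if len(acc_idx) == 0 or not hydrogen_map:
        return []

    donors = sorted(hydrogen_map)
    don_idx = np.asarray(donors, dtype=int)
    coords = frame.coordinates
    box = frame.box

    # donor-acceptor oxygen separations, minimum image
    doa = minimum_image(
        coords[don_idx][:, None, :] - coords[acc_idx][None, :, :], box)
    r_oa = np.linalg.norm(doa, axis=-1)
    same_mol = top.molecule_id[don_idx][:, None] == top.molecule_id[acc_idx][None, :]
    within = (r_oa <= criteria.d_max) & ~same_mol

    cos_max = math.cos(math.radians(criteria.angle_max))
    mol_types = top.molecule_type.astype(str)
    records: list[HBondRecord] = []
    for di, d_atom in enumerate(don_idx):
        cand = np.flatnonzero(within[di])
        if len(cand) == 0:
            continue
        vec_oa = -doa[di, cand]                    # donor O -> acceptor O
        r = r_oa[di, cand]
        for h in hydrogen_map[int(d_atom)]:
            vec_oh = minimum_image(coords[h] - coords[d_atom], box)
            norm_oh = np.linalg.norm(vec_oh)
            if norm_oh == 0:
                continue
            cosang = vec_oa @ vec_oh / (r * norm_oh)
            ok = np.flatnonzero(cosang >= cos_max - 1e-12)
            if len(ok) == 0:
                continue
            if one_acceptor_per_hydrogen:
                ok = ok[[np.argmin(r[ok])]]
            for j in ok:
                a_atom = int(acc_idx[cand[j]])
                records.append(HBondRecord(
                    frame_index=frame_index,
                    donor=int(d_atom),
                    hydrogen=int(h),
                    acceptor=a_atom,
                    distance=float(r[j]),
                    angle=float(math.degrees(
                        math.acos(min(1.0, max(-1.0, cosang[j]))))),
                    bond_class=_pair_class(mol_types[d_atom], mol_types[a_atom]),
                ))
    return records


def census(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    *,
    include_ring_oxygens: bool = False,
    one_acceptor_per_hydrogen: bool = True,
    reuse_hydrogen_map: bool = False,
) -> HBondCensus:
    """Frame-averaged per-class bond totals and per-molecule averages.

    Per-molecule semantics: WT, TW are divided by the trehalose count; TT is
    counted toward both partners (bond count × 2 / n_THAL); WW is the class
    total divided by the water count.  Classes whose molecule type is absent
    are reported as None rather than zero-divided.
    """
    if traj.n_frames < 1:
        raise ValueError("census needs at least one frame")
    top = traj.topology
    hmap = attached_hydrogens(traj.frames[0], top) if reuse_hydrogen_map else None
    counts = {c: [] for c in CLASS_TOKENS}
    for i, fr in enumerate(traj.frames):
        recs = detect_hbonds(
            fr, top, criteria, include_ring_oxygens=include_ring_oxygens,
            one_acceptor_per_hydrogen=one_acceptor_per_hydrogen,
            frame_index=i, hydrogen_map=hmap)
        per_frame = {c: 0 for c in CLASS_TOKENS}
        for r in recs:
            if r.bond_class in per_frame:
                per_frame[r.bond_class] += 1
        for c in CLASS_TOKENS:
            counts[c].append(per_frame[c])

    n_thal = top.count_molecules("THAL")
    n_water = top.count_molecules("WATER")
    totals_mean = {c: float(np.mean(v)) for c, v in counts.items()}
    totals_sd = {c: float(np.std(v)) for c, v in counts.items()}
    per_molecule: dict[str, float | None] = {}
    for c in CLASS_TOKENS:
        if c == "WW":
            per_molecule[c] = totals_mean[c] / n_water if n_water else None
        elif c == "TT":
            per_molecule[c] = 2.0 * totals_mean[c] / n_thal if n_thal else None
        else:
            per_molecule[c] = totals_mean[c] / n_thal if n_thal else None
    return HBondCensus(
        totals_mean=totals_mean, totals_sd=totals_sd,
        per_molecule=per_molecule, n_frames=traj.n_frames,
        n_thal=n_thal, n_water=n_water, criteria=criteria,
    )
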