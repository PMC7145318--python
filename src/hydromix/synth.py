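"""Synthetic trajectory, configuration and curve generators with known ground truth.

Every analysis stage in this package is validated against fixtures produced
here: rigid pseudo-disaccharide molecules carrying the full site-label set,
three-site waters, Brownian walkers with prescribed diffusion coefficients,
two-state (telegraph) bond/unbond dynamics with prescribed rate constants,
clustered/percolating aggregates under periodic boundaries, and
density-vs-temperature curves with a prescribed maximum.

The molecular templates are deliberately coarse: analyses only need correct
labels, multiplicities and controllable geometry, not chemical accuracy.
All generators are deterministic under a fixed seed.  The Brownian generator
emits unwrapped coordinates in an auxiliary channel (``Frame.unwrapped``);
mean-square displacements must never be computed on wrapped coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import Box, Frame, Topology, Trajectory

__all__ = [
    "MoleculeTemplate",
    "TelegraphSpec",
    "TelegraphResult",
    "water_template",
    "point_template",
    "pseudo_trehalose_template",
    "generate_gas_configuration",
    "generate_hydrated_trehalose",
    "generate_clustered_configuration",
    "generate_brownian_trajectory",
    "simulate_telegraph_states",
    "generate_telegraph_hbond_trajectory",
    "generate_density_curves",
]

_CC = 1.54     # ring C-C / hexagon radius, Å
_CO = 1.43     # C-O bond, Å
_OH = 0.96     # O-H bond, Å
_HOH_DEG = 104.5


def signed_dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                    p4: np.ndarray) -> float:
    """Standard signed dihedral (degrees, in (-180, 180]) of four points."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    angle = math.degrees(math.atan2(y, float(np.dot(n1, n2))))
    return angle if angle > -180.0 else 180.0


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid molecule: local coordinates plus per-atom labels and parameters."""

    molecule_type: str
    labels: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray
    masses: tuple[float, ...]
    charges: tuple[float, ...]
    lj_sigma: tuple[float, ...]
    lj_epsilon: tuple[float, ...]
    #: per hydroxyl oxygen: (atom index, outward unit vector, plane-normal unit vector)
    hydroxyl_frames: tuple[tuple[int, tuple[float, ...], tuple[float, ...]], ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        if coords.shape[0] != len(self.labels):
            raise ValueError("labels/coords length mismatch")
        if coords.shape[0] > 1:
            d = coords[:, None, :] - coords[None, :, :]
            r = np.linalg.norm(d, axis=-1)
            np.fill_diagonal(r, np.inf)
            if r.min() <= 0.9:
                raise ValueError(
                    f"template has intramolecular distance {r.min():.3f} Å <= 0.9 Å")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def centered(self) -> np.ndarray:
        return self.coords - self.coords.mean(axis=0)


def water_template(q_ow: float = -0.8476, q_hw: float = 0.4238,
                   sigma_ow: float = 3.166, eps_ow: float = 0.650) -> MoleculeTemplate:
    """Rigid 3-site water; SPC-like charges/LJ by default (test fixture values)."""
    half = math.radians(_HOH_DEG / 2.0)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [_OH * math.cos(half), _OH * math.sin(half), 0.0],
        [_OH * math.cos(half), -_OH * math.sin(half), 0.0],
    ])
    return MoleculeTemplate(
        molecule_type="WATER",
        labels=("Ow", "Hw", "Hw"),
        elements=("O", "H", "H"),
        coords=coords,
        masses=(15.9994, 1.008, 1.008),
        charges=(q_ow, q_hw, q_hw),
        lj_sigma=(sigma_ow, 0.0, 0.0),
        lj_epsilon=(eps_ow, 0.0, 0.0),
    )


def point_template(molecule_type: str = "OTHER", element: str = "X",
                   mass: float = 39.948, charge: float = 0.0,
                   sigma: float = 3.4, epsilon: float = 1.0) -> MoleculeTemplate:
    """Single-site particle, used for ideal-gas and Brownian fixtures."""
    return MoleculeTemplate(
        molecule_type=molecule_type, labels=("X",), elements=(element,),
        coords=np.zeros((1, 3)), masses=(mass,), charges=(charge,),
        lj_sigma=(sigma,), lj_epsilon=(epsilon,),
    )


def _hexose_ring(center: np.ndarray, e1: np.ndarray, e2: np.ndarray):
    """One coarse hexose ring: C1..C6 hexagon, hydroxyl O1..O4 (each with Ho)
    on C2..C5, ether oxygen Oe above the ring centre.

    Returns (labels, elements, coords, hydroxyl_frames).
    """
    e3 = np.cross(e1, e2)
    labels, elements, coords, frames = [], [], [], []
    carbons = []
    for k in range(6):
        theta = math.radians(60.0 * k)
        pos = center + _CC * (math.cos(theta) * e1 + math.sin(theta) * e2)
        carbons.append(pos)
        labels.append(f"C{k + 1}")
        elements.append("C")
        coords.append(pos)
    # hydroxyls on C2..C5, pointing radially outward
    for j in range(4):
        c = carbons[j + 1]
        rhat = (c - center) / np.linalg.norm(c - center)
        o_pos = c + _CO * rhat
        frames.append((len(coords), rhat, e3))
        labels.append(f"O{j + 1}")
        elements.append("O")
        coords.append(o_pos)
        labels.append("Ho")
        elements.append("H")
        coords.append(o_pos + _OH * rhat)
    labels.append("Oe")
    elements.append("O")
    coords.append(center + 1.35 * e3)
    return labels, elements, coords, frames


def pseudo_trehalose_template(dihedral_deg: float = 140.0,
                              bridge_bend_deg: float = 150.0) -> MoleculeTemplate:
    """Rigid two-ring pseudo-trehalose with the full site-label set.

    Two coarse hexose rings joined by a bridging oxygen Ob; the inter-ring
    dihedral Oe(ring 1)-C1(ring 1)-Ob-C1(ring 2) is set to ``dihedral_deg``.
    ``bridge_bend_deg`` is the C1-Ob-C1 angle.
    """
    xhat = np.array([1.0, 0.0, 0.0])
    # ring 1 in the xy-plane
    lab_a, el_a, xyz_a, frames_a = _hexose_ring(np.zeros(3), xhat,
                                                np.array([0.0, 1.0, 0.0]))
    c1a = np.array(xyz_a[0])
    ob = c1a + _CO * xhat
    bend = math.radians(180.0 - bridge_bend_deg)
    u = np.array([math.cos(bend), math.sin(bend), 0.0])
    c1b = ob + _CO * u
    center_b = c1b + _CC * u
    e1b = -u
    e2b = np.cross(np.array([0.0, 0.0, 1.0]), e1b)
    lab_b, el_b, xyz_b, frames_b = _hexose_ring(center_b, e1b, e2b)
    xyz_b = [np.asarray(p, float) for p in xyz_b]
    # ring 2 built so its C1 coincides with the bridge attachment point
    assert np.allclose(xyz_b[0], c1b)

    oe_a = xyz_a[-1]

    def rotate_ring_b(alpha_deg: float) -> list[np.ndarray]:
        rot = Rotation.from_rotvec(np.radians(alpha_deg) * xhat)
        return [ob + rot.apply(p - ob) for p in xyz_b]

    delta0 = signed_dihedral(oe_a, c1a, ob, c1b)
    best = None
    for alpha in (dihedral_deg - delta0, delta0 - dihedral_deg):
        cand = rotate_ring_b(alpha)
        got = signed_dihedral(oe_a, c1a, ob, cand[0])
        err = abs((got - dihedral_deg + 180.0) % 360.0 - 180.0)
        if best is None or err < best[0]:
            best = (err, cand)
    xyz_b = best[1]

    labels = lab_a + ["Ob"] + lab_b
    elements = el_a + ["O"] + el_b
    coords = np.array(xyz_a + [ob] + xyz_b)
    n_a = len(lab_a)
    hydroxyl_frames = []
    for idx, rhat, nhat in frames_a:
        hydroxyl_frames.append((idx, tuple(rhat), tuple(nhat)))
    ring_c = coords[n_a + 1: n_a + 7]
    nhat2 = np.cross(ring_c[1] - ring_c[0], ring_c[2] - ring_c[0])
    nhat2 = nhat2 / np.linalg.norm(nhat2)
    for idx, _rhat, _nhat in frames_b:
        # outward direction survives the ring rotation as the O->Ho bond
        o_pos = coords[n_a + 1 + idx]
        ho_pos = coords[n_a + 1 + idx + 1]
        rhat2 = (ho_pos - o_pos) / np.linalg.norm(ho_pos - o_pos)
        hydroxyl_frames.append((n_a + 1 + idx, tuple(rhat2), tuple(nhat2)))

    masses = tuple(12.011 if e == "C" else (15.9994 if e == "O" else 1.008)
                   for e in elements)
    charges = []
    for lab, e in zip(labels, elements):
        if e == "C":
            charges.append(0.2083333333)
        elif lab in ("O1", "O2", "O3", "O4"):
            charges.append(-0.6)
        elif lab in ("Oe", "Ob"):
            charges.append(-0.3)
        else:  # Ho
            charges.append(0.4)
    sigma = tuple(3.5 if e == "C" else (3.0 if e == "O" else 0.0) for e in elements)
    eps = tuple(0.3 if e == "C" else (0.5 if e == "O" else 0.0) for e in elements)
    return MoleculeTemplate(
        molecule_type="THAL", labels=tuple(labels), elements=tuple(elements),
        coords=coords, masses=masses, charges=tuple(charges),
        lj_sigma=sigma, lj_epsilon=eps,
        hydroxyl_frames=tuple(hydroxyl_frames),
    )


# ---------------------------------------------------------------------------
# assembly helpers


class _SystemBuilder:
    """Accumulates placed molecules into a Topology + coordinate array."""

    def __init__(self) -> None:
        self._labels: list[str] = []
        self._elements: list[str] = []
        self._mol_ids: list[int] = []
        self._mol_types: list[str] = []
        self._masses: list[float] = []
        self._charges: list[float] = []
        self._sigma: list[float] = []
        self._eps: list[float] = []
        self._coords: list[np.ndarray] = []
        self._next_mol = 0

    def add(self, template: MoleculeTemplate, coords: np.ndarray) -> int:
        mol_id = self._next_mol
        self._next_mol += 1
        self._labels.extend(template.labels)
        self._elements.extend(template.elements)
        self._mol_ids.extend([mol_id] * template.n_atoms)
        self._mol_types.extend([template.molecule_type] * template.n_atoms)
        self._masses.extend(template.masses)
        self._charges.extend(template.charges)
        self._sigma.extend(template.lj_sigma)
        self._eps.extend(template.lj_epsilon)
        self._coords.append(np.asarray(coords, float).reshape(-1, 3))
        return mol_id

    def topology(self) -> Topology:
        return Topology(
            element=self._elements, site_label=self._labels,
            molecule_id=self._mol_ids, molecule_type=self._mol_types,
            mass=self._masses, charge=self._charges,
            lj_sigma=self._sigma, lj_epsilon=self._eps,
        )

    def coordinates(self) -> np.ndarray:
        if not self._coords:
            return np.zeros((0, 3))
        return np.concatenate(self._coords, axis=0)


def _random_rotation(rng: np.random.Generator) -> Rotation:
    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def default_template(molecule_type: str) -> MoleculeTemplate:
    if molecule_type == "THAL":
        return pseudo_trehalose_template()
    if molecule_type == "WATER":
        return water_template()
    return point_template(molecule_type=molecule_type)


def _place_blocks(
    blocks: Sequence[tuple[np.ndarray, np.ndarray]],
    box: Box,
    rng: np.random.Generator,
    min_distance: float,
    max_tries: int,
    rotate: bool = True,
) -> list[np.ndarray]:
    """Place rigid blocks (coords, heavy_mask) with uniform random centre and
    orientation, resampling on heavy-atom clash under minimum image."""
    from .core import minimum_image

    lengths = box.array
    placed_heavy: list[np.ndarray] = []
    heavy_arr = np.zeros((0, 3))
    out = []
    for coords, heavy in blocks:
        local = coords - coords.mean(axis=0)
        single = coords.shape[0] == 1
        for attempt in range(max_tries):
            centre = rng.uniform(0.0, 1.0, 3) * lengths
            if rotate and not single:
                cand = centre + _random_rotation(rng).apply(local)
            else:
                cand = centre + local
            cand_heavy = cand[heavy]
            if heavy_arr.shape[0]:
                d = minimum_image(
                    cand_heavy[:, None, :] - heavy_arr[None, :, :], box)
                if np.min(np.linalg.norm(d, axis=-1)) < min_distance:
                    continue
            out.append(cand)
            heavy_arr = np.concatenate([heavy_arr, cand_heavy], axis=0)
            break
        else:
            raise ValueError(
                f"could not place molecule after {max_tries} attempts; "
                "try a larger box")
    return out


def generate_gas_configuration(
    counts: Mapping[str, int],
    box: Box,
    seed: int,
    n_frames: int = 1,
    min_distance: float = 2.0,
    max_tries: int = 500,
    templates: Mapping[str, MoleculeTemplate] | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Uniformly placed, uniformly oriented molecules with clash resampling.

    ``counts`` maps molecule-type tokens to molecule counts; THAL and WATER
    get their standard templates, any other token a single-site particle.
    Frames are independent configurations sharing one topology.
    """
    rng = np.random.default_rng(seed)
    tmpl = {t: (templates or {}).get(t) or default_template(t) for t in counts}
    builder = _SystemBuilder()
    order: list[str] = []
    for t, n in counts.items():
        if n < 0:
            raise ValueError("molecule counts must be >= 0")
        for _ in range(n):
            builder.add(tmpl[t], tmpl[t].coords)  # placeholder coords
            order.append(t)
    top = builder.topology()
    blocks = [(tmpl[t].coords, tmpl[t].heavy_mask) for t in order]
    frames = []
    for i in range(n_frames):
        placed = _place_blocks(blocks, box, rng, min_distance, max_tries)
        coords = (np.concatenate(placed, axis=0) if placed else np.zeros((0, 3)))
        frames.append(Frame(time=i * dt, box=box, coordinates=coords))
    return Trajectory(topology=top, frames=frames)


def generate_hydrated_trehalose(
    n_thal: int,
    waters_per_site: int,
    d_hb: float,
    box: Box,
    seed: int,
    n_extra_waters: int = 0,
    tilt_deg: float = 70.0,
    template: MoleculeTemplate | None = None,
) -> Trajectory:
    """Pseudo-trehalose molecules, each hydroxyl oxygen decorated with
    ``waters_per_site`` donor waters at distance ``d_hb``.

    Each water's donating hydrogen points exactly at its hydroxyl oxygen
    (donor angle 0°); the O(thal)->Ow direction is tilted ``tilt_deg`` out of
    the ring plane so the trehalose hydroxyl hydrogen does NOT satisfy the
    60° donor criterion toward the water.  By construction, detection at the
    3.5 Å / 60° criteria finds exactly ``8 * n_thal * waters_per_site``
    water->THAL bonds and no others.
    """
    if waters_per_site < 0:
        raise ValueError("waters_per_site must be >= 0")
    if waters_per_site and not (2.4 < d_hb <= 3.5):
        raise ValueError("d_hb must lie in (2.4, 3.5] for a detectable bond")
    rng = np.random.default_rng(seed)
    thal = template or pseudo_trehalose_template()
    wat = water_template()

    # build one decorated rigid unit: THAL + its shell waters
    unit_coords = [thal.coords]
    water_coords: list[np.ndarray] = []
    tilt = math.radians(tilt_deg)
    hw1_dir = wat.coords[1] / np.linalg.norm(wat.coords[1])  # O->H bond in template
    for o_idx, rhat, nhat in thal.hydroxyl_frames:
        rhat = np.asarray(rhat)
        nhat = np.asarray(nhat)
        that = np.cross(nhat, rhat)
        o_pos = thal.coords[o_idx]
        for k in range(waters_per_site):
            psi = 2.0 * math.pi * k / max(waters_per_site, 1)
            direction = (math.cos(tilt) * rhat
                         + math.sin(tilt) * (math.cos(psi) * nhat
                                             + math.sin(psi) * that))
            ow = o_pos + d_hb * direction
            # orient the water so one O-H bond points back at the hydroxyl O
            rot = Rotation.align_vectors([-direction], [hw1_dir])[0]
            water_coords.append(ow + rot.apply(wat.coords))
    unit = np.concatenate(unit_coords + water_coords, axis=0) if water_coords \
        else thal.coords
    heavy = np.concatenate(
        [thal.heavy_mask] + [wat.heavy_mask] * len(water_coords))

    blocks = [(unit, heavy)] * n_thal + \
        [(wat.coords, wat.heavy_mask)] * n_extra_waters
    placed = _place_blocks(blocks, box, rng, min_distance=3.6, max_tries=500)

    builder = _SystemBuilder()
    coords_out = []
    n_shell = 8 * waters_per_site
    for i in range(n_thal):
        unit_placed = placed[i]
        builder.add(thal, thal.coords)
        coords_out.append(unit_placed[:thal.n_atoms])
        for w in range(n_shell):
            builder.add(wat, wat.coords)
            lo = thal.n_atoms + 3 * w
            coords_out.append(unit_placed[lo:lo + 3])
    for j in range(n_extra_waters):
        builder.add(wat, wat.coords)
        coords_out.append(placed[n_thal + j])
    top = builder.topology()
    coords = np.concatenate(coords_out, axis=0) if coords_out else np.zeros((0, 3))
    return Trajectory(topology=top, frames=[Frame(0.0, box, coords)])


def generate_clustered_configuration(
    cluster_sizes: Sequence[int],
    link_distance: float,
    box: Box,
    percolating: bool = False,
    seed: int = 0,
    template: MoleculeTemplate | None = None,
) -> Trajectory:
    """Chains of molecules whose bridge oxygens (Ob) link consecutive members.

    Consecutive members' Ob sites sit within ``link_distance``; distinct
    clusters are separated by more than twice that.  With ``percolating``
    the first cluster is a chain whose Ob sites are spaced Lx/n apart along
    x, closing on its own periodic image.
    """
    if any(s < 1 for s in cluster_sizes):
        raise ValueError("cluster sizes must be >= 1")
    rng = np.random.default_rng(seed)
    thal = template or pseudo_trehalose_template()
    ob_idx = list(thal.labels).index("Ob")
    ob_local = thal.coords[ob_idx]
    lengths = box.array
    spacing = 0.9 * link_distance
    pitch = 2.05 * link_distance
    jitter_amp = 0.02 * link_distance

    ob_positions: list[np.ndarray] = []
    sizes = list(cluster_sizes)
    margin = 0.5 * pitch
    row, layer = 0, 0
    for ci, size in enumerate(sizes):
        if percolating and ci == 0:
            s = lengths[0] / size
            if s > link_distance:
                raise ValueError(
                    f"box x-length {lengths[0]} too large for a percolating "
                    f"chain of {size} molecules with link distance {link_distance}")
            xs = np.arange(size) * s
        else:
            extent = (size - 1) * spacing
            if extent > lengths[0] - 2.0 * link_distance:
                raise ValueError(
                    f"cluster of {size} molecules does not fit the box along x")
            xs = 0.5 * (lengths[0] - extent) + np.arange(size) * spacing
        y = margin + row * pitch
        z = margin + layer * pitch
        if y > lengths[1] - margin:
            raise ValueError("clusters do not fit the box; enlarge it")
        for x in xs:
            jit = rng.uniform(-jitter_amp, jitter_amp, 3)
            jit[0] *= 0.5  # keep consecutive x-spacings within the link distance
            ob_positions.append(np.array([x, y, z]) + jit)
        layer += 1
        if margin + layer * pitch > lengths[2] - margin:
            layer = 0
            row += 1

    builder = _SystemBuilder()
    coords_out = []
    for pos in ob_positions:
        builder.add(thal, thal.coords)
        coords_out.append(np.mod(thal.coords - ob_local + pos, lengths))
    top = builder.topology()
    coords = np.concatenate(coords_out, axis=0)
    return Trajectory(topology=top, frames=[Frame(0.0, box, coords)])


def generate_brownian_trajectory(
    counts: Mapping[str, int],
    D_by_species: Mapping[str, float],
    dt: float,
    n_steps: int,
    box: Box,
    seed: int,
) -> Trajectory:
    """Independent Gaussian walkers; per-axis step variance 2*D*dt per species.

    Produces ``n_steps + 1`` frames.  Wrapped coordinates go in
    ``Frame.coordinates``; image-consistent unwrapped positions in
    ``Frame.unwrapped``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for sp, d in D_by_species.items():
        if d < 0:
            raise ValueError(f"diffusion coefficient for {sp} must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = box.array
    builder = _SystemBuilder()
    sigmas = []
    for sp, n in counts.items():
        tmpl = point_template(molecule_type=sp)
        if sp not in D_by_species:
            raise ValueError(f"no diffusion coefficient for species {sp!r}")
        for _ in range(n):
            builder.add(tmpl, tmpl.coords)
            sigmas.append(math.sqrt(2.0 * D_by_species[sp] * dt))
    top = builder.topology()
    n_part = len(sigmas)
    sigma = np.asarray(sigmas)[None, :, None]
    r0 = rng.uniform(0.0, 1.0, (n_part, 3)) * lengths
    steps = rng.standard_normal((n_steps, n_part, 3)) * sigma
    unwrapped = np.concatenate(
        [r0[None], r0[None] + np.cumsum(steps, axis=0)], axis=0)
    wrapped = np.mod(unwrapped, lengths)
    frames = [Frame(time=t * dt, box=box, coordinates=wrapped[t],
                    unwrapped=unwrapped[t]) for t in range(n_steps + 1)]
    return Trajectory(topology=top, frames=frames)


# ---------------------------------------------------------------------------
# telegraph (two-state) hydrogen-bond dynamics


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-state bond/unbond dynamics for donor-acceptor water pairs."""

    k_forward: float      # ps^-1, bond -> broken
    k_backward: float     # ps^-1, broken -> bond
    n_pairs: int
    dt: float             # ps
    n_steps: int
    bonded_distance: float = 2.8
    broken_distance: float = 3.2
    broken_angle_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.k_forward <= 0 or self.k_backward <= 0:
            raise ValueError("rates must be > 0")
        if self.dt <= 0 or self.n_steps < 1 or self.n_pairs < 1:
            raise ValueError("dt, n_steps and n_pairs must be positive")
        if not self.bonded_distance <= 3.5:
            raise ValueError("bonded geometry must satisfy the distance criterion")
        if self.broken_distance > 3.5 and self.broken_angle_deg <= 60.0:
            pass  # broken by distance
        elif self.broken_angle_deg <= 60.0:
            raise ValueError("broken geometry must violate the bond criteria")
        if self.broken_distance > 3.5:
            raise ValueError(
                "broken separation must stay below the reformation cutoff (3.5 Å)")

    @property
    def p_bonded(self) -> float:
        """Stationary bonded fraction k_b / (k_f + k_b)."""
        return self.k_backward / (self.k_forward + self.k_backward)


def simulate_telegraph_states(spec: TelegraphSpec, seed: int) -> np.ndarray:
    """Boolean state matrix (n_pairs, n_steps): True = bonded.

    Each pair is an independent two-state chain with per-step switching
    probabilities 1 - exp(-k*dt), started from the stationary distribution.
    """
    rng = np.random.default_rng(seed)
    p_f = 1.0 - math.exp(-spec.k_forward * spec.dt)
    p_b = 1.0 - math.exp(-spec.k_backward * spec.dt)
    states = np.empty((spec.n_pairs, spec.n_steps), dtype=bool)
    states[:, 0] = rng.random(spec.n_pairs) < spec.p_bonded
    u = rng.random((spec.n_pairs, spec.n_steps - 1))
    for t in range(1, spec.n_steps):
        prev = states[:, t - 1]
        switch = np.where(prev, u[:, t - 1] < p_f, u[:, t - 1] < p_b)
        states[:, t] = prev ^ switch
    return states


@dataclass
class TelegraphResult:
    """Telegraph trajectory plus the hidden ground-truth state series."""

    trajectory: Trajectory
    states: np.ndarray          # (n_pairs, n_steps) bool, True = bonded
    spec: TelegraphSpec
    donor_oxygens: np.ndarray   # atom indices of the donor Ow per pair
    acceptor_oxygens: np.ndarray


def generate_telegraph_hbond_trajectory(spec: TelegraphSpec, seed: int) -> TelegraphResult:
    """Water pairs alternating between bonded and broken geometry.

    Pairs sit on a 10 Å grid so they never interact across cells.  In the
    bonded state the donor O-H bond points exactly at the acceptor oxygen at
    ``bonded_distance``; in the broken state the donor is rotated to
    ``broken_angle_deg`` and the acceptor moved to ``broken_distance`` —
    violating the 60° criterion while staying inside the reformation cutoff.
    """
    states = simulate_telegraph_states(spec, seed)
    wat = water_template()

    def planar_water(theta1_deg: float) -> np.ndarray:
        """In-plane water: Ow at origin, first O-H bond at theta1 from +x."""
        t1 = math.radians(theta1_deg)
        t2 = math.radians(theta1_deg - _HOH_DEG)
        return np.array([
            [0.0, 0.0, 0.0],
            [_OH * math.cos(t1), _OH * math.sin(t1), 0.0],
            [_OH * math.cos(t2), _OH * math.sin(t2), 0.0],
        ])

    # bonded: first O-H bond points exactly at the acceptor (+x); the second
    # sits at -104.5°.  broken: rotated by -broken_angle so BOTH hydrogens
    # violate the angle criterion (the second lands at -(angle + 104.5)°).
    donor_bonded = planar_water(0.0)
    donor_broken = planar_water(-spec.broken_angle_deg)
    # acceptor: H-H bisector along +x so its hydrogens never donate back
    acceptor_local = planar_water(_HOH_DEG / 2.0)

    cell = 10.0
    n_side = int(math.ceil(spec.n_pairs ** (1.0 / 3.0)))
    box = Box((n_side * cell, n_side * cell, n_side * cell))
    idx = np.arange(spec.n_pairs)
    origins = (np.stack([idx % n_side, (idx // n_side) % n_side,
                         idx // (n_side * n_side)], axis=1) * cell + 2.0)

    builder = _SystemBuilder()
    donor_ox, acc_ox = [], []
    for p in range(spec.n_pairs):
        builder.add(wat, wat.coords)
        builder.add(wat, wat.coords)
        donor_ox.append(6 * p)       # donor Ow is atom 0 of its water
        acc_ox.append(6 * p + 3)
    top = builder.topology()

    frames = []
    for t in range(spec.n_steps):
        bonded = states[:, t]
        coords = np.empty((spec.n_pairs * 6, 3))
        donor = np.where(bonded[:, None, None], donor_bonded[None],
                         donor_broken[None])
        dist = np.where(bonded, spec.bonded_distance, spec.broken_distance)
        acc = acceptor_local[None] + np.stack(
            [dist, np.zeros_like(dist), np.zeros_like(dist)], axis=1)[:, None, :]
        coords[0::6], coords[1::6], coords[2::6] = (
            (origins[:, None, :] + donor)[:, 0],
            (origins[:, None, :] + donor)[:, 1],
            (origins[:, None, :] + donor)[:, 2])
        coords[3::6], coords[4::6], coords[5::6] = (
            (origins[:, None, :] + acc)[:, 0],
            (origins[:, None, :] + acc)[:, 1],
            (origins[:, None, :] + acc)[:, 2])
        frames.append(Frame(time=t * spec.dt, box=box, coordinates=coords))
    traj = Trajectory(topology=top, frames=frames)
    return TelegraphResult(trajectory=traj, states=states, spec=spec,
                           donor_oxygens=np.array(donor_ox),
                           acceptor_oxygens=np.array(acc_ox))


# ---------------------------------------------------------------------------
# density-temperature curves


def generate_density_curves(
    tg_by_omega: Mapping[float, float],
    temperatures: Sequence[float],
    curvature: float = 2.0e-5,
    noise_sd: float = 0.0,
    seed: int = 0,
    rho_max: float | None = None,
) -> pd.DataFrame:
    """Parabolic density-vs-temperature curves with maxima at prescribed Tg.

    rho(T; omega) = rho0(omega) - curvature * (T - Tg(omega))**2 + noise,
    with rho0(omega) = 1.0 + 0.4 * omega unless ``rho_max`` is given.
    """
    temps = np.asarray(sorted(temperatures), float)
    if len(temps) < 4:
        raise ValueError("need at least 4 temperatures")
    rng = np.random.default_rng(seed)
    rows = []
    for omega, tg in tg_by_omega.items():
        n_below = int(np.sum(temps < tg))
        n_above = int(np.sum(temps > tg))
        if n_below < 2 or n_above < 2:
            raise ValueError(
                f"Tg={tg} K needs >= 2 temperature points on each side of it")
        rho0 = rho_max if rho_max is not None else 1.0 + 0.4 * omega
        rho = rho0 - curvature * (temps - tg) ** 2
        if noise_sd > 0:
            rho = rho + rng.normal(0.0, noise_sd, len(temps))
        for t, r in zip(temps, rho):
            rows.append({"omega": omega, "T": t, "rho": r})
    return pd.DataFrame(rows)
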