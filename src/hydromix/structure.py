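"""Spatial correlation functions: RDFs, running integrals, spatial and
combined (distance-angle) distribution functions, and dihedral distributions.

Intramolecular pairs are always excluded: these tools probe intermolecular
structure.  Site labels may carry an occurrence qualifier ``label@k``
(k = 1-based occurrence within the molecule, in atom-index order) to
disambiguate labels that appear once per ring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .core import Topology, Trajectory, minimum_image
from .synth import signed_dihedral

__all__ = [
    "RDFResult",
    "CDFResult",
    "SDFResult",
    "DihedralResult",
    "compute_rdf",
    "compute_running_integral",
    "compute_sdf",
    "compute_cdf_distance_angle",
    "compute_dihedral_distribution",
    "resolve_qualified_label",
]

DEFAULT_BIN_WIDTH = 0.05  # Å


@dataclass
class RDFResult:
    """g(r) with running integral on shared bins."""

    r: np.ndarray           # bin centres, Å
    g: np.ndarray
    n_r: np.ndarray         # running integral N(r)
    bin_width: float
    rho_b: float            # partner number density, Å^-3
    n_frames: int
    n_a: int
    n_b: int
    pair: tuple[str, str] = ("A", "B")


@dataclass
class CDFResult:
    """Joint (distance, acute inter-vector angle) probability density."""

    r_edges: np.ndarray       # Å
    phi_edges: np.ndarray     # degrees, [0, 90]
    density: np.ndarray       # shape (n_r, n_phi); integrates to 1
    n_samples: int
    samples: np.ndarray | None = None   # (n, 2) raw (r, phi) when requested

    @property
    def r_marginal(self) -> np.ndarray:
        dphi = np.diff(self.phi_edges)
        return self.density @ dphi

    @property
    def phi_marginal(self) -> np.ndarray:
        dr = np.diff(self.r_edges)
        return dr @ self.density


@dataclass
class SDFResult:
    """3-D target-site density (Å^-3) in the body frame of a reference molecule."""

    density: np.ndarray        # (nx, ny, nz)
    origin: np.ndarray         # grid corner, Å
    spacing: float             # Å
    n_reference_frames: int    # reference-molecule × frame count

    @property
    def total_mass(self) -> float:
        """Mean number of target sites inside the grid per reference."""
        return float(self.density.sum() * self.spacing ** 3)


@dataclass
class DihedralResult:
    bin_centers: np.ndarray      # degrees, (-180, 180]
    density: np.ndarray          # per degree; integrates to 1
    circular_mean: float
    circular_std: float
    n_samples: int


# ---------------------------------------------------------------------------
# selection helpers


def _split_qualifier(label: str) -> tuple[str, int | None]:
    if "@" in label:
        base, _, k = label.partition("@")
        return base, int(k)
    return label, None


def resolve_qualified_label(top: Topology, molecule_type: str, label: str) -> dict[int, int]:
    """Map molecule_id -> atom index for a (possibly ``label@k``-qualified) site.

    Raises if an unqualified label matches more than one atom per molecule.
    """
    base, occurrence = _split_qualifier(label)
    out: dict[int, int] = {}
    labels = top.site_label.astype(str)
    for mol, idx in top.atoms_by_molecule().items():
        if top.molecule_type[idx[0]] != molecule_type:
            continue
        matches = [int(i) for i in idx if labels[i] == base]
        if not matches:
            raise ValueError(
                f"no atom with label {base!r} in molecule {mol} ({molecule_type})")
        if occurrence is None:
            if len(matches) > 1:
                raise ValueError(
                    f"label {base!r} matches {len(matches)} atoms per "
                    f"{molecule_type} molecule; qualify it as "
                    f"'{base}@1'..'{base}@{len(matches)}'")
            out[mol] = matches[0]
        else:
            if occurrence < 1 or occurrence > len(matches):
                raise ValueError(
                    f"occurrence {occurrence} out of range for label {base!r} "
                    f"({len(matches)} matches per molecule)")
            out[mol] = matches[occurrence - 1]
    if not out:
        raise ValueError(f"no {molecule_type} molecules in topology")
    return out


# ---------------------------------------------------------------------------
# RDF


def compute_rdf(
    traj: Trajectory,
    sites_a: np.ndarray,
    sites_b: np.ndarray,
    r_max: float = 12.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    pair: tuple[str, str] = ("A", "B"),
) -> RDFResult:
    """Site-site radial distribution function with running integral.

    Normalized by shell volume 4*pi*r^2*dr, partner density and the number
    of A sites and frames.  Intramolecular and self pairs are excluded; the
    partner density is corrected for the per-A excluded (same-molecule)
    partner count so overlapping selections stay normalized.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sites_a = np.asarray(sites_a, dtype=int)
    sites_b = np.asarray(sites_b, dtype=int)
    if len(sites_a) == 0 or len(sites_b) == 0:
        raise ValueError("empty site selection")
    min_len = min(fr.box.min_length for fr in traj.frames)
    if r_max > 0.5 * min_len + 1e-9:
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest box length ({min_len / 2})")

    top = traj.topology
    mol_a = top.molecule_id[sites_a]
    mol_b = top.molecule_id[sites_b]
    # average number of same-molecule partners (incl. self) per A site
    excluded = float(np.mean(
        (mol_a[:, None] == mol_b[None, :]).sum(axis=1)))

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    hist = np.zeros(len(edges) - 1)
    vol = 0.0
    chunk = max(1, int(2e6 / max(len(sites_b), 1)))
    for fr in traj.frames:
        vol += fr.box.volume
        ca = fr.coordinates[sites_a]
        cb = fr.coordinates[sites_b]
        for lo in range(0, len(sites_a), chunk):
            hi = lo + chunk
            d = minimum_image(ca[lo:hi, None, :] - cb[None, :, :], fr.box)
            r = np.linalg.norm(d, axis=-1)
            mask = mol_a[lo:hi, None] != mol_b[None, :]
            h, _ = np.histogram(r[mask], bins=edges)
            hist += h
    mean_vol = vol / traj.n_frames
    rho_b = (len(sites_b) - excluded) / mean_vol
    if rho_b <= 0:
        raise ValueError("no intermolecular partners available")
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * math.pi * centers ** 2 * bin_width
    g = hist / (traj.n_frames * len(sites_a) * rho_b * shell)
    integrand = 4.0 * math.pi * rho_b * g * centers ** 2
    n_r = np.concatenate([[0.0], cumulative_trapezoid(integrand, centers)])
    return RDFResult(r=centers, g=g, n_r=n_r, bin_width=bin_width,
                     rho_b=rho_b, n_frames=traj.n_frames,
                     n_a=len(sites_a), n_b=len(sites_b), pair=pair)


def compute_running_integral(rdf: RDFResult, r_cut: float) -> float:
    """N(r_cut): average partner count within r_cut, by trapezoidal accumulation."""
    if r_cut < 0:
        raise ValueError("r_cut must be >= 0")
    if r_cut == 0:
        return 0.0
    if r_cut > rdf.r[-1] + 0.5 * rdf.bin_width + 1e-12:
        raise ValueError(f"r_cut={r_cut} beyond binned range ({rdf.r[-1]})")
    return float(np.interp(r_cut, rdf.r, rdf.n_r))


# ---------------------------------------------------------------------------
# SDF


def compute_sdf(
    traj: Trajectory,
    reference_type: str,
    align_sites: list[str],
    target_sites: np.ndarray,
    grid_spacing: float = 0.5,
    extent: float = 8.0,
) -> SDFResult:
    """Target-site density in the body frame of each reference molecule.

    For every (frame, reference molecule) the align-site atoms are
    superposed by least squares onto the first reference molecule of the
    first frame; all target sites (minimum-image relative to the reference
    centroid) are rotated into that body frame and accumulated on a cubic
    grid spanning ±extent.
    """
    if len(align_sites) < 3:
        raise ValueError("need >= 3 alignment sites")
    top = traj.topology
    maps = [resolve_qualified_label(top, reference_type, lab) for lab in align_sites]
    mols = sorted(maps[0])
    align_idx = {mol: np.array([m[mol] for m in maps]) for mol in mols}
    target_sites = np.asarray(target_sites, dtype=int)

    nbins = int(round(2 * extent / grid_spacing))
    edges = -extent + grid_spacing * np.arange(nbins + 1)
    hist = np.zeros((nbins, nbins, nbins))
    ref_local: np.ndarray | None = None
    n_ref = 0

    for fr in traj.frames:
        for mol in mols:
            idx = align_idx[mol]
            pos = fr.coordinates[idx]
            # make the alignment set whole across the boundary
            rel = minimum_image(pos - pos[0], fr.box)
            centroid_local = rel.mean(axis=0)
            local = rel - centroid_local
            if ref_local is None:
                s = np.linalg.svd(local, compute_uv=False)
                if s[1] < 1e-8:
                    raise ValueError("alignment sites are collinear")
                ref_local = local
            rot, _ = Rotation.align_vectors(ref_local, local)
            centroid = pos[0] + centroid_local
            if len(target_sites):
                mask = top.molecule_id[target_sites] != mol
                tgt = target_sites[mask]
                disp = minimum_image(fr.coordinates[tgt] - centroid, fr.box)
                body = rot.apply(disp)
                inside = np.all(np.abs(body) < extent, axis=1)
                if np.any(inside):
                    h, _ = np.histogramdd(body[inside], bins=(edges, edges, edges))
                    hist += h
            n_ref += 1
    if n_ref == 0:
        raise ValueError(f"no molecules of type {reference_type!r}")
    density = hist / (n_ref * grid_spacing ** 3)
    return SDFResult(density=density, origin=np.full(3, -extent),
                     spacing=grid_spacing, n_reference_frames=n_ref)


# ---------------------------------------------------------------------------
# combined distribution function (distance vs inter-vector angle)


def compute_cdf_distance_angle(
    traj: Trajectory,
    dist_sites: tuple[str, str],
    vec_a: tuple[str, str],
    vec_b: tuple[str, str],
    r_max: float = 12.0,
    bins: tuple[int, int] = (60, 45),
    molecule_type: str = "THAL",
    collect_samples: bool = False,
) -> CDFResult:
    """Joint density of an intermolecular site distance and the acute angle
    between two intramolecular vectors, over all molecule pairs.

    The angle is folded to [0°, 90°] because the ring vectors are
    orientation-symmetric; alignment/stacking shows up near 0°.
    """
    top = traj.topology
    site_a = resolve_qualified_label(top, molecule_type, dist_sites[0])
    site_b = resolve_qualified_label(top, molecule_type, dist_sites[1])
    va0 = resolve_qualified_label(top, molecule_type, vec_a[0])
    va1 = resolve_qualified_label(top, molecule_type, vec_a[1])
    vb0 = resolve_qualified_label(top, molecule_type, vec_b[0])
    vb1 = resolve_qualified_label(top, molecule_type, vec_b[1])
    mols = sorted(site_a)
    if len(mols) < 2:
        raise ValueError("need at least two molecules for an intermolecular CDF")
    ia = np.array([site_a[m] for m in mols])
    ib = np.array([site_b[m] for m in mols])
    iva0 = np.array([va0[m] for m in mols])
    iva1 = np.array([va1[m] for m in mols])
    ivb0 = np.array([vb0[m] for m in mols])
    ivb1 = np.array([vb1[m] for m in mols])

    r_edges = np.linspace(0.0, r_max, bins[0] + 1)
    phi_edges = np.linspace(0.0, 90.0, bins[1] + 1)
    hist = np.zeros((bins[0], bins[1]))
    sample_list: list[np.ndarray] = []
    n_samples = 0
    for fr in traj.frames:
        box = fr.box
        pa = fr.coordinates[ia]
        pb = fr.coordinates[ib]
        v1 = minimum_image(fr.coordinates[iva1] - fr.coordinates[iva0], box)
        v2 = minimum_image(fr.coordinates[ivb1] - fr.coordinates[ivb0], box)
        norm1 = np.linalg.norm(v1, axis=1)
        norm2 = np.linalg.norm(v2, axis=1)
        bad = (norm1 == 0) | (norm2 == 0)
        if np.any(bad):
            warnings.warn("zero-length orientation vector; affected molecules skipped")
        d = minimum_image(pa[:, None, :] - pb[None, :, :], box)
        r = np.linalg.norm(d, axis=-1)
        ii, jj = np.nonzero(
            (r <= r_max)
            & (np.arange(len(mols))[:, None] != np.arange(len(mols))[None, :])
            & ~bad[:, None] & ~bad[None, :])
        if len(ii) == 0:
            continue
        cosphi = np.abs(np.einsum("ij,ij->i", v1[ii], v2[jj])
                        / (norm1[ii] * norm2[jj]))
        phi = np.degrees(np.arccos(np.clip(cosphi, -1.0, 1.0)))
        h, _, _ = np.histogram2d(r[ii, jj], phi, bins=(r_edges, phi_edges))
        hist += h
        n_samples += len(ii)
        if collect_samples:
            sample_list.append(np.stack([r[ii, jj], phi], axis=1))
    if n_samples == 0:
        raise ValueError("no molecule pairs within r_max")
    dr = np.diff(r_edges)[:, None]
    dphi = np.diff(phi_edges)[None, :]
    density = hist / (hist.sum() * dr * dphi)
    samples = np.concatenate(sample_list) if sample_list else None
    return CDFResult(r_edges=r_edges, phi_edges=phi_edges, density=density,
                     n_samples=n_samples, samples=samples)


# ---------------------------------------------------------------------------
# dihedral distribution


def compute_dihedral_distribution(
    traj: Trajectory,
    quad: tuple[str, str, str, str] = ("Oe@1", "C1@1", "Ob", "C1@2"),
    bin_width: float = 2.0,
    molecule_type: str = "THAL",
) -> DihedralResult:
    """Signed dihedral distribution of four labelled sites per molecule.

    Bond vectors are taken minimum-image consistent within the molecule.
    Reports a normalized histogram over (-180°, 180°] plus circular mean
    and circular standard deviation.
    """
    top = traj.topology
    maps = [resolve_qualified_label(top, molecule_type, lab) for lab in quad]
    mols = sorted(maps[0])
    idx = np.array([[m[mol] for m in maps] for mol in mols])  # (M, 4)
    angles = []
    for fr in traj.frames:
        pos = fr.coordinates[idx]                # (M, 4, 3)
        # rebuild each quad relative to its first atom, minimum image
        rel = minimum_image(pos - pos[:, :1, :], fr.box)
        for m in range(rel.shape[0]):
            angles.append(signed_dihedral(rel[m, 0], rel[m, 1],
                                          rel[m, 2], rel[m, 3]))
    angles = np.asarray(angles)
    nbins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    hist, _ = np.histogram(angles, bins=edges)
    density = hist / (hist.sum() * bin_width)
    rad = np.radians(angles)
    mean_vec = complex(np.cos(rad).mean(), np.sin(rad).mean())
    rbar = abs(mean_vec)
    circ_mean = math.degrees(math.atan2(mean_vec.imag, mean_vec.real))
    circ_std = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(max(rbar, 1e-300)))))
    return DihedralResult(
        bin_centers=0.5 * (edges[:-1] + edges[1:]), density=density,
        circular_mean=circ_mean, circular_std=circ_std, n_samples=len(angles))
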