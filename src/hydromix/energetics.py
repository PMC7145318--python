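"""Pairwise intermolecular Lennard-Jones + Coulomb energy decomposition.

Class sums (water-water, water-THAL, THAL-THAL) over all intermolecular
atom pairs within a real-space cutoff; Lorentz-Berthelot mixing for LJ
cross terms.  Coulomb interactions are truncated at the same cutoff (no
Ewald: a per-class decomposition is not well-defined for the reciprocal
term); an optional shifted potential reduces truncation artefacts.
Intramolecular pairs are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory, minimum_image

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyBreakdown",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "class_interaction_energies",
]

#: e^2 N_A / (4 pi eps0) in kJ Å / (mol e^2)
COULOMB_CONSTANT = 1389.35457644382


def lj_pair_energy(r: float, sigma_i: float, sigma_j: float,
                   eps_i: float, eps_j: float) -> float:
    """Lennard-Jones pair energy (kJ/mol) with Lorentz-Berthelot mixing."""
    if r <= 0:
        raise ValueError("r must be > 0")
    sigma = 0.5 * (sigma_i + sigma_j)
    eps = np.sqrt(eps_i * eps_j)
    sr6 = (sigma / r) ** 6
    return float(4.0 * eps * (sr6 * sr6 - sr6))


def coulomb_pair_energy(r: float, q_i: float, q_j: float) -> float:
    """Coulomb pair energy (kJ/mol) for charges in elementary units, r in Å."""
    if r <= 0:
        raise ValueError("r must be > 0")
    return COULOMB_CONSTANT * q_i * q_j / r


@dataclass
class EnergyBreakdown:
    """Frame-averaged intermolecular class sums (kJ/mol per simulation cell)."""

    e_ww: float
    e_wt: float
    e_tt: float
    e_other: float
    cutoff: float
    n_frames: int
    per_frame: np.ndarray | None = None   # (n_frames, 4) in class order

    @property
    def total(self) -> float:
        return self.e_ww + self.e_wt + self.e_tt + self.e_other


_CLASS_INDEX = {"WW": 0, "WT": 1, "TT": 2, "OTHER": 3}


def class_interaction_energies(
    traj: Trajectory,
    cutoff: float = 15.0,
    shifted: bool = False,
    keep_per_frame: bool = False,
    chunk: int = 256,
) -> EnergyBreakdown:
    """LJ + Coulomb sums per interacting molecule-type class.

    Every intermolecular atom pair with minimum-image separation <= cutoff
    contributes to the class given by its two molecule types (WATER/THAL;
    anything else lands in OTHER).  With ``shifted`` both terms are shifted
    to vanish at the cutoff.
    """
    top = traj.topology
    n = top.n_atoms
    if n == 0 or traj.n_frames == 0:
        raise ValueError("empty trajectory")
    for fr in traj.frames:
        if cutoff > 0.5 * fr.box.min_length + 1e-9:
            raise ValueError(
                f"cutoff {cutoff} exceeds half the smallest box length")
    if not (np.all(np.isfinite(top.charge)) and np.all(np.isfinite(top.lj_sigma))
            and np.all(np.isfinite(top.lj_epsilon))):
        bad = int(np.flatnonzero(~(np.isfinite(top.charge)
                                   & np.isfinite(top.lj_sigma)
                                   & np.isfinite(top.lj_epsilon)))[0])
        raise ValueError(f"atom {bad} is missing interaction parameters")

    type_code = np.where(top.molecule_type == "WATER", 0,
                         np.where(top.molecule_type == "THAL", 1, 2))
    pair_class = np.array([[0, 1, 3],
                           [1, 2, 3],
                           [3, 3, 3]])   # W/T/other x W/T/other -> class index
    sqrt_eps = np.sqrt(top.lj_epsilon)
    per_frame = np.zeros((traj.n_frames, 4))
    for t, fr in enumerate(traj.frames):
        coords = fr.coordinates
        acc = np.zeros(4)
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            d = minimum_image(coords[lo:hi, None, :] - coords[None, :, :], fr.box)
            r = np.linalg.norm(d, axis=-1)
            rows = np.arange(lo, hi)[:, None]
            cols = np.arange(n)[None, :]
            mask = ((cols > rows)
                    & (top.molecule_id[lo:hi, None] != top.molecule_id[None, :])
                    & (r <= cutoff))
            ii, jj = np.nonzero(mask)
            if len(ii) == 0:
                continue
            gi = ii + lo
            rij = r[ii, jj]
            if np.any(rij == 0):
                raise ValueError("zero intermolecular distance encountered")
            sigma = 0.5 * (top.lj_sigma[gi] + top.lj_sigma[jj])
            eps = sqrt_eps[gi] * sqrt_eps[jj]
            sr6 = (sigma / rij) ** 6
            e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
            e_c = COULOMB_CONSTANT * top.charge[gi] * top.charge[jj] / rij
            if shifted:
                src6 = (sigma / cutoff) ** 6
                e_lj -= 4.0 * eps * (src6 * src6 - src6)
                e_c -= COULOMB_CONSTANT * top.charge[gi] * top.charge[jj] / cutoff
            cls = pair_class[type_code[gi], type_code[jj]]
            np.add.at(acc, cls, e_lj + e_c)
        per_frame[t] = acc
    mean = per_frame.mean(axis=0)
    return EnergyBreakdown(
        e_ww=float(mean[0]), e_wt=float(mean[1]), e_tt=float(mean[2]),
        e_other=float(mean[3]), cutoff=cutoff, n_frames=traj.n_frames,
        per_frame=per_frame if keep_per_frame else None)
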