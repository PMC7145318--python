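"""Trajectory/topology data model, periodic geometry, file I/O and composition arithmetic.

Conventions used throughout the package: coordinates in Å, time in ps,
energy in kJ/mol, temperature in K, charges in elementary charges.
Boxes are orthorhombic. Atom indexing is 0-based internally; PDB serials
are 1-based at the I/O boundary only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "M_THAL",
    "M_WATER",
    "VALID_SITE_LABELS",
    "AtomRecord",
    "Box",
    "Frame",
    "Trajectory",
    "Topology",
    "Composition",
    "TrajectoryParseError",
    "minimum_image_displacement",
    "minimum_image",
    "select_sites",
    "composition_builder",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
]

#: Molar masses (g/mol) used for composition arithmetic.
M_THAL = 342.296
M_WATER = 18.0153

VALID_SITE_LABELS = frozenset(
    {"O1", "O2", "O3", "O4", "Oe", "Ob", "C1", "C2", "C3", "C4", "C5", "C6",
     "Ho", "Ow", "Hw", "X"}
)

#: Site labels restricted to a molecule type.
_WATER_ONLY_LABELS = frozenset({"Ow", "Hw"})
_THAL_ONLY_LABELS = frozenset({"O1", "O2", "O3", "O4", "Ob", "Oe"})


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file cannot be parsed; names frame and line."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology sidecar."""

    atom_index: int
    element: str
    site_label: str
    molecule_id: int
    molecule_type: str
    mass: float
    charge: float
    lj_sigma: float
    lj_epsilon: float

    def __post_init__(self) -> None:
        if self.site_label not in VALID_SITE_LABELS:
            raise ValueError(
                f"unknown site label {self.site_label!r}; valid labels: "
                f"{sorted(VALID_SITE_LABELS)}"
            )
        if not self.mass > 0:
            raise ValueError(f"atom {self.atom_index}: mass must be > 0")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.atom_index}: LJ parameters must be >= 0")


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in Å."""

    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        lengths = tuple(float(x) for x in self.lengths)
        if len(lengths) != 3 or any(not math.isfinite(x) or x <= 0 for x in lengths):
            raise ValueError(f"box lengths must be three positive finite values, got {self.lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.array))

    @property
    def min_length(self) -> float:
        return float(min(self.lengths))

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) per axis."""
        arr = np.asarray(coords, dtype=float)
        return np.mod(arr, self.array)


class Topology:
    """Per-atom static data: identity, site labels, molecule membership, parameters.

    Columnar storage (one numpy array per field) so selections and pair
    loops vectorize.  THAL and WATER molecule types carry label-multiplicity
    invariants; any other type token is accepted and treated generically.
    """

    COLUMNS = ("atom_index", "element", "site_label", "molecule_id",
               "molecule_type", "mass", "charge", "lj_sigma", "lj_epsilon")

    def __init__(
        self,
        element: Sequence[str],
        site_label: Sequence[str],
        molecule_id: Sequence[int],
        molecule_type: Sequence[str],
        mass: Sequence[float],
        charge: Sequence[float],
        lj_sigma: Sequence[float],
        lj_epsilon: Sequence[float],
    ) -> None:
        self.element = np.asarray(element, dtype=object)
        self.site_label = np.asarray(site_label, dtype=object)
        self.molecule_id = np.asarray(molecule_id, dtype=np.int64)
        self.molecule_type = np.asarray(molecule_type, dtype=object)
        self.mass = np.asarray(mass, dtype=float)
        self.charge = np.asarray(charge, dtype=float)
        self.lj_sigma = np.asarray(lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(lj_epsilon, dtype=float)
        n = len(self.element)
        for name in ("site_label", "molecule_id", "molecule_type", "mass",
                     "charge", "lj_sigma", "lj_epsilon"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology column {name} has wrong length")
        self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[AtomRecord]) -> "Topology":
        recs = list(records)
        return cls(
            element=[r.element for r in recs],
            site_label=[r.site_label for r in recs],
            molecule_id=[r.molecule_id for r in recs],
            molecule_type=[r.molecule_type for r in recs],
            mass=[r.mass for r in recs],
            charge=[r.charge for r in recs],
            lj_sigma=[r.lj_sigma for r in recs],
            lj_epsilon=[r.lj_epsilon for r in recs],
        )

    def to_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(i, self.element[i], self.site_label[i],
                       int(self.molecule_id[i]), self.molecule_type[i],
                       float(self.mass[i]), float(self.charge[i]),
                       float(self.lj_sigma[i]), float(self.lj_epsilon[i]))
            for i in range(self.n_atoms)
        ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Topology":
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"topology table missing columns: {missing}")
        df = df.sort_values("atom_index").reset_index(drop=True)
        if not np.array_equal(df["atom_index"].to_numpy(), np.arange(len(df))):
            raise ValueError("atom_index must be 0..n-1 without gaps")
        return cls(
            element=df["element"].astype(str).tolist(),
            site_label=df["site_label"].astype(str).tolist(),
            molecule_id=df["molecule_id"].astype(int).tolist(),
            molecule_type=df["molecule_type"].astype(str).tolist(),
            mass=df["mass"].to_numpy(float),
            charge=df["charge"].to_numpy(float),
            lj_sigma=df["lj_sigma"].to_numpy(float),
            lj_epsilon=df["lj_epsilon"].to_numpy(float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "atom_index": np.arange(self.n_atoms),
            "element": self.element,
            "site_label": self.site_label,
            "molecule_id": self.molecule_id,
            "molecule_type": self.molecule_type,
            "mass": self.mass,
            "charge": self.charge,
            "lj_sigma": self.lj_sigma,
            "lj_epsilon": self.lj_epsilon,
        })

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        if np.any(self.mass <= 0):
            raise ValueError("all masses must be > 0")
        if np.any(self.lj_sigma < 0) or np.any(self.lj_epsilon < 0):
            raise ValueError("LJ parameters must be >= 0")
        unknown = set(self.site_label) - VALID_SITE_LABELS
        if unknown:
            raise ValueError(
                f"unknown site labels {sorted(unknown)}; valid labels: "
                f"{sorted(VALID_SITE_LABELS)}"
            )
        water_mask = self.molecule_type == "WATER"
        thal_mask = self.molecule_type == "THAL"
        bad = np.isin(self.site_label.astype(str), sorted(_WATER_ONLY_LABELS)) & ~water_mask
        if np.any(bad):
            raise ValueError("Ow/Hw labels are only valid on WATER molecules")
        bad = np.isin(self.site_label.astype(str), sorted(_THAL_ONLY_LABELS)) & ~thal_mask
        if np.any(bad):
            raise ValueError("O1-O4/Ob/Oe labels are only valid on THAL molecules")
        # per-THAL label multiplicities: one Ob, two Oe, two each of O1-O4
        for mol in np.unique(self.molecule_id[thal_mask]):
            labels = self.site_label[self.molecule_id == mol]
            counts = {lab: int(np.sum(labels == lab)) for lab in
                      ("Ob", "Oe", "O1", "O2", "O3", "O4")}
            expected = {"Ob": 1, "Oe": 2, "O1": 2, "O2": 2, "O3": 2, "O4": 2}
            if counts != expected:
                raise ValueError(
                    f"THAL molecule {mol} has label counts {counts}, expected {expected}"
                )

    # -- queries -----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id))

    def molecule_types(self) -> dict[int, str]:
        """Mapping molecule_id -> molecule_type."""
        ids, first = np.unique(self.molecule_id, return_index=True)
        return {int(i): self.molecule_type[j] for i, j in zip(ids, first)}

    def count_molecules(self, molecule_type: str) -> int:
        return sum(1 for t in self.molecule_types().values() if t == molecule_type)

    def atoms_by_molecule(self) -> dict[int, np.ndarray]:
        order = np.argsort(self.molecule_id, kind="stable")
        ids = self.molecule_id[order]
        out: dict[int, np.ndarray] = {}
        for mol in np.unique(ids):
            out[int(mol)] = order[ids == mol]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            np.array_equal(self.element, other.element)
            and np.array_equal(self.site_label, other.site_label)
            and np.array_equal(self.molecule_id, other.molecule_id)
            and np.array_equal(self.molecule_type, other.molecule_type)
            and np.allclose(self.mass, other.mass)
            and np.allclose(self.charge, other.charge)
            and np.allclose(self.lj_sigma, other.lj_sigma)
            and np.allclose(self.lj_epsilon, other.lj_epsilon)
        )


@dataclass
class Frame:
    """One snapshot: time (ps), box, coordinates (Å), optional unwrapped coordinates."""

    time: float
    box: Box
    coordinates: np.ndarray
    unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.size == 0:
            self.coordinates = self.coordinates.reshape(0, 3)
        if self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not math.isfinite(self.time):
            raise ValueError("frame time must be finite")
        if self.unwrapped is not None:
            self.unwrapped = np.asarray(self.unwrapped, dtype=float).reshape(
                self.coordinates.shape)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != self.topology.n_atoms:
                raise ValueError(
                    f"frame {i}: {fr.n_atoms} atoms vs topology {self.topology.n_atoms}")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    def uniform_dt(self, rtol: float = 1e-6) -> float:
        """Frame spacing in ps; raises if the grid is not uniform."""
        times = self.times
        if len(times) < 2:
            raise ValueError("need at least two frames for a frame spacing")
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], rtol=rtol):
            raise ValueError("frame times are not uniformly spaced")
        return float(dts[0])

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image(displacement: np.ndarray, box: Box) -> np.ndarray:
    """Map displacement vectors into the minimum-image cell [-L/2, L/2)."""
    d = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite coordinates in displacement")
    lengths = box.array
    return d - lengths * np.floor(d / lengths + 0.5)


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement a - b; each component lies in [-L/2, L/2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return minimum_image(a - b, box)


# ---------------------------------------------------------------------------
# selection and composition


def select_sites(top: Topology, molecule_type: str, site_labels: Iterable[str]) -> np.ndarray:
    """Ascending atom indices matching both the molecule type and any site label."""
    labels = set(site_labels)
    unknown = labels - VALID_SITE_LABELS
    if unknown:
        raise ValueError(
            f"unknown site labels {sorted(unknown)}; valid labels: "
            f"{sorted(VALID_SITE_LABELS)}"
        )
    mask = (top.molecule_type == molecule_type) & np.isin(
        top.site_label.astype(str), sorted(labels))
    return np.flatnonzero(mask)


@dataclass(frozen=True)
class Composition:
    """Integer molecule counts and the resulting trehalose mass fraction."""

    n_water: int
    n_thal: int

    def __post_init__(self) -> None:
        if self.n_water < 0 or self.n_thal < 0:
            raise ValueError("molecule counts must be non-negative")

    @property
    def omega(self) -> float:
        m_t = self.n_thal * M_THAL
        m_w = self.n_water * M_WATER
        if m_t + m_w == 0:
            raise ValueError("empty composition")
        return m_t / (m_t + m_w)


def composition_builder(n_water: int, omega_target: float) -> Composition:
    """Integer trehalose count reaching a target mass fraction at fixed water count.

    n_thal = round(n_water * M_WATER * omega / (M_THAL * (1 - omega))); the
    achieved omega is recomputed from the integer counts.
    """
    if n_water <= 0:
        raise ValueError("n_water must be > 0")
    if not 0.0 <= omega_target < 1.0:
        raise ValueError("omega_target must lie in [0, 1); omega=1 needs "
                         "infinitely many THAL at fixed water count")
    n_thal = int(round(n_water * M_WATER * omega_target / (M_THAL * (1.0 - omega_target))))
    return Composition(n_water=n_water, n_thal=n_thal)


# ---------------------------------------------------------------------------
# topology sidecar I/O


def write_topology(top: Topology, path: str | Path, sep: str = "\t") -> None:
    top.to_dataframe().to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_topology(path: str | Path, sep: str = "\t") -> Topology:
    return Topology.from_dataframe(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# trajectory I/O (XYZ with extended comment line; PDB with CRYST1)

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_BOX_RE = re.compile(r'box="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-+0-9.eE]+)")


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "xyz") -> None:
    """Write a trajectory re-readable by :func:`read_trajectory`."""
    if format == "xyz":
        _write_xyz(traj, path)
    elif format == "pdb":
        _write_pdb(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path: str | Path, format: str, topology: Topology) -> Trajectory:
    """Read a trajectory, checking per-frame atom counts against the topology."""
    if format == "xyz":
        frames = _read_xyz(path, topology)
    elif format == "pdb":
        frames = _read_pdb(path, topology)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(topology=topology, frames=frames)


def _write_xyz(traj: Trajectory, path: str | Path) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for fr in traj.frames:
            lx, ly, lz = fr.box.lengths
            props = "species:S:1:pos:R:3"
            if fr.unwrapped is not None:
                props += ":unwrapped:R:3"
            fh.write(f"{fr.n_atoms}\n")
            fh.write(
                f'Lattice="{lx:.10g} 0 0 0 {ly:.10g} 0 0 0 {lz:.10g}" '
                f"Time={fr.time:.10g} Properties={props}\n"
            )
            for i in range(fr.n_atoms):
                x, y, z = fr.coordinates[i]
                line = f"{top.element[i]} {x:.8f} {y:.8f} {z:.8f}"
                if fr.unwrapped is not None:
                    ux, uy, uz = fr.unwrapped[i]
                    line += f" {ux:.8f} {uy:.8f} {uz:.8f}"
                fh.write(line + "\n")


def _read_xyz(path: str | Path, topology: Topology) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    frame_idx = 0
    n_lines = len(lines)
    while pos < n_lines:
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"frame {frame_idx}, line {pos + 1}: expected atom count, got "
                f"{lines[pos]!r}")
        if n_atoms != topology.n_atoms:
            raise TrajectoryParseError(
                f"frame {frame_idx}, line {pos + 1}: {n_atoms} atoms in file vs "
                f"{topology.n_atoms} in topology")
        if pos + 1 + n_atoms >= n_lines + (1 if n_atoms == 0 else 0) and pos + 1 >= n_lines:
            raise TrajectoryParseError(f"frame {frame_idx}: truncated (missing comment line)")
        comment = lines[pos + 1]
        box = _parse_xyz_box(comment, frame_idx, pos + 2)
        m = _TIME_RE.search(comment)
        time = float(m.group(1)) if m else float(frame_idx)
        coords = np.empty((n_atoms, 3))
        unwrapped = None
        for i in range(n_atoms):
            lineno = pos + 2 + i
            if lineno >= n_lines:
                raise TrajectoryParseError(
                    f"frame {frame_idx}: truncated at line {lineno + 1}")
            parts = lines[lineno].split()
            if len(parts) not in (4, 7):
                raise TrajectoryParseError(
                    f"frame {frame_idx}, line {lineno + 1}: malformed atom line "
                    f"{lines[lineno]!r}")
            try:
                coords[i] = [float(v) for v in parts[1:4]]
                if len(parts) == 7:
                    if unwrapped is None:
                        unwrapped = np.empty((n_atoms, 3))
                    unwrapped[i] = [float(v) for v in parts[4:7]]
            except ValueError:
                raise TrajectoryParseError(
                    f"frame {frame_idx}, line {lineno + 1}: malformed atom line "
                    f"{lines[lineno]!r}")
        frames.append(Frame(time=time, box=box, coordinates=coords, unwrapped=unwrapped))
        pos += 2 + n_atoms
        frame_idx += 1
    return frames


def _parse_xyz_box(comment: str, frame_idx: int, lineno: int) -> Box:
    m = _LATTICE_RE.search(comment)
    if m:
        vals = [float(v) for v in m.group(1).split()]
        if len(vals) != 9:
            raise TrajectoryParseError(
                f"frame {frame_idx}, line {lineno}: Lattice needs 9 values")
        off_diag = [vals[i] for i in (1, 2, 3, 5, 6, 7)]
        if any(abs(v) > 1e-9 for v in off_diag):
            raise TrajectoryParseError(
                f"frame {frame_idx}, line {lineno}: only orthorhombic boxes supported")
        return Box((vals[0], vals[4], vals[8]))
    m = _BOX_RE.search(comment)
    if m:
        vals = [float(v) for v in m.group(1).split()]
        if len(vals) != 3:
            raise TrajectoryParseError(
                f"frame {frame_idx}, line {lineno}: box needs 3 values")
        return Box(tuple(vals))
    raise TrajectoryParseError(
        f"frame {frame_idx}, line {lineno}: missing box record (Lattice= or box=)")


_RESNAMES = {"THAL": "THL", "WATER": "HOH"}


def _write_pdb(traj: Trajectory, path: str | Path) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for imodel, fr in enumerate(traj.frames, start=1):
            lx, ly, lz = fr.box.lengths
            fh.write(f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
            fh.write(f"REMARK 250 TIME={fr.time:.10g}\n")
            fh.write(f"MODEL {imodel:>8d}\n")
            for i in range(fr.n_atoms):
                x, y, z = fr.coordinates[i]
                name = str(top.site_label[i])[:4]
                resname = _RESNAMES.get(str(top.molecule_type[i]),
                                        str(top.molecule_type[i])[:3].upper() or "UNK")
                serial = min(i + 1, 99999)
                resseq = int(top.molecule_id[i]) % 10000
                elem = str(top.element[i])[:2].rjust(2)
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s}{resname:>4s} A{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_pdb(path: str | Path, topology: Topology) -> list[Frame]:
    frames: list[Frame] = []
    box: Box | None = None
    time: float | None = None
    coords: list[list[float]] = []
    frame_idx = 0

    def finish(lineno: int) -> None:
        nonlocal coords, time, frame_idx
        if not coords and topology.n_atoms > 0:
            return
        if box is None:
            raise TrajectoryParseError(
                f"frame {frame_idx}, line {lineno}: missing CRYST1 box record")
        if len(coords) != topology.n_atoms:
            raise TrajectoryParseError(
                f"frame {frame_idx}, line {lineno}: {len(coords)} atoms in file vs "
                f"{topology.n_atoms} in topology")
        t = time if time is not None else float(frame_idx)
        frames.append(Frame(time=t, box=box, coordinates=np.array(coords).reshape(-1, 3)))
        coords = []
        time = None
        frame_idx += 1

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = Box((float(line[6:15]), float(line[15:24]), float(line[24:33])))
                except ValueError:
                    raise TrajectoryParseError(
                        f"frame {frame_idx}, line {lineno}: malformed CRYST1")
            elif line.startswith("REMARK 250 TIME="):
                time = float(line.split("TIME=")[1])
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    coords.append([float(line[30:38]), float(line[38:46]),
                                   float(line[46:54])])
                except ValueError:
                    raise TrajectoryParseError(
                        f"frame {frame_idx}, line {lineno}: malformed ATOM record")
            elif rec.strip() == "ENDMDL":
                finish(lineno)
    if coords:
        finish(lineno)
    return frames
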