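"""Structures, trajectories and atom selections.

The data model is deliberately small: an :class:`Atom` carries identity
(author residue numbering is authoritative throughout — no internal
renumbering), coordinates, the crystallographic B-factor, and the per-atom
nonbonded parameters used by :mod:`pullkit.energetics` and
:mod:`pullkit.surface`.  PDB files are parsed and written through biotite;
trajectories can additionally round-trip through a plain-text ``xyz-frames``
dialect (documented in the README) so that every fixture in the test suite is
human-readable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "SelectionError",
    "ELEMENT_MASSES",
    "ELEMENT_VDW_RADII",
    "read_pdb",
    "read_pdb_trajectory",
    "write_pdb",
    "write_trajectory",
    "read_xyz_frames",
    "resolve_selection",
    "read_parameter_table",
    "apply_parameter_table",
]

DEFAULT_FRAME_SPACING_PS = 10.0  # snapshot interval of the analysed runs

# Standard atomic masses (amu) and Bondi-style van der Waals radii (Å) used to
# fill fields that plain PDB files do not carry.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.990, "CL": 35.45, "K": 39.098,
}
ELEMENT_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "FE": 1.40, "ZN": 1.39, "MG": 1.73,
    "CA": 2.31, "NA": 2.27, "CL": 1.75, "K": 2.75,
}
_DEFAULT_MASS = 12.011
_DEFAULT_RADIUS = 1.70


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class SelectionError(ValueError):
    """Raised when a selection resolves to no atoms or is inconsistent."""


@dataclass
class Atom:
    """A single atom with identity, coordinates and nonbonded parameters.

    ``charge`` (elementary charges), ``lj_epsilon`` (kcal/mol) and
    ``lj_rmin_half`` (Å) default to NaN; energetics refuses to run until a
    parameter table supplies them.  ``mass`` and ``vdw_radius`` are filled
    from the bundled element table when not given explicitly.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    b_factor: float = 0.0
    mass: float = math.nan
    charge: float = math.nan
    lj_epsilon: float = math.nan
    lj_rmin_half: float = math.nan
    vdw_radius: float = math.nan

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} {self.name}: position must be a finite 3-vector")
        el = self.element.upper()
        if math.isnan(self.mass):
            self.mass = ELEMENT_MASSES.get(el, _DEFAULT_MASS)
        if math.isnan(self.vdw_radius):
            self.vdw_radius = ELEMENT_VDW_RADII.get(el, _DEFAULT_RADIUS)
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial} {self.name}: mass must be positive")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial} {self.name}: vdw radius must be positive")


class Structure:
    """An ordered collection of atoms (one model)."""

    def __init__(self, atoms: Sequence[Atom], title: str = "") -> None:
        self.atoms: list[Atom] = list(atoms)
        self.title = title
        keys = [(a.chain_id, a.residue_number, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom key (chain, residue, name) = {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @positions.setter
    def positions(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    def array(self, field_name: str) -> np.ndarray:
        return np.array([getattr(a, field_name) for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return self.array("mass").astype(float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return self.array("vdw_radius").astype(float)

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.array("residue_number").astype(int)

    def residues(self) -> list[tuple[str, int]]:
        """(chain_id, residue_number) pairs in order of first appearance."""
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def atom_indices_of_residue(self, residue_number: int, chain_id: str | None = None) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if a.residue_number == residue_number and (chain_id is None or a.chain_id == chain_id)
        ]

    def copy(self) -> "Structure":
        return Structure([replace(a, position=a.position.copy()) for a in self.atoms], self.title)


@dataclass
class Trajectory:
    """Ordered coordinate frames with timestamps over a fixed topology."""

    frames: np.ndarray  # (n_frames, n_atoms, 3) Å
    times: np.ndarray  # ps, strictly increasing
    structure_ref: Structure

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("number of frames and timestamps differ")
        if self.frames.shape[1] != self.structure_ref.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def window(self, t_start: float, t_end: float) -> "Trajectory":
        """Sub-trajectory with t_start <= t <= t_end."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        if not np.any(mask):
            raise ValueError(f"no frames in window [{t_start}, {t_end}] ps")
        return Trajectory(self.frames[mask], self.times[mask], self.structure_ref)


@dataclass
class Selection:
    """Declarative atom selection over a structure.

    All stated criteria are combined with AND; a criterion left as ``None``
    does not constrain.  ``residue_numbers`` may mix single numbers and
    inclusive ``(lo, hi)`` ranges, matching how regions are cited in the
    literature (author numbering).
    """

    label: str = "selection"
    residue_numbers: Sequence[int | tuple[int, int]] | None = None
    residue_names: Sequence[str] | None = None
    atom_names: Sequence[str] | None = None
    chain_ids: Sequence[str] | None = None

    def _residue_match(self, resnum: int) -> bool:
        assert self.residue_numbers is not None
        for item in self.residue_numbers:
            if isinstance(item, tuple):
                lo, hi = item
                if lo <= resnum <= hi:
                    return True
            elif resnum == item:
                return True
        return False

    def resolve(self, structure: Structure) -> np.ndarray:
        if structure.n_atoms == 0:
            raise SelectionError("cannot resolve a selection on an empty structure")
        idx = []
        names = set(self.atom_names) if self.atom_names is not None else None
        resnames = set(self.residue_names) if self.residue_names is not None else None
        chains = set(self.chain_ids) if self.chain_ids is not None else None
        for i, a in enumerate(structure.atoms):
            if names is not None and a.name not in names:
                continue
            if resnames is not None and a.residue_name not in resnames:
                continue
            if chains is not None and a.chain_id not in chains:
                continue
            if self.residue_numbers is not None and not self._residue_match(a.residue_number):
                continue
            idx.append(i)
        if not idx:
            raise SelectionError(f"selection {self.label!r} matched no atoms")
        return np.asarray(idx, dtype=int)


def resolve_selection(sel: Selection, structure: Structure) -> np.ndarray:
    """Deterministic, sorted atom indices of ``sel`` in ``structure``."""
    return sel.resolve(structure)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: Path) -> int:
    """Cheap line-level validation so parse errors can name the line."""
    n_atom_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n_atom_lines += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated {rec} record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise PDBParseError(f"{path}:{lineno}: unreadable coordinate field") from None
            if line[26] != " ":
                raise PDBParseError(
                    f"{path}:{lineno}: insertion code {line[26]!r} is not supported"
                )
    if n_atom_lines == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return n_atom_lines


def _atoms_from_biotite(arr, serials, b_factors) -> list[Atom]:
    atoms = []
    for i in range(arr.array_length()):
        el = str(arr.element[i]).upper()
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=el if el else "C",
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                position=np.asarray(arr.coord[i], dtype=float),
                b_factor=float(b_factors[i]),
            )
        )
    return atoms


def read_pdb(path: str | Path) -> Structure:
    """Read the first model of a PDB file.

    B-factors and author residue numbering are preserved; the first altloc is
    kept; insertion codes are rejected.
    """
    import biotite.structure.io.pdb as bio_pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    pdb_file = bio_pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(
        model=1, altloc="first", extra_fields=["b_factor", "atom_id"]
    )
    return Structure(_atoms_from_biotite(arr, arr.atom_id, arr.b_factor), title=path.stem)


def read_pdb_trajectory(
    path: str | Path, frame_spacing: float = DEFAULT_FRAME_SPACING_PS
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Times default to ``model_index * frame_spacing`` (ps), matching the
    snapshot interval of the analysed simulations.
    """
    import biotite.structure.io.pdb as bio_pdb

    path = Path(path)
    _prevalidate_pdb(path)
    pdb_file = bio_pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(altloc="first", extra_fields=["b_factor", "atom_id"])
    first = stack[0]
    structure = Structure(_atoms_from_biotite(first, first.atom_id, first.b_factor), title=path.stem)
    frames = np.asarray(stack.coord, dtype=float)
    times = np.arange(frames.shape[0], dtype=float) * frame_spacing
    return Trajectory(frames, times, structure)


def _biotite_array(structure: Structure):
    import biotite.structure as bio_struct

    n = structure.n_atoms
    arr = bio_struct.AtomArray(n)
    arr.add_annotation("b_factor", float)
    arr.add_annotation("atom_id", int)
    for i, a in enumerate(structure.atoms):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_number
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = False
        arr.b_factor[i] = a.b_factor
        arr.atom_id[i] = a.serial
        arr.coord[i] = a.position
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file preserving B-factors and numbering."""
    import biotite.structure.io.pdb as bio_pdb

    pdb_file = bio_pdb.PDBFile()
    pdb_file.set_structure(_biotite_array(structure))
    pdb_file.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "multi-model-pdb") -> None:
    """Write a trajectory as a multi-model PDB or as xyz-frames text.

    PDB model timestamps are implicit (model index × frame spacing); the
    xyz-frames dialect stores explicit times and is exact to the printed
    precision (6 decimals).
    """
    if traj.n_frames == 0:
        raise ValueError("refusing to write a trajectory with zero frames")
    fmt = format.lower().replace("_", "-")
    if fmt in ("multi-model-pdb", "pdb"):
        import biotite.structure as bio_struct
        import biotite.structure.io.pdb as bio_pdb

        arr = _biotite_array(traj.structure_ref)
        stack = bio_struct.stack([arr] * traj.n_frames)
        stack.coord = np.asarray(traj.frames, dtype=np.float32)
        pdb_file = bio_pdb.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
    elif fmt in ("xyz-frames", "xyzf"):
        with open(path, "w") as fh:
            for t, frame in zip(traj.times, traj.frames):
                fh.write(f"{traj.n_atoms} {t:.6f}\n")
                for atom, xyz in zip(traj.structure_ref.atoms, frame):
                    fh.write(f"{atom.element} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_xyz_frames(path: str | Path, structure_ref: Structure) -> Trajectory:
    """Read the xyz-frames dialect back onto an existing topology."""
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        header = lines[i].split()
        if len(header) != 2:
            raise PDBParseError(f"{path}: malformed xyz-frames header at line {i + 1}")
        natoms, t = int(header[0]), float(header[1])
        if natoms != structure_ref.n_atoms:
            raise PDBParseError(
                f"{path}: frame has {natoms} atoms, topology has {structure_ref.n_atoms}"
            )
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[i + 1 + k].split()
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        times.append(t)
        i += natoms + 1
    if not frames:
        raise PDBParseError(f"{path}: empty xyz-frames file")
    return Trajectory(np.array(frames), np.array(times), structure_ref)


# ---------------------------------------------------------------------------
# Nonbonded parameter tables
# ---------------------------------------------------------------------------

def read_parameter_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """Read a whitespace-separated nonbonded parameter table.

    Columns: ``atom_name residue_name charge epsilon rmin_half vdw_radius``;
    ``*`` in the residue column acts as a wildcard.  Lines starting with ``#``
    are comments.
    """
    table: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            name, resname = parts[0], parts[1]
            charge, eps, rmin_half, radius = (float(x) for x in parts[2:])
            table[(name, resname)] = (charge, eps, rmin_half, radius)
    if not table:
        raise ValueError(f"{path}: empty parameter table")
    return table


def apply_parameter_table(
    structure: Structure,
    table: dict[tuple[str, str], tuple[float, float, float, float]],
) -> None:
    """Fill per-atom charge/LJ/radius fields from a parameter table, in place."""
    for a in structure.atoms:
        entry = table.get((a.name, a.residue_name)) or table.get((a.name, "*"))
        if entry is None:
            continue
        a.charge, a.lj_epsilon, a.lj_rmin_half, a.vdw_radius = entry
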