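"""Side-chain contacts, native-contact sets and the buried-core selection.

A contact exists when the centers of mass of two side chains are within the
cutoff (6 Å by default, boundary inclusive).  Contacts present in at least
60% of the frames of at least one force-free run are *native*; the union of
an anchor residue's native partners over replicate runs, plus the anchor
itself, defines the buried hydrophobic core whose solvent exposure the
unfolding analysis tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, Trajectory

__all__ = [
    "ContactSet",
    "CoreSelection",
    "BACKBONE_ATOM_NAMES",
    "sidechain_atom_indices",
    "sidechain_com",
    "contact_pairs",
    "native_contacts",
    "merge_native_over_runs",
]

DEFAULT_CUTOFF = 6.0  # Å, side-chain COM distance, inclusive
DEFAULT_MIN_OCCUPANCY = 0.60
_DISTANCE_EPS = 1e-9  # absorbs COM rounding at the inclusive boundary

BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


@dataclass
class ContactSet:
    """Occupancy of every residue ever in contact with an anchor residue."""

    anchor_residue: int
    partners: list[tuple[int, float]]  # (residue_number, occupancy in [0,1])
    cutoff: float = DEFAULT_CUTOFF
    occupancy_threshold: float = DEFAULT_MIN_OCCUPANCY

    def __post_init__(self) -> None:
        for res, occ in self.partners:
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy of residue {res} outside [0,1]: {occ}")
            if res == self.anchor_residue:
                raise ValueError("anchor cannot be its own partner")

    def native_partners(self) -> list[int]:
        return sorted(r for r, occ in self.partners if occ >= self.occupancy_threshold)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# anchor\tpartner\toccupancy\tnative\n")
            for res, occ in sorted(self.partners):
                native = int(occ >= self.occupancy_threshold)
                fh.write(f"{self.anchor_residue}\t{res}\t{occ:.4f}\t{native}\n")


@dataclass
class CoreSelection:
    """Anchor plus its merged native partners."""

    residues: list[int]
    anchor_residue: int
    label: str = "C-terminal hydrophobic core"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("core selection must be non-empty")
        self.residues = sorted(set(self.residues))


def sidechain_atom_indices(structure: Structure, residue_number: int, chain_id: str | None = None) -> list[int]:
    """Heavy side-chain atom indices of a residue (Cβ outward).

    Glycine (or any residue without side-chain heavy atoms) falls back to its
    Cα as a stand-in.
    """
    res_atoms = structure.atom_indices_of_residue(residue_number, chain_id)
    if not res_atoms:
        raise ValueError(f"residue {residue_number} not found")
    side = [
        i for i in res_atoms
        if structure.atoms[i].name not in BACKBONE_ATOM_NAMES
        and structure.atoms[i].element.upper() != "H"
    ]
    if not side:
        ca = [i for i in res_atoms if structure.atoms[i].name == "CA"]
        if not ca:
            raise ValueError(f"residue {residue_number} has neither side-chain heavy atoms nor CA")
        side = ca
    return side


def sidechain_com(
    structure: Structure,
    residue_number: int,
    coords: np.ndarray | None = None,
    chain_id: str | None = None,
) -> np.ndarray:
    """Mass-weighted center of mass of a residue's side-chain heavy atoms."""
    idx = sidechain_atom_indices(structure, residue_number, chain_id)
    coords = structure.positions if coords is None else np.asarray(coords, dtype=float)
    masses = np.array([structure.atoms[i].mass for i in idx])
    return (masses[:, None] * coords[idx]).sum(axis=0) / masses.sum()


def _residue_coms(structure: Structure, coords: np.ndarray | None = None) -> tuple[list[tuple[str, int]], np.ndarray]:
    residues = structure.residues()
    coms = np.empty((len(residues), 3))
    for k, (chain, res) in enumerate(residues):
        coms[k] = sidechain_com(structure, res, coords=coords, chain_id=chain)
    return residues, coms


def contact_pairs(
    structure: Structure,
    coords: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    exclude_neighbors: int = 1,
) -> set[tuple[int, int]]:
    """Residue pairs whose side-chain COMs are within ``cutoff`` (inclusive).

    Pairs within ``exclude_neighbors`` positions along the same chain are
    dropped (covalent neighbours are trivially close).  Returned as
    ``(res_i, res_j)`` with ``res_i < res_j``.
    """
    residues, coms = _residue_coms(structure, coords)
    diff = coms[:, None, :] - coms[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    pairs: set[tuple[int, int]] = set()
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            chain_i, res_i = residues[i]
            chain_j, res_j = residues[j]
            if chain_i == chain_j and abs(res_i - res_j) <= exclude_neighbors:
                continue
            if dist[i, j] <= cutoff + _DISTANCE_EPS:
                pairs.add((min(res_i, res_j), max(res_i, res_j)))
    return pairs


def native_contacts(
    traj: Trajectory,
    anchor: int,
    cutoff: float = DEFAULT_CUTOFF,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
    exclude_neighbors: int = 1,
) -> ContactSet:
    """Occupancy of every residue's contact with ``anchor`` over a trajectory.

    Native partners are those in contact in at least ``min_occupancy`` of the
    frames (inclusive), evaluated against force-free trajectories.
    """
    structure = traj.structure_ref
    residues = structure.residues()
    anchor_entries = [(c, r) for (c, r) in residues if r == anchor]
    if not anchor_entries:
        raise ValueError(f"anchor residue {anchor} not present in topology")
    anchor_chain = anchor_entries[0][0]
    counts: dict[int, int] = {}
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        anchor_com = sidechain_com(structure, anchor, coords=coords, chain_id=anchor_chain)
        for chain, res in residues:
            if res == anchor:
                continue
            if chain == anchor_chain and abs(res - anchor) <= exclude_neighbors:
                continue
            com = sidechain_com(structure, res, coords=coords, chain_id=chain)
            if np.linalg.norm(com - anchor_com) <= cutoff + _DISTANCE_EPS:
                counts[res] = counts.get(res, 0) + 1
    partners = [(res, n / traj.n_frames) for res, n in sorted(counts.items())]
    return ContactSet(anchor, partners, cutoff=cutoff, occupancy_threshold=min_occupancy)


def merge_native_over_runs(sets: list[ContactSet]) -> CoreSelection:
    """Union of native partners over replicate runs, plus the anchor.

    A contact native in *at least one* force-free run enters the core.
    """
    if not sets:
        raise ValueError("need at least one contact set")
    anchors = {s.anchor_residue for s in sets}
    if len(anchors) != 1:
        raise ValueError(f"contact sets have mixed anchors: {sorted(anchors)}")
    anchor = anchors.pop()
    residues: set[int] = {anchor}
    for s in sets:
        residues.update(s.native_partners())
    return CoreSelection(sorted(residues), anchor_residue=anchor)
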