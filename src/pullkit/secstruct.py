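"""Per-frame secondary-structure classification from backbone hydrogen bonds.

A simplified DSSP: backbone N–H···O=C hydrogen bonds are scored with the
Kabsch–Sander electrostatic energy and called below −0.5 kcal/mol; runs of
i→i+4 bonds give α-helix (H), i→i+3 give 3₁₀ (G), bridge patterns give
strand (E), isolated turns give T, everything else coil (C).  Priority on
overlap is H > G > E > T.  β-bulges and the bend class are intentionally not
handled — the goal is an unfolding-timeline observable, not DSSP parity.
Amide hydrogens are built geometrically when absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, Trajectory

__all__ = [
    "SSTimeline",
    "HBOND_ENERGY_CUTOFF",
    "backbone_hbond_energy",
    "assign_frame",
    "assign_timeline",
    "ideal_backbone",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_FACTOR = 0.084 * 332.0  # Kabsch–Sander prefactor, kcal/mol·Å


@dataclass
class SSTimeline:
    """Secondary-structure classes per frame and residue."""

    classes: np.ndarray  # (n_frames, n_residues) of single characters
    times: np.ndarray  # ps
    residue_numbers: np.ndarray

    def counts(self, klass: str) -> np.ndarray:
        return (self.classes == klass).sum(axis=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# time_ps\t" + "\t".join(str(r) for r in self.residue_numbers) + "\n")
            for t, row in zip(self.times, self.classes):
                fh.write(f"{t:.3f}\t" + "\t".join(row) + "\n")


def _backbone_map(structure: Structure) -> tuple[list[tuple[str, int]], dict[tuple[str, int], dict[str, int]]]:
    residues = structure.residues()
    table: dict[tuple[str, int], dict[str, int]] = {key: {} for key in residues}
    for i, a in enumerate(structure.atoms):
        if a.name in ("N", "CA", "C", "O", "H", "HN"):
            table[(a.chain_id, a.residue_number)].setdefault("H" if a.name == "HN" else a.name, i)
    return residues, table


def _amide_h_position(n_pos: np.ndarray, ca_pos: np.ndarray, c_prev_pos: np.ndarray) -> np.ndarray:
    """Place an amide H 1.01 Å from N along the bisector away from CA and C(i−1)."""
    u = n_pos - ca_pos
    v = n_pos - c_prev_pos
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = u + v
    norm = np.linalg.norm(d)
    if norm < 1e-6:  # pathological straight geometry
        d = np.cross(u, [1.0, 0.0, 0.0])
        norm = np.linalg.norm(d)
    return n_pos + 1.01 * d / norm


def backbone_hbond_energy(
    structure: Structure,
    donor_residue_index: int,
    acceptor_residue_index: int,
    coords: np.ndarray | None = None,
) -> float:
    """Kabsch–Sander H-bond energy, donor N–H (residue i) to acceptor C=O.

    E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol; a bond is
    called when E < −0.5.  Residues are addressed by index into the
    structure's residue list.  Raises ``KeyError`` if backbone atoms are
    missing.
    """
    coords = structure.positions if coords is None else np.asarray(coords, dtype=float)
    residues, table = _backbone_map(structure)
    donor = table[residues[donor_residue_index]]
    acceptor = table[residues[acceptor_residue_index]]
    n_pos = coords[donor["N"]]
    if "H" in donor:
        h_pos = coords[donor["H"]]
    else:
        if donor_residue_index == 0:
            return 0.0  # N-terminal amine: no single amide H
        prev = table[residues[donor_residue_index - 1]]
        h_pos = _amide_h_position(n_pos, coords[donor["CA"]], coords[prev["C"]])
    c_pos = coords[acceptor["C"]]
    o_pos = coords[acceptor["O"]]
    r_on = np.linalg.norm(o_pos - n_pos)
    r_ch = np.linalg.norm(c_pos - h_pos)
    r_oh = np.linalg.norm(o_pos - h_pos)
    r_cn = np.linalg.norm(c_pos - n_pos)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry, not a real bond
        return 0.0
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(structure: Structure, coords: np.ndarray) -> np.ndarray:
    """bonds[i, j] is True when donor residue i H-bonds acceptor residue j."""
    residues, table = _backbone_map(structure)
    n = len(residues)
    coords = np.asarray(coords, dtype=float)
    # precompute positions; skip residues with incomplete backbones
    ok = np.zeros(n, dtype=bool)
    pos_n = np.zeros((n, 3))
    pos_c = np.zeros((n, 3))
    pos_o = np.zeros((n, 3))
    pos_h = np.zeros((n, 3))
    has_h = np.zeros(n, dtype=bool)
    for i, key in enumerate(residues):
        entry = table[key]
        if all(name in entry for name in ("N", "CA", "C", "O")):
            ok[i] = True
            pos_n[i] = coords[entry["N"]]
            pos_c[i] = coords[entry["C"]]
            pos_o[i] = coords[entry["O"]]
            if "H" in entry:
                pos_h[i] = coords[entry["H"]]
                has_h[i] = True
    for i in range(1, n):
        if ok[i] and ok[i - 1] and not has_h[i]:
            entry = table[residues[i]]
            pos_h[i] = _amide_h_position(pos_n[i], coords[entry["CA"]], pos_c[i - 1])
            has_h[i] = True

    bonds = np.zeros((n, n), dtype=bool)
    for i in range(n):  # donor
        if not ok[i] or not has_h[i]:
            continue
        for j in range(n):  # acceptor
            if not ok[j] or abs(i - j) < 2:
                continue
            r_on = np.linalg.norm(pos_o[j] - pos_n[i])
            if r_on > 5.2:  # beyond any plausible H-bond
                continue
            r_ch = np.linalg.norm(pos_c[j] - pos_h[i])
            r_oh = np.linalg.norm(pos_o[j] - pos_h[i])
            r_cn = np.linalg.norm(pos_c[j] - pos_n[i])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < HBOND_ENERGY_CUTOFF:
                bonds[i, j] = True
    return bonds


def assign_frame(structure: Structure, coords: np.ndarray | None = None) -> np.ndarray:
    """Secondary-structure class per residue for one frame."""
    coords = structure.positions if coords is None else coords
    bonds = _hbond_matrix(structure, coords)
    n = bonds.shape[0]
    # turn[k][i]: acceptor i accepts from donor i+k (an "i -> i+k turn" at i)
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4)}
    for k in (3, 4):
        for i in range(n - k):
            if bonds[i + k, i]:
                turn[k][i] = True

    cls = np.full(n, "C", dtype="<U1")
    # turns first (lowest priority, overwritten below)
    for k in (3, 4):
        for i in range(n - k):
            if turn[k][i]:
                for j in range(i + 1, i + k):
                    if cls[j] == "C":
                        cls[j] = "T"
    # strands: bridges between sequence-distant residues
    bridge = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 3:
                continue
            anti = bonds[i, j] and bonds[j, i]
            para = (
                (0 < i and bonds[j, i - 1] and i + 1 < n and bonds[i + 1, j])
                or (0 < j and bonds[i, j - 1] and j + 1 < n and bonds[j + 1, i])
            )
            if anti or para:
                bridge[i] = bridge[j] = True
    cls[bridge] = "E"
    # 3-10 helices: two consecutive 3-turns
    for i in range(n - 4):
        if turn[3][i] and turn[3][i + 1]:
            cls[i + 1 : i + 4] = "G"
    # alpha helices win over everything
    for i in range(n - 5):
        if turn[4][i] and turn[4][i + 1]:
            cls[i + 1 : i + 5] = "H"
    return cls


def assign_timeline(traj: Trajectory) -> SSTimeline:
    """Classify every frame of a trajectory (unfolding-timeline observable)."""
    structure = traj.structure_ref
    residues = structure.residues()
    classes = np.full((traj.n_frames, len(residues)), "C", dtype="<U1")
    for f in range(traj.n_frames):
        classes[f] = assign_frame(structure, traj.frames[f])
    resnums = np.array([r for _, r in residues], dtype=int)
    return SSTimeline(classes, traj.times.copy(), resnums)


# ---------------------------------------------------------------------------
# Ideal-backbone generator (fixture geometry)
# ---------------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = np.deg2rad(111.2)
_ANGLE_CA_C_N = np.deg2rad(116.2)
_ANGLE_C_N_CA = np.deg2rad(121.7)
_ANGLE_CA_C_O = np.deg2rad(120.8)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural extension reference frame: place atom d from a-b-c internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_backbone(phi: float, psi: float, n_residues: int, chain_id: str = "A") -> Structure:
    """Poly-alanine-like backbone (N, CA, C, O) at uniform (φ, ψ), ω = 180°.

    Angles in degrees.  φ=−57, ψ=−47 gives an α-helix; φ=ψ=180 an extended
    chain.  Used to generate classification fixtures.
    """
    from .structure import Atom

    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    phi_r, psi_r, omega_r = np.deg2rad(phi), np.deg2rad(psi), np.pi
    # seed first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + _BOND_CA_C * np.array([np.cos(np.pi - _ANGLE_N_CA_C), np.sin(np.pi - _ANGLE_N_CA_C), 0.0])
    backbone = [(n0, ca0, c0)]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _place(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, psi_r)
        ca_i = _place(ca_prev, c_prev, n_i, _BOND_N_CA, _ANGLE_C_N_CA, omega_r)
        c_i = _place(c_prev, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi_r)
        backbone.append((n_i, ca_i, c_i))

    atoms = []
    serial = 1
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        # carbonyl O anti to the next amide N: dihedral N-CA-C-O = psi + 180
        o_i = _place(n_i, ca_i, c_i, _BOND_C_O, _ANGLE_CA_C_O, psi_r + np.pi)
        for name, pos, element in (("N", n_i, "N"), ("CA", ca_i, "C"), ("C", c_i, "C"), ("O", o_i, "O")):
            atoms.append(
                Atom(serial=serial, name=name, element=element, residue_name="ALA",
                     residue_number=i + 1, chain_id=chain_id, position=pos)
            )
            serial += 1
    return Structure(atoms, title=f"ideal_backbone_phi{phi}_psi{psi}")
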