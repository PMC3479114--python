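"""Nonbonded side-chain interaction energies and mutant−WT differencing.

Pairwise energies are a 12-6 Lennard-Jones term and a Coulomb term, both
multiplied by a C¹-continuous cubic-in-r² switching function that turns the
interaction off between ``switch_on`` (10 Å) and ``cutoff`` (12 Å).  The
electrostatics are deliberately switched truncation, not Ewald: the analysed
trajectories are solvent-free and desk-scale, so a reaction-field or lattice
sum would be spurious precision.  A positive mutant−WT energy difference is
destabilizing (enthalpically unfavourable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contacts import sidechain_atom_indices
from .structure import Structure, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "NonbondedParams",
    "EnergyDecomposition",
    "switch_factor",
    "lj_switched",
    "coulomb_cut",
    "sidechain_interaction_energy",
    "mutation_delta",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)


@dataclass
class NonbondedParams:
    """Global nonbonded settings; per-atom parameters live on the atoms."""

    cutoff: float = 12.0  # Å
    switch_on: float = 10.0  # Å
    dielectric: float = 1.0

    def __post_init__(self) -> None:
        if not self.switch_on < self.cutoff:
            raise ValueError("switch_on must be smaller than cutoff")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


@dataclass
class EnergyDecomposition:
    vdw: float  # kcal/mol, time-averaged
    coulomb: float  # kcal/mol, time-averaged
    scope: str  # "vs_protein" or "vs_system"
    window: tuple[float, float]
    n_frames: int

    @property
    def total(self) -> float:
        return self.vdw + self.coulomb


def switch_factor(r, switch_on: float = 10.0, cutoff: float = 12.0):
    """CHARMM-style switching function S(r): 1 below, 0 above, C¹ between.

    S = (c²−r²)² (c² + 2r² − 3s²) / (c²−s²)³ for s < r < c.
    """
    r = np.asarray(r, dtype=float)
    s2, c2 = switch_on**2, cutoff**2
    r2 = r * r
    mid = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * s2) / (c2 - s2) ** 3
    out = np.where(r <= switch_on, 1.0, np.where(r >= cutoff, 0.0, mid))
    return float(out) if out.ndim == 0 else out


def lj_switched(r, eps_ij, rmin_ij, switch_on: float = 10.0, cutoff: float = 12.0):
    """Switched 12-6 Lennard-Jones energy (kcal/mol).

    ``rmin_ij`` is the pair distance of the minimum, at which the unswitched
    energy is exactly −eps_ij.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    q = (np.asarray(rmin_ij, dtype=float) / r) ** 6
    e = np.asarray(eps_ij, dtype=float) * (q * q - 2.0 * q)
    out = e * switch_factor(r, switch_on, cutoff)
    return float(out) if out.ndim == 0 else out


def coulomb_cut(r, qi, qj, cutoff: float = 12.0, dielectric: float = 1.0,
                switch_on: float = 10.0):
    """Switched, truncated Coulomb energy (kcal/mol)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    e = COULOMB_CONSTANT * np.asarray(qi, dtype=float) * np.asarray(qj, dtype=float) / (dielectric * r)
    out = e * switch_factor(r, switch_on, cutoff)
    return float(out) if out.ndim == 0 else out


def _per_atom_params(structure: Structure, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q = np.empty(len(indices))
    eps = np.empty(len(indices))
    rh = np.empty(len(indices))
    for k, i in enumerate(indices):
        a = structure.atoms[i]
        if math.isnan(a.charge) or math.isnan(a.lj_epsilon) or math.isnan(a.lj_rmin_half):
            raise ValueError(
                f"atom {a.serial} {a.name} (residue {a.residue_name} {a.residue_number}) "
                "lacks nonbonded parameters; supply a parameter table"
            )
        q[k], eps[k], rh[k] = a.charge, a.lj_epsilon, a.lj_rmin_half
    return q, eps, rh


def sidechain_interaction_energy(
    traj: Trajectory,
    residue: int,
    scope: str = "vs_protein",
    params: NonbondedParams | None = None,
    window: tuple[float, float] | None = None,
    exclusions: set[tuple[int, int]] | None = None,
    chain_id: str | None = None,
) -> EnergyDecomposition:
    """Time-averaged interaction energy of a residue's side chain with its scope.

    The scope is every atom of the system except the side chain itself
    (Lorentz–Berthelot combination: ε_ij = sqrt(ε_i ε_j), rmin_ij = rh_i + rh_j).
    The trajectories carried by this package contain no explicit solvent, so
    ``vs_system`` equals ``vs_protein`` plus an identically-zero solvent term;
    both scopes are accepted and recorded.  ``exclusions`` holds bonded
    (1-2/1-3) atom-index pairs to skip.
    """
    if scope not in ("vs_protein", "vs_system"):
        raise ValueError(f"unknown scope {scope!r}")
    params = params or NonbondedParams()
    structure = traj.structure_ref
    side_idx = np.asarray(sidechain_atom_indices(structure, residue, chain_id), dtype=int)
    rest_idx = np.setdiff1d(np.arange(structure.n_atoms), side_idx)
    sub = traj if window is None else traj.window(*window)

    q_s, eps_s, rh_s = _per_atom_params(structure, side_idx)
    q_r, eps_r, rh_r = _per_atom_params(structure, rest_idx)
    eps_ij = np.sqrt(eps_s[:, None] * eps_r[None, :])
    rmin_ij = rh_s[:, None] + rh_r[None, :]
    qq = q_s[:, None] * q_r[None, :]

    if exclusions:
        excl = np.zeros((len(side_idx), len(rest_idx)), dtype=bool)
        excl_set = {(min(i, j), max(i, j)) for i, j in exclusions}
        for a, i in enumerate(side_idx):
            for b, j in enumerate(rest_idx):
                if (min(i, j), max(i, j)) in excl_set:
                    excl[a, b] = True
        eps_ij = np.where(excl, 0.0, eps_ij)
        qq = np.where(excl, 0.0, qq)

    vdw_sum = 0.0
    coul_sum = 0.0
    for f in range(sub.n_frames):
        coords = sub.frames[f]
        diff = coords[side_idx][:, None, :] - coords[rest_idx][None, :, :]
        r = np.sqrt((diff**2).sum(axis=2))
        r = np.maximum(r, 1e-12)
        s = switch_factor(r, params.switch_on, params.cutoff)
        q6 = (rmin_ij / r) ** 6
        vdw_sum += float((eps_ij * (q6 * q6 - 2.0 * q6) * s).sum())
        coul_sum += float((COULOMB_CONSTANT * qq / (params.dielectric * r) * s).sum())

    n = sub.n_frames
    win = (float(sub.times[0]), float(sub.times[-1]))
    return EnergyDecomposition(vdw_sum / n, coul_sum / n, scope, win, n)


def mutation_delta(
    traj_wt: Trajectory,
    traj_mut: Trajectory,
    residue: int,
    scope: str = "vs_protein",
    params: NonbondedParams | None = None,
    window: tuple[float, float] | None = None,
    exclusions_wt: set[tuple[int, int]] | None = None,
    exclusions_mut: set[tuple[int, int]] | None = None,
) -> tuple[float, float]:
    """Mutant − wild-type interaction energy per component (Δvdw, Δcoulomb).

    Positive values are destabilizing.  The residue is addressed by its
    (shared) author number in both topologies.
    """
    e_wt = sidechain_interaction_energy(traj_wt, residue, scope, params, window, exclusions_wt)
    e_mut = sidechain_interaction_energy(traj_mut, residue, scope, params, window, exclusions_mut)
    return e_mut.vdw - e_wt.vdw, e_mut.coulomb - e_wt.coulomb
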