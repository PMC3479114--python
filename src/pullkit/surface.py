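"""Solvent-accessible surface area by Shrake–Rupley point sampling.

A deterministic generalized-spiral (Fibonacci) point set is placed on each
atom's probe-expanded sphere; points falling inside any other expanded sphere
of the occluding context are buried.  Splitting the computed selection from
the occluding context lets the caller ask, e.g., for the exposure of a buried
core while the whole protein still shades it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Series
from .structure import Selection, Structure, Trajectory, resolve_selection

__all__ = ["SasaResult", "sphere_points", "sasa", "sasa_series", "sasa_frame"]

DEFAULT_PROBE_RADIUS = 1.4  # Å, water-sized probe
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Å², aligned with atom_indices
    atom_indices: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere points (golden-angle spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    pts.setflags(write=False)
    return pts


def _radii_for(structure: Structure, indices: np.ndarray) -> np.ndarray:
    radii = np.empty(len(indices))
    for k, i in enumerate(indices):
        a = structure.atoms[i]
        r = a.vdw_radius
        if not np.isfinite(r) or r <= 0:
            raise ValueError(
                f"atom {a.serial} {a.name} (residue {a.residue_name} {a.residue_number}) "
                "has no usable van der Waals radius"
            )
        radii[k] = r
    return radii


def sasa_frame(
    coords: np.ndarray,
    radii: np.ndarray,
    compute_idx: np.ndarray,
    context_idx: np.ndarray,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (Å²) of ``compute_idx`` atoms occluded by ``context_idx``.

    Coordinate-level kernel shared by :func:`sasa` and :func:`sasa_series`;
    ``radii`` must cover all atoms referenced by either index array.
    """
    coords = np.asarray(coords, dtype=float)
    unit = sphere_points(int(n_points))
    expanded = radii + probe
    max_r = expanded[context_idx].max() if len(context_idx) else 0.0
    tree = cKDTree(coords[context_idx]) if len(context_idx) else None
    out = np.empty(len(compute_idx))
    for k, i in enumerate(compute_idx):
        r_i = expanded[i]
        pts = coords[i] + r_i * unit
        accessible = np.ones(len(pts), dtype=bool)
        if tree is not None:
            neigh = tree.query_ball_point(coords[i], r_i + max_r)
            for j_local in neigh:
                j = context_idx[j_local]
                if j == i:
                    continue
                d2 = ((pts - coords[j]) ** 2).sum(axis=1)
                accessible &= d2 >= expanded[j] ** 2
                if not accessible.any():
                    break
        out[k] = 4.0 * np.pi * r_i**2 * accessible.sum() / len(pts)
    return out


def sasa(
    structure: Structure,
    compute_sel: Selection | None = None,
    context_sel: Selection | None = None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    coords: np.ndarray | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA of ``compute_sel``, shaded by ``context_sel``.

    ``context_sel`` defaults to the whole structure (self-occlusion included);
    ``coords`` overrides the structure's own coordinates, e.g. for a
    trajectory frame.
    """
    all_idx = np.arange(structure.n_atoms)
    compute_idx = all_idx if compute_sel is None else resolve_selection(compute_sel, structure)
    context_idx = all_idx if context_sel is None else resolve_selection(context_sel, structure)
    coords = structure.positions if coords is None else np.asarray(coords, dtype=float)
    radii = np.full(structure.n_atoms, np.nan)
    union = np.union1d(compute_idx, context_idx)
    radii[union] = _radii_for(structure, union)
    per_atom = sasa_frame(coords, radii, compute_idx, context_idx, probe, n_points)
    return SasaResult(per_atom, compute_idx, probe, int(n_points))


def sasa_series(
    traj: Trajectory,
    compute_sel: Selection | None = None,
    context_sel: Selection | None = None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> Series:
    """Total SASA of a selection along a trajectory (one value per frame)."""
    structure = traj.structure_ref
    all_idx = np.arange(structure.n_atoms)
    compute_idx = all_idx if compute_sel is None else resolve_selection(compute_sel, structure)
    context_idx = all_idx if context_sel is None else resolve_selection(context_sel, structure)
    radii = np.full(structure.n_atoms, np.nan)
    union = np.union1d(compute_idx, context_idx)
    radii[union] = _radii_for(structure, union)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        values[f] = sasa_frame(traj.frames[f], radii, compute_idx, context_idx, probe, n_points).sum()
    label = compute_sel.label if compute_sel is not None else "all"
    return Series(traj.times.copy(), values, unit="A2", label=f"sasa_{label}")
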