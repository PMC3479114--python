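"""Coarse-grained bead-chain domain and constant-velocity pulling simulator.

The synthetic generator stands in for cluster-scale all-atom pulling runs: a
folded bead chain carries a small buried core whose solvent exposure is gated
by a terminal "shield" strap (the α-helix analogue).  Attractive wells are
placed only on pairs that are close in the built fold (a Gō-type model), so
the native geometry is the potential minimum; everything else repels through
a WCA wall.  Dynamics are BAOAB Langevin at 300 K with the pulling protocol
of the analysed simulations: a dummy point moves at constant velocity along
the fixed→pulled axis and drags the pulled bead through a harmonic spring,
the reported tensile force being F = k·extension.

Internal units: Å, ps, amu, kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .structure import Atom, Structure, Trajectory

__all__ = [
    "KCAL_MOL_A_IN_PN",
    "BOLTZMANN_KCAL_MOL_K",
    "ACCEL_CONVERSION",
    "ToyDomainSpec",
    "PullingConfig",
    "ToyTopology",
    "ForceSeries",
    "SimResult",
    "build_toy_domain",
    "apply_mutation",
    "langevin_pull",
    "equilibrium_run",
    "run_dynamics",
    "potential_energy",
    "kinetic_energy",
    "scripted_unfolding_trajectory",
]

KCAL_MOL_A_IN_PN = 69.479  # 1 kcal/mol/Å in piconewtons
BOLTZMANN_KCAL_MOL_K = 0.0019872041  # kcal/mol/K
ACCEL_CONVERSION = 418.4  # (kcal/mol/Å)/amu -> Å/ps²


@dataclass
class ToyDomainSpec:
    """Construction parameters of the folded toy domain.

    The chain wraps a spherical cup (the body) with a polar opening, dives
    mid-chain into a five-bead core cluster at the center, and ends in a
    short terminal strap docked across the opening above the core — the
    terminal-helix analogue whose undocking exposes the core.  The designed
    core (``core_members``) and its anchor default to the beads the
    native-contact rule recovers: the anchor plus its non-neighbour partners
    within the contact cutoff.  ``contact_epsilon = 0`` builds an unfolded
    straight chain with no designed contacts (barrier-free control).
    """

    n_beads: int = 36
    bead_mass: float = 110.0  # amu, residue-scale
    bond_length: float = 4.6  # Å, nominal shell spacing
    bond_stiffness: float = 100.0  # kcal/mol/Å², E = ½k(Δr)²
    contact_epsilon: float = 4.0  # kcal/mol per designed contact
    contact_distance: float = 7.5  # Å, design (Gō well) cutoff; wider than the
    # 6 Å analysis rule so near-miss pairs are restrained at their native distance
    scaffold_scale: float = 2.0  # body/core contacts are this much deeper than
    # shield-involving ones, so shield undocking is the designed first rupture
    core_members: tuple[int, ...] | None = None  # filled by build_toy_domain
    shield_members: tuple[int, ...] | None = None
    designed_core_anchor: int | None = None
    seed: int = 0
    # geometry details
    shell_radius: float = 7.0  # Å
    core_scale: float = 3.2  # Å, core cluster radius
    n_shield: int = 4  # strap (terminal-helix analogue) bead count
    opening_half_angle_deg: float = 65.0  # polar opening of the body cup
    strap_height: float = 7.0  # Å, strap elevation above the core
    strap_halfwidth: float = 4.2  # Å, strap span across the opening
    bead_vdw_radius: float = 3.5  # Å, for SASA
    wca_rmin: float = 3.8  # Å, excluded-volume wall position
    wca_epsilon: float = 1.0  # kcal/mol

    def __post_init__(self) -> None:
        if self.n_beads < 16:
            raise ValueError("toy domain needs at least 16 beads")
        if self.contact_epsilon < 0:
            raise ValueError("contact well depth must be non-negative")
        if self.core_members is not None and self.shield_members is not None:
            if set(self.core_members) & set(self.shield_members):
                raise ValueError("core and shield members must be disjoint")


@dataclass
class PullingConfig:
    """Constant-velocity pulling / equilibrium dynamics settings."""

    spring_k: float = 2.0  # kcal/mol/Å²
    pull_velocity: float = 5.0  # Å/ns
    timestep: float = 2.0  # fs
    friction: float = 1.0  # ps⁻¹ Langevin damping
    temperature: float = 300.0  # K
    fixed_bead: int = 0
    pulled_bead: int = -1  # -1 = last bead
    duration: float = 3.5  # ns
    snapshot_interval: float = 10.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spring_k", "pull_velocity", "timestep", "temperature", "duration", "snapshot_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


@dataclass
class ToyTopology:
    """Bonds, designed (Gō) contacts and repulsive pairs of a toy domain."""

    bonds: np.ndarray  # (m, 2) int
    bond_r0: np.ndarray  # (m,)
    bond_k: float
    contacts: np.ndarray  # (c, 2) int
    contact_rmin: np.ndarray  # (c,)
    contact_eps: np.ndarray  # (c,)
    wca_pairs: np.ndarray  # (w, 2) int
    wca_rmin: float
    wca_eps: float

    def bonded_exclusions(self) -> set[tuple[int, int]]:
        """1-2 and 1-3 atom-index pairs along the chain."""
        excl: set[tuple[int, int]] = set()
        adjacency: dict[int, set[int]] = {}
        for i, j in self.bonds:
            adjacency.setdefault(int(i), set()).add(int(j))
            adjacency.setdefault(int(j), set()).add(int(i))
            excl.add((min(int(i), int(j)), max(int(i), int(j))))
        for center, neigh in adjacency.items():
            for a in neigh:
                for b in neigh:
                    if a < b:
                        excl.add((a, b))
        return excl


@dataclass
class ForceSeries:
    """Spring-extension force record of a pulling run.

    The invariant ``force == spring_k × extension`` holds at every sample by
    construction (Hooke's law bookkeeping).
    """

    times: np.ndarray  # ps
    extension: np.ndarray  # Å
    force: np.ndarray  # kcal/mol/Å
    dummy_position: np.ndarray  # Å along the pull axis, relative to start
    spring_k: float

    @property
    def force_pN(self) -> np.ndarray:
        return self.force * KCAL_MOL_A_IN_PN

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# time_ps\textension_A\tforce_kcal_mol_A\tforce_pN\tdummy_A\n")
            for t, e, f, d in zip(self.times, self.extension, self.force, self.dummy_position):
                fh.write(f"{t:.6f}\t{e:.6f}\t{f:.6f}\t{f * KCAL_MOL_A_IN_PN:.6f}\t{d:.6f}\n")


@dataclass
class SimResult:
    trajectory: Trajectory
    force_series: ForceSeries | None
    velocities: np.ndarray  # (n_snapshots, n_beads, 3) Å/ps
    potential_energies: np.ndarray  # kcal/mol, internal potential (no spring)
    kinetic_energies: np.ndarray  # kcal/mol


# ---------------------------------------------------------------------------
# Toy-domain construction
# ---------------------------------------------------------------------------

def _spiral_cup(n: int, radius: float, h_max: float) -> np.ndarray:
    """Saff–Kuijlaars generalized spiral over a partial sphere.

    Near-uniform points ordered south→north with consecutive points adjacent
    on the surface, covering z/R ∈ [−1, h_max] (a cup with a polar opening).
    """
    pts = np.empty((n, 3))
    phi = 0.0
    for k in range(n):
        h = -1.0 + (1.0 + h_max) * k / (n - 1)
        theta = math.acos(max(-1.0, min(1.0, h)))
        if abs(h) >= 1.0:
            phi = 0.0
        else:
            phi = (phi + 3.6 / math.sqrt(n * (1.0 - h * h))) % (2.0 * math.pi)
        pts[k] = (
            radius * math.sin(theta) * math.cos(phi),
            radius * math.sin(theta) * math.sin(phi),
            radius * math.cos(theta),
        )
    return pts


def _core_cluster(scale: float) -> np.ndarray:
    """Five-bead core: a tetrahedron around the anchor, one edge facing up.

    Chain order is down1, anchor, down2, up1, up2 (anchor at the origin): the
    chain-adjacent beads down1/down2 flank the anchor, so the native-contact
    rule (which drops i±1 neighbours) recovers exactly {anchor, up1, up2} —
    the two beads that face the shield lid and gain solvent exposure when it
    peels away.
    """
    a = scale / math.sqrt(2.0)
    down1 = np.array([0.0, a, -a])
    down2 = np.array([0.0, -a, -a])
    up1 = np.array([a, 0.0, a])
    up2 = np.array([-a, 0.0, a])
    anchor = np.array([0.0, 0.0, 0.0])
    return np.stack([down1, anchor, down2, up1, up2])


def build_toy_domain(spec: ToyDomainSpec) -> tuple[Structure, ToyTopology, ToyDomainSpec]:
    """Build the folded bead chain, its topology, and the completed spec.

    Deterministic for a given seed.  Returns a copy of ``spec`` with
    ``core_members``, ``shield_members`` and ``designed_core_anchor`` filled
    in (when not supplied).  Bond rest lengths and contact minima equal the
    built distances, so the construction is a potential minimum.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_beads

    if spec.contact_epsilon == 0.0:
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * spec.bond_length
        core_idx = (n // 2 - 1, n // 2, n // 2 + 1)
        anchor_idx = n // 2
        shield_idx = tuple(range(n - spec.n_shield, n))
    else:
        n_core = 5
        n_body = n - n_core - spec.n_shield
        if n_body < 12 or spec.n_shield < 3:
            raise ValueError("n_beads too small for the cup/core/strap layout")
        h_max = math.cos(math.radians(spec.opening_half_angle_deg))
        body = _spiral_cup(n_body, spec.shell_radius, h_max)
        core = _core_cluster(spec.core_scale)
        # terminal strap: crosses the polar opening above the core pair
        strap_x = np.linspace(-spec.strap_halfwidth, spec.strap_halfwidth, spec.n_shield)
        strap = np.stack([strap_x, np.zeros(spec.n_shield), np.full(spec.n_shield, spec.strap_height)], axis=1)
        coords = np.concatenate([body, core, strap])
        core_start = n_body
        anchor_idx = core_start + 1  # chain order down1, anchor, down2, up1, up2
        core_idx = (anchor_idx, core_start + 3, core_start + 4)  # anchor, up1, up2
        shield_idx = tuple(range(n - spec.n_shield, n))

    coords = coords + 0.005 * rng.standard_normal(coords.shape)

    filled = replace(
        spec,
        core_members=spec.core_members or core_idx,
        shield_members=spec.shield_members or shield_idx,
        designed_core_anchor=(
            spec.designed_core_anchor if spec.designed_core_anchor is not None else anchor_idx
        ),
    )
    if set(filled.core_members) & set(filled.shield_members):
        raise ValueError("core and shield members must be disjoint")

    atoms = [
        Atom(
            serial=i + 1,
            name="CB",
            element="C",
            residue_name="BEA",
            residue_number=i + 1,
            chain_id="A",
            position=coords[i],
            mass=spec.bead_mass,
            charge=0.0,
            lj_epsilon=max(spec.contact_epsilon, 0.05),
            lj_rmin_half=1.75,  # pair minimum ~3.5 Å, the core packing distance
            vdw_radius=spec.bead_vdw_radius,
        )
        for i in range(n)
    ]
    structure = Structure(atoms, title=f"toy_domain_seed{spec.seed}")

    bonds = np.array([[i, i + 1] for i in range(n - 1)], dtype=np.int64)
    bond_r0 = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)

    con, rmin, eps = [], [], []
    shield_set = set(filled.shield_members)
    if spec.contact_epsilon > 0.0:
        for i in range(n):
            for j in range(i + 2, n):
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d <= spec.contact_distance:
                    con.append((i, j))
                    rmin.append(d)
                    scale = 1.0 if (i in shield_set or j in shield_set) else spec.scaffold_scale
                    eps.append(spec.contact_epsilon * scale)
    contacts = np.array(con, dtype=np.int64).reshape(-1, 2)
    contact_rmin = np.array(rmin)
    contact_eps = np.array(eps)

    contact_set = set(map(tuple, con))
    wca = np.array(
        [(i, j) for i in range(n) for j in range(i + 2, n) if (i, j) not in contact_set],
        dtype=np.int64,
    ).reshape(-1, 2)

    topology = ToyTopology(
        bonds=bonds,
        bond_r0=bond_r0,
        bond_k=spec.bond_stiffness,
        contacts=contacts,
        contact_rmin=contact_rmin,
        contact_eps=contact_eps,
        wca_pairs=wca,
        wca_rmin=spec.wca_rmin,
        wca_eps=spec.wca_epsilon,
    )
    return structure, topology, filled


def apply_mutation(
    structure: Structure,
    topology: ToyTopology,
    spec: ToyDomainSpec,
    epsilon_scale: float = 0.5,
) -> tuple[Structure, ToyTopology]:
    """Destabilizing "mutation": scale contact wells touching the core beads.

    Mirrors side-chain-packing mutations — only the interactions of the
    designated core beads weaken; geometry and connectivity are unchanged.
    The per-bead LJ epsilon used by the analysis energetics is scaled in step.
    """
    if spec.core_members is None:
        raise ValueError("spec.core_members is unset; build the domain first")
    if epsilon_scale < 0:
        raise ValueError("epsilon scale must be non-negative")
    core = set(spec.core_members)
    eps = topology.contact_eps.copy()
    for k, (i, j) in enumerate(topology.contacts):
        if int(i) in core or int(j) in core:
            eps[k] *= epsilon_scale
    new_top = replace(topology, contact_eps=eps)
    new_struct = structure.copy()
    for i in core:
        new_struct.atoms[i].lj_epsilon *= epsilon_scale
    return new_struct, new_top


# ---------------------------------------------------------------------------
# Forces and BAOAB integration (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forces_energy(
    x, bonds, bond_r0, bond_k, con, con_rmin, con_eps,
    wca, wca_rmin, wca_eps, f,
):
    f[:] = 0.0
    pe = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        pe += 0.5 * bond_k * dr * dr
        fac = -bond_k * dr / r
        f[i, 0] += fac * dx; f[i, 1] += fac * dy; f[i, 2] += fac * dz
        f[j, 0] -= fac * dx; f[j, 1] -= fac * dy; f[j, 2] -= fac * dz
    for c in range(con.shape[0]):
        i, j = con[c, 0], con[c, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        q6 = (con_rmin[c] / r) ** 6
        pe += con_eps[c] * (q6 * q6 - 2.0 * q6)
        # dE/dr = eps * (-12 q12 + 12 q6)/r ; force = -dE/dr along r_hat
        fac = 12.0 * con_eps[c] * (q6 * q6 - q6) / r2
        f[i, 0] += fac * dx; f[i, 1] += fac * dy; f[i, 2] += fac * dz
        f[j, 0] -= fac * dx; f[j, 1] -= fac * dy; f[j, 2] -= fac * dz
    for c in range(wca.shape[0]):
        i, j = wca[c, 0], wca[c, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < wca_rmin * wca_rmin:
            r = math.sqrt(r2)
            q6 = (wca_rmin / r) ** 6
            pe += wca_eps * (q6 * q6 - 2.0 * q6 + 1.0)
            fac = 12.0 * wca_eps * (q6 * q6 - q6) / r2
            f[i, 0] += fac * dx; f[i, 1] += fac * dy; f[i, 2] += fac * dz
            f[j, 0] -= fac * dx; f[j, 1] -= fac * dy; f[j, 2] -= fac * dz
    return pe


@njit(cache=True)
def _baoab_chunk(
    x, v, f, inv_m_acc, dt, c1, sigma, normals,
    bonds, bond_r0, bond_k, con, con_rmin, con_eps, wca, wca_rmin, wca_eps,
    spring_k, dummy_start, pull_dir, pull_vel, t_start, pulled, fixed,
):
    """Advance ``normals.shape[0]`` BAOAB steps; returns the final PE."""
    n_steps = normals.shape[0]
    n = x.shape[0]
    pe = 0.0
    for s in range(n_steps):
        for i in range(n):
            v[i, 0] += 0.5 * dt * f[i, 0] * inv_m_acc[i]
            v[i, 1] += 0.5 * dt * f[i, 1] * inv_m_acc[i]
            v[i, 2] += 0.5 * dt * f[i, 2] * inv_m_acc[i]
        v[fixed, 0] = 0.0; v[fixed, 1] = 0.0; v[fixed, 2] = 0.0
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]
        for i in range(n):
            v[i, 0] = c1 * v[i, 0] + sigma[i] * normals[s, i, 0]
            v[i, 1] = c1 * v[i, 1] + sigma[i] * normals[s, i, 1]
            v[i, 2] = c1 * v[i, 2] + sigma[i] * normals[s, i, 2]
        v[fixed, 0] = 0.0; v[fixed, 1] = 0.0; v[fixed, 2] = 0.0
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]
        pe = _forces_energy(x, bonds, bond_r0, bond_k, con, con_rmin, con_eps, wca, wca_rmin, wca_eps, f)
        if spring_k > 0.0:
            t_now = t_start + (s + 1) * dt
            travel = pull_vel * t_now
            dxs = dummy_start[0] + pull_dir[0] * travel - x[pulled, 0]
            dys = dummy_start[1] + pull_dir[1] * travel - x[pulled, 1]
            dzs = dummy_start[2] + pull_dir[2] * travel - x[pulled, 2]
            f[pulled, 0] += spring_k * dxs
            f[pulled, 1] += spring_k * dys
            f[pulled, 2] += spring_k * dzs
        f[fixed, 0] = 0.0; f[fixed, 1] = 0.0; f[fixed, 2] = 0.0
        for i in range(n):
            v[i, 0] += 0.5 * dt * f[i, 0] * inv_m_acc[i]
            v[i, 1] += 0.5 * dt * f[i, 1] * inv_m_acc[i]
            v[i, 2] += 0.5 * dt * f[i, 2] * inv_m_acc[i]
        v[fixed, 0] = 0.0; v[fixed, 1] = 0.0; v[fixed, 2] = 0.0
    return pe


def potential_energy(coords: np.ndarray, topology: ToyTopology) -> float:
    """Internal potential energy (bonds + contacts + WCA), kcal/mol."""
    f = np.zeros_like(np.asarray(coords, dtype=float))
    return float(
        _forces_energy(
            np.asarray(coords, dtype=float),
            topology.bonds, topology.bond_r0, topology.bond_k,
            topology.contacts, topology.contact_rmin, topology.contact_eps,
            topology.wca_pairs, topology.wca_rmin, topology.wca_eps, f,
        )
    )


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    v2 = (np.asarray(velocities) ** 2).sum(axis=1)
    return float(0.5 * (masses * v2).sum() / ACCEL_CONVERSION)


def run_dynamics(
    structure: Structure,
    topology: ToyTopology,
    cfg: PullingConfig,
    pulling: bool = True,
) -> SimResult:
    """Integrate Langevin dynamics, with or without the pulling spring.

    Snapshots (coordinates, velocities, energies, and — when pulling — the
    spring force record) are taken every ``cfg.snapshot_interval`` ps,
    including the initial state at t = 0.  The same seed gives bit-identical
    output.
    """
    n = structure.n_atoms
    fixed = cfg.fixed_bead % n
    pulled = cfg.pulled_bead % n
    if fixed == pulled:
        raise ValueError("fixed and pulled beads must differ")
    dt = cfg.timestep * 1e-3  # fs -> ps
    steps_per_snap = int(round(cfg.snapshot_interval / dt))
    n_snap = int(round(cfg.duration * 1000.0 / cfg.snapshot_interval))
    if steps_per_snap < 1 or n_snap < 1:
        raise ValueError("duration/snapshot_interval/timestep combination yields no steps")

    masses = structure.masses
    x = structure.positions.copy()
    rng = np.random.default_rng(cfg.seed)
    kt = BOLTZMANN_KCAL_MOL_K * cfg.temperature
    v = rng.standard_normal((n, 3)) * np.sqrt(kt * ACCEL_CONVERSION / masses)[:, None]
    v[fixed] = 0.0

    axis = x[pulled] - x[fixed]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("fixed and pulled beads coincide; pull axis undefined")
    axis = axis / norm
    dummy_start = x[pulled].copy()
    pull_vel = cfg.pull_velocity * 1e-3 if pulling else 0.0  # Å/ns -> Å/ps
    spring_k = cfg.spring_k if pulling else 0.0

    c1 = math.exp(-cfg.friction * dt)
    sigma = np.sqrt(kt * ACCEL_CONVERSION / masses * (1.0 - c1 * c1))
    if cfg.friction == 0.0:
        sigma = np.zeros_like(sigma)
    inv_m_acc = ACCEL_CONVERSION / masses

    f = np.zeros((n, 3))
    pe = _forces_energy(
        x, topology.bonds, topology.bond_r0, topology.bond_k,
        topology.contacts, topology.contact_rmin, topology.contact_eps,
        topology.wca_pairs, topology.wca_rmin, topology.wca_eps, f,
    )
    if spring_k > 0.0:
        f[pulled] += spring_k * (dummy_start - x[pulled])
    f[fixed] = 0.0

    frames = np.empty((n_snap + 1, n, 3))
    vels = np.empty((n_snap + 1, n, 3))
    times = np.empty(n_snap + 1)
    pes = np.empty(n_snap + 1)
    kes = np.empty(n_snap + 1)
    ext = np.empty(n_snap + 1)
    dummy_scalar = np.empty(n_snap + 1)

    def _record(k: int, t: float, pe_now: float) -> None:
        frames[k] = x
        vels[k] = v
        times[k] = t
        pes[k] = pe_now
        kes[k] = kinetic_energy(v, masses)
        travel = pull_vel * t
        dummy = dummy_start + axis * travel
        ext[k] = float(np.linalg.norm(dummy - x[pulled]))
        dummy_scalar[k] = travel

    _record(0, 0.0, pe)
    for k in range(1, n_snap + 1):
        t_start = (k - 1) * cfg.snapshot_interval
        normals = rng.standard_normal((steps_per_snap, n, 3))
        pe = _baoab_chunk(
            x, v, f, inv_m_acc, dt, c1, sigma, normals,
            topology.bonds, topology.bond_r0, topology.bond_k,
            topology.contacts, topology.contact_rmin, topology.contact_eps,
            topology.wca_pairs, topology.wca_rmin, topology.wca_eps,
            spring_k, dummy_start, axis, pull_vel, t_start, pulled, fixed,
        )
        if not np.all(np.isfinite(x)) or np.abs(x).max() > 1e5:
            raise RuntimeError(
                "integrator blow-up (coordinates diverged); use a smaller timestep"
            )
        _record(k, k * cfg.snapshot_interval, pe)

    traj = Trajectory(frames, times, structure)
    force_series = None
    if pulling:
        force_series = ForceSeries(
            times=times.copy(),
            extension=ext,
            force=cfg.spring_k * ext,
            dummy_position=dummy_scalar,
            spring_k=cfg.spring_k,
        )
    return SimResult(traj, force_series, vels, pes, kes)


def langevin_pull(
    structure: Structure, topology: ToyTopology, cfg: PullingConfig
) -> tuple[Trajectory, ForceSeries]:
    """Constant-velocity pulling run; see :func:`run_dynamics`."""
    res = run_dynamics(structure, topology, cfg, pulling=True)
    assert res.force_series is not None
    return res.trajectory, res.force_series


def equilibrium_run(
    structure: Structure, topology: ToyTopology, cfg: PullingConfig
) -> Trajectory:
    """Force-free 300 K run (native-contact and RMSF input)."""
    return run_dynamics(structure, topology, cfg, pulling=False).trajectory


# ---------------------------------------------------------------------------
# Scripted trajectories (exact ground truth for detector tests)
# ---------------------------------------------------------------------------

def scripted_unfolding_trajectory(
    structure: Structure,
    plan: list[tuple[int, "Selection | np.ndarray | list[int]", np.ndarray]],
    n_frames: int,
    frame_spacing: float = 10.0,
    force_slope: float = 0.02,  # kcal/mol/Å per ps
    spring_k: float = 2.0,
) -> tuple[Trajectory, ForceSeries]:
    """Deterministic trajectory applying displacements at scripted frames.

    Each plan entry ``(frame, selection, displacement)`` rigidly displaces the
    selected atoms at that frame (persisting afterwards).  The accompanying
    force series is a sawtooth: it ramps linearly and drops to zero at every
    scripted frame — programmed rupture events with exact ground truth.
    """
    from .structure import Selection as _Selection

    base = structure.positions
    events: list[tuple[int, np.ndarray, np.ndarray]] = []
    for frame, sel, disp in plan:
        if not 0 <= frame < n_frames:
            raise ValueError(f"scripted frame {frame} outside [0, {n_frames})")
        if isinstance(sel, _Selection):
            idx = sel.resolve(structure)
        else:
            idx = np.asarray(sel, dtype=int)
        events.append((frame, idx, np.asarray(disp, dtype=float)))

    frames = np.empty((n_frames, structure.n_atoms, 3))
    current = base.copy()
    times = np.arange(n_frames, dtype=float) * frame_spacing
    force = np.empty(n_frames)
    last_drop_t = times[0]
    drop_frames = sorted({frame for frame, _, _ in events})
    for fidx in range(n_frames):
        for frame, idx, disp in events:
            if frame == fidx:
                current[idx] += disp
        frames[fidx] = current
        if fidx in drop_frames:
            last_drop_t = times[fidx]
        force[fidx] = force_slope * (times[fidx] - last_drop_t)
    extension = force / spring_k
    fs = ForceSeries(times.copy(), extension, force, dummy_position=extension.copy(), spring_k=spring_k)
    return Trajectory(frames, times, structure), fs
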