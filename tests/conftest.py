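"""Shared fixtures: small structures and session-scoped simulator runs."""

import numpy as np
import pytest

from pullkit import pulling
from pullkit.structure import Atom, Selection, Structure, Trajectory


def make_atom(serial, name, element, resname, resnum, pos, chain="A", **kw):
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=resnum, chain_id=chain, position=np.asarray(pos, float), **kw
    )


@pytest.fixture(scope="session")
def toy_domain():
    """Default folded toy domain: (structure, topology, completed spec)."""
    spec = pulling.ToyDomainSpec(seed=0)
    return pulling.build_toy_domain(spec)


@pytest.fixture(scope="session")
def core_selection(toy_domain):
    _, _, spec = toy_domain
    return Selection(label="core", residue_numbers=[i + 1 for i in spec.core_members])


@pytest.fixture(scope="session")
def equil_traj(toy_domain):
    """0.5 ns force-free run of the default domain (fixed seed)."""
    structure, topology, _ = toy_domain
    cfg = pulling.PullingConfig(duration=0.5, seed=11)
    return pulling.equilibrium_run(structure, topology, cfg)


@pytest.fixture(scope="session")
def pull_run(toy_domain):
    """One default pulling run (fixed seed): (trajectory, force series)."""
    structure, topology, _ = toy_domain
    cfg = pulling.PullingConfig(seed=7)
    return pulling.langevin_pull(structure, topology, cfg)


@pytest.fixture
def tiny_structure():
    """Three-residue, five-atom structure with hand-set fields."""
    atoms = [
        make_atom(1, "CA", "C", "GLY", 10, [0.0, 0.0, 0.0], b_factor=25.0),
        make_atom(2, "CA", "C", "ALA", 11, [3.8, 0.0, 0.0], b_factor=30.0),
        make_atom(3, "CB", "C", "ALA", 11, [4.5, 1.2, 0.3], b_factor=32.0),
        make_atom(4, "CA", "C", "SER", 12, [7.6, 0.0, 0.0], b_factor=20.0),
        make_atom(5, "OG", "O", "SER", 12, [8.3, 1.1, -0.4], b_factor=22.0),
    ]
    return Structure(atoms, title="tiny")


def static_trajectory(structure, n_frames=5, spacing=10.0):
    frames = np.repeat(structure.positions[None, :, :], n_frames, axis=0)
    times = np.arange(n_frames, dtype=float) * spacing
    return Trajectory(frames, times, structure)
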