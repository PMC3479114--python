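"""Rigid-body superposition, RMSD/RMSF profiles and series smoothing.

Superposition is the standard Kabsch algorithm (SVD with a determinant guard
so only proper rotations are returned).  RMSF profiles are computed against an
iteratively refined mean structure (two alignment passes), and crystallographic
B-factors convert to fluctuations through RMSF = sqrt(3B / 8π²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Selection, Structure, Trajectory, resolve_selection

__all__ = [
    "Series",
    "RMSFProfile",
    "kabsch_superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf_profile",
    "bfactor_to_rmsf",
    "rmsf_to_bfactor",
    "running_average",
]


@dataclass
class Series:
    """A uniformly sampled, unit-tagged time series."""

    times: np.ndarray  # ps
    values: np.ndarray
    unit: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# time_ps\t{self.label or 'value'}_{self.unit or 'au'}\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6f}\t{v:.6f}\n")


@dataclass
class RMSFProfile:
    residue_numbers: np.ndarray
    rmsf: np.ndarray  # Å
    n_frames_used: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.residue_numbers.shape != self.rmsf.shape:
            raise ValueError("residue_numbers and rmsf must have equal length")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be non-negative")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# residue\trmsf_A\n")
            for r, v in zip(self.residue_numbers, self.rmsf):
                fh.write(f"{r}\t{v:.6f}\n")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD.  The
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    # collinearity check: centered points must span >= 2 dimensions
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("points are collinear; superposition is degenerate")

    h = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = (w[:, None] * reference).sum(axis=0) - rotation @ (w[:, None] * mobile).sum(axis=0)
    moved = mob_c @ rotation.T
    rmsd = float(np.sqrt((w * ((moved - ref_c) ** 2).sum(axis=1)).sum()))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    fit_sel: Selection,
    measure_sel: Selection | None = None,
) -> Series:
    """Per-frame RMSD to a reference after superposition.

    Each frame is superposed onto the reference over ``fit_sel``; the RMSD is
    then measured over ``measure_sel`` (defaults to ``fit_sel``).  Using a
    distinct, immobile fit selection measures displacement of the region of
    interest in the reference frame of the rest of the molecule.
    """
    measure_sel = measure_sel if measure_sel is not None else fit_sel
    fit_idx = resolve_selection(fit_sel, traj.structure_ref)
    meas_idx = resolve_selection(measure_sel, traj.structure_ref)
    ref_fit = reference.positions[fit_idx]
    ref_meas = reference.positions[meas_idx]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        rot, trans, _ = kabsch_superpose(frame[fit_idx], ref_fit)
        values[i] = _rmsd(apply_transform(frame[meas_idx], rot, trans), ref_meas)
    return Series(traj.times.copy(), values, unit="A", label=f"rmsd_{measure_sel.label}")


def rmsf_profile(
    traj: Trajectory,
    sel: Selection,
    window: tuple[float, float] | None = None,
    n_passes: int = 2,
) -> RMSFProfile:
    """Per-residue RMSF over a time window.

    Frames are aligned (over ``sel``) onto an iteratively refined mean
    structure — first pass against the first frame, subsequent passes against
    the running mean — then RMSF_i = sqrt(<|x_i - <x_i>|²>_t).  One value per
    selected atom is reported under its residue number, so the usual use is a
    Cα (or bead) selection.
    """
    sub = traj if window is None else traj.window(*window)
    if sub.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames in the window")
    idx = resolve_selection(sel, traj.structure_ref)
    coords = sub.frames[:, idx, :].copy()

    # n_passes = 0 skips alignment (frames already share a fixed frame of
    # reference, e.g. scripted fixtures with no net rigid motion)
    reference = coords[0]
    for _ in range(max(0, n_passes)):
        aligned = np.empty_like(coords)
        for i in range(coords.shape[0]):
            rot, trans, _ = kabsch_superpose(coords[i], reference)
            aligned[i] = apply_transform(coords[i], rot, trans)
        reference = aligned.mean(axis=0)
        coords = aligned

    mean = coords.mean(axis=0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    residues = traj.structure_ref.residue_numbers[idx]
    win = (float(sub.times[0]), float(sub.times[-1]))
    return RMSFProfile(residues, rmsf, n_frames_used=sub.n_frames, window=win)


_B_FACTOR_COEFF = 3.0 / (8.0 * np.pi**2)


def bfactor_to_rmsf(b):
    """Convert a crystallographic B-factor (Å²) to an RMSF (Å).

    RMSF = sqrt(3 B / 8π²), the isotropic harmonic relation.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("B-factor must be non-negative")
    out = np.sqrt(_B_FACTOR_COEFF * b)
    return float(out) if out.ndim == 0 else out


def rmsf_to_bfactor(rmsf):
    rmsf = np.asarray(rmsf, dtype=float)
    if np.any(rmsf < 0):
        raise ValueError("RMSF must be non-negative")
    out = rmsf**2 / _B_FACTOR_COEFF
    return float(out) if out.ndim == 0 else out


def running_average(series: Series, width: float = 20.0) -> Series:
    """Centered running mean over a time width (ps), length preserving.

    The window spans ``w = round(width / spacing)`` consecutive samples
    (minimum 1), centered on each sample — for even ``w`` the extra sample is
    taken on the trailing (later) side.  Windows are truncated at the series
    edges, so edge values average fewer samples.
    """
    if len(series) < 2:
        raise ValueError("running average needs at least 2 samples")
    spacing = np.diff(series.times)
    if not np.allclose(spacing, spacing[0], rtol=1e-6, atol=1e-9):
        raise ValueError("running average requires uniform sampling")
    dt = float(spacing[0])
    if width < dt:
        raise ValueError(f"width {width} ps is smaller than the sample spacing {dt} ps")
    w = max(1, int(round(width / dt)))
    before = (w - 1) // 2
    after = w // 2
    n = len(series)
    csum = np.concatenate(([0.0], np.cumsum(series.values)))
    lo = np.maximum(np.arange(n) - before, 0)
    hi = np.minimum(np.arange(n) + after, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return Series(series.times.copy(), smoothed, unit=series.unit, label=series.label)
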