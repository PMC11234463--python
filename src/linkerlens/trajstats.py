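"""Trajectory windowing and MD-derived statistics.

Implements the four quantities used to compare polyP-binding-pocket dynamics
across linker variants:

* RMSD to a reference after optional Kabsch superposition,
* per-atom / per-residue RMSF about the time-averaged position,
* center-of-mass (CoM) distance between two selections (e.g. the two
  polyP-binding loops), and
* heavy-atom contact counts at a strict < 5 Å cutoff, counting distinct
  *target* atoms in contact rather than atom pairs.

Analysis windows are taken from the tail of each trajectory ("the last
100 ns"), inclusive of both endpoints, so a 0–1000 ns run sampled every
1 ns contributes 101 frames and three such runs pool to 303 data points
(1001 and 3003 at 0.1 ns sampling).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure, read_pdb_models

__all__ = [
    "Trajectory",
    "SelectionStats",
    "RmsfProfile",
    "window_last",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rmsf",
    "com_distance",
    "contact_count",
    "selection_stats",
    "read_trajectory_pdb",
]

DEFAULT_CONTACT_CUTOFF = 5.0  # Å, strict <


@dataclass
class Trajectory:
    """Frames congruent with a reference Structure's atom order.

    frames: (n_frames, n_atoms, 3) Å; times: ns, strictly increasing.
    """

    frames: np.ndarray
    times: np.ndarray
    reference: Structure | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class SelectionStats:
    com_distances: np.ndarray  # Å per frame
    contact_counts: np.ndarray  # int per frame
    frame_times: np.ndarray  # ns


@dataclass(frozen=True)
class RmsfProfile:
    per_atom: np.ndarray     # Å
    per_residue: np.ndarray  # Å, mean over each residue's member atoms


def window_last(traj: Trajectory, duration: float) -> Trajectory:
    """Keep frames with time ≥ t_end − duration (both endpoints inclusive)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = traj.times
    span = t[-1] - t[0]
    if span < duration:
        raise ValueError(f"trajectory span {span} ns shorter than window {duration} ns")
    cutoff = t[-1] - duration
    # tolerate float round-off at the window edge
    mask = t >= cutoff - 1e-9
    return Trajectory(frames=traj.frames[mask], times=t[mask], reference=traj.reference)


def kabsch_rotation(ref: np.ndarray, mob: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of mob onto ref (least-squares, Kabsch).

    Returns (R, t_ref, t_mob): rotate mob−t_mob by R then add t_ref.
    """
    c_ref = ref.mean(axis=0)
    c_mob = mob.mean(axis=0)
    h = (mob - c_mob).T @ (ref - c_ref)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if s[1] < 1e-10:
        warnings.warn("degenerate (collinear) coordinates in superposition", stacklevel=2)
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return rot, c_ref, c_mob


def kabsch_rmsd(ref_coords: np.ndarray, mob_coords: np.ndarray, superpose: bool = True) -> float:
    """RMSD = √(Σᵢ|rᵢ − rᵢ′|² / N), after optimal superposition if requested."""
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mob_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3) with equal N")
    if superpose:
        if len(ref) < 3:
            raise ValueError("superposition needs ≥3 atoms")
        rot, c_ref, c_mob = kabsch_rotation(ref, mob)
        mob = (mob - c_mob) @ rot.T + c_ref
    return float(np.sqrt(((mob - ref) ** 2).sum(axis=1).mean()))


def superpose_frames(traj: Trajectory, fit_indices: np.ndarray | None = None) -> Trajectory:
    """Kabsch-fit every frame onto frame 1 (over fit_indices, default all atoms)."""
    idx = np.arange(traj.n_atoms) if fit_indices is None else np.asarray(fit_indices)
    ref = traj.frames[0][idx]
    out = np.empty_like(traj.frames)
    out[0] = traj.frames[0]
    for k in range(1, traj.n_frames):
        rot, c_ref, c_mob = kabsch_rotation(ref, traj.frames[k][idx])
        out[k] = (traj.frames[k] - c_mob) @ rot.T + c_ref
    return Trajectory(frames=out, times=traj.times.copy(), reference=traj.reference)


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    residue_atom_indices: list[np.ndarray] | None = None,
    superpose: bool = True,
) -> RmsfProfile:
    """Root-mean-square fluctuation about the time-averaged position.

    per-atom RMSF_i = √( mean_t |r_i(t) − r̄_i|² ); per-residue values are the
    arithmetic mean of the member atoms' RMSFs. Frames are Kabsch-fitted to
    frame 1 over the selection first (global rotation/translation removed),
    unless ``superpose=False``.
    """
    if traj.n_frames < 2:
        raise ValueError("rmsf needs ≥2 frames")
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    work = superpose_frames(traj, idx) if superpose and len(idx) >= 3 else traj
    coords = work.frames[:, idx, :]
    mean_pos = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    if residue_atom_indices is not None:
        per_res = np.array([per_atom[np.asarray(g)].mean() for g in residue_atom_indices])
    else:
        per_res = per_atom.copy()
    return RmsfProfile(per_atom=per_atom, per_residue=per_res)


def com_distance(
    frame: np.ndarray,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """Distance between the (mass-weighted) centroids of two atom selections."""
    frame = np.asarray(frame, dtype=float)
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("com_distance: empty selection")

    def com(sel: np.ndarray) -> np.ndarray:
        pts = frame[sel]
        if mass_weighted:
            if masses is None:
                raise ValueError("mass_weighted=True requires masses")
            w = masses[sel]
            return (pts * w[:, None]).sum(axis=0) / w.sum()
        return pts.mean(axis=0)

    return float(np.linalg.norm(com(sel_a) - com(sel_b)))


def contact_count(
    frame: np.ndarray,
    source_sel: np.ndarray,
    target_sel: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> int:
    """Number of distinct *target* atoms with ≥1 source atom strictly closer
    than ``cutoff``. Atoms are counted, not pairs; the selections must be
    disjoint (the NTD/CTD and polyP/loop selections never share atoms)."""
    source_sel = np.asarray(source_sel, dtype=int)
    target_sel = np.asarray(target_sel, dtype=int)
    if np.intersect1d(source_sel, target_sel).size:
        raise ValueError("contact_count: source and target selections overlap")
    frame = np.asarray(frame, dtype=float)
    src = frame[source_sel]
    tgt = frame[target_sel]
    tree = cKDTree(src)
    dmin, _ = tree.query(tgt, k=1)
    return int((dmin < cutoff).sum())


def selection_stats(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    masses: np.ndarray | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    mass_weighted: bool = True,
) -> SelectionStats:
    """Per-frame CoM distance between selections and contact count (A as
    source, B as target)."""
    com = np.array([
        com_distance(f, sel_a, sel_b, masses=masses, mass_weighted=mass_weighted)
        for f in traj.frames
    ])
    contacts = np.array([
        contact_count(f, sel_a, sel_b, cutoff=cutoff) for f in traj.frames
    ])
    return SelectionStats(com_distances=com, contact_counts=contacts,
                          frame_times=traj.times.copy())


# ---------------------------------------------------------------------------
# Trajectory I/O: multi-model PDB with REMARK TIME_NS, or XYZ + times CSV

def read_trajectory_pdb(stream) -> Trajectory:
    """Read a multi-model PDB as a trajectory; frame times come from
    ``REMARK   6 TIME_NS <t>`` lines (frame index in ns when absent)."""
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    times = [
        float(line.split()[-1])
        for line in io.StringIO(text)
        if line.startswith("REMARK") and "TIME_NS" in line
    ]
    models = read_pdb_models(text)
    frames = np.stack([m.coords() for m in models])
    if len(times) != len(models):
        times = list(range(len(models)))
    return Trajectory(frames=frames, times=np.asarray(times, dtype=float),
                      reference=models[0])
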