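"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its arguments and a seed (NumPy's PCG64
generator via ``numpy.random.default_rng``, so outputs are bit-stable across
platforms and repeat calls), and each emits its ground truth alongside the
data so downstream recovery can be asserted exactly:

* ideal α-helices on a cylinder (rise 1.5 Å, twist 100°, radius 2.3 Å —
  giving the canonical d(i,i+3) = 5.05 Å, d(i,i+4) = 6.20 Å signature),
* single-chain linker proteins with a REG anchor and an optional Pro-X-Pro
  or glycine-rich interruption at a chosen linker position,
* reference-jittered trajectories with known per-atom fluctuation scale
  (i.i.d. Gaussian noise of σ per coordinate gives per-atom RMSF √3·σ),
* Michaelis–Menten initial-rate datasets with multiplicative noise, and
* alignments with planted REG / Pro-X-Pro / GRGG motifs at known columns.

Synthetic structures carry Cα atoms only: sufficient for helix assignment,
superposition, RMSF, CoM and contact statistics. Surface-area tests use
explicit multi-atom toys instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evolution import Alignment
from .kinetics import KineticsDataset, michaelis_menten
from .linker import LinkerReport, MotifHit, Termination
from .structio import ONE_TO_THREE, Atom, Chain, Residue, Structure
from .trajstats import Trajectory

__all__ = [
    "GeneratorConfig",
    "build_helix",
    "ca_chain",
    "gen_linker_protein",
    "gen_trajectory",
    "gen_mm_dataset",
    "gen_alignment",
]

# residues that can never create REG, Pro-X-Pro or glycine-rich hits
SAFE_ALPHABET = "ADEFHIKLMNQSTVWY"

HELIX_RISE = 1.5     # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3   # Å


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of generator settings; same (config, seed) → identical bytes."""

    seed: int = 0
    traj_sigma: float = 0.5     # Å, per-coordinate jitter
    kinetics_cv: float = 0.05   # multiplicative noise CV
    msa_sub_rate: float = 0.1   # per-site substitution probability
    rng_algorithm: str = "PCG64"


def helix_coords(
    n_res: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Cα positions of an ideal α-helix on a cylinder."""
    if n_res < 1:
        raise ValueError("n_res must be ≥1")
    i = np.arange(n_res, dtype=float)
    ang = np.deg2rad(twist) * i
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])
    if origin is not None:
        pts = pts + np.asarray(origin, dtype=float)
    return pts


def ca_chain(
    coords: np.ndarray,
    sequence: str,
    chain_id: str = "A",
    start_resseq: int = 1,
) -> Chain:
    """Build a Cα-only chain from coordinates and a 1-letter sequence."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) != len(sequence):
        raise ValueError("coords and sequence lengths differ")
    chain = Chain(id=chain_id)
    for k, (xyz, letter) in enumerate(zip(coords, sequence.upper())):
        resname = ONE_TO_THREE.get(letter, "UNK")
        chain.residues.append(
            Residue(
                resname=resname,
                resseq=start_resseq + k,
                atoms=[Atom(name="CA", element="C", coords=xyz)],
            )
        )
    return chain


def build_helix(
    n_res: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
    start_resseq: int = 1,
    chain_id: str = "A",
) -> Structure:
    """Cα-only ideal α-helix of ALA residues with author numbering."""
    pts = helix_coords(n_res, rise, twist, radius)
    chain = ca_chain(pts, "A" * n_res, chain_id=chain_id, start_resseq=start_resseq)
    return Structure(name=f"helix{n_res}", chains=[chain])


def _coil_line(n: int, start: np.ndarray, direction: np.ndarray, spacing: float = 3.8) -> np.ndarray:
    """Straight Cα trace: d(i,i+3) = 3·spacing = 11.4 Å, never helical."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return np.asarray(start, dtype=float) + spacing * np.arange(n)[:, None] * d


def gen_linker_protein(
    pre_len: int,
    linker_len: int,
    interrupt: str = "none",       # none | PxP | GRGG
    interrupt_pos: int | None = None,  # 1-based position within the linker
    seed: int = 0,
    chain_id: str = "A",
    start_resseq: int = 1,
    suffix_len: int = 6,
) -> tuple[Structure, str, LinkerReport]:
    """Single-chain fixture: coil prefix, REG anchor, helical linker with an
    optional interruption, coil suffix — plus the ground-truth report.

    The helical geometry runs from the REG anchor through the interruption
    motif's last residue (a Pro-X-Pro block at linker position k leaves k−1
    helical residues before it); everything after is an extended coil. With
    ``linker_len == 0`` the chain ends at the anchor (termination chain_end).
    Sequence letters outside REG and the interruption are drawn from an
    alphabet that cannot form spurious motifs.
    """
    if linker_len < 0:
        raise ValueError("linker_len must be ≥0")
    rng = np.random.default_rng(seed)

    motif_txt = ""
    if interrupt == "none":
        k = None
        helical_len = linker_len
    elif interrupt in ("PxP", "GRGG"):
        if interrupt_pos is None:
            raise ValueError(f"interrupt={interrupt!r} requires interrupt_pos")
        k = interrupt_pos
        motif_len = 3 if interrupt == "PxP" else 4
        if k < 1 or k + motif_len - 1 > linker_len:
            raise ValueError(
                f"interruption at linker position {k} (length {motif_len}) "
                f"does not fit a {linker_len}-residue linker"
            )
        helical_len = k - 1
        if interrupt == "PxP":
            x = rng.choice(list(SAFE_ALPHABET))
            motif_txt = f"P{x}P"
        else:
            motif_txt = "GRGG"
    else:
        raise ValueError(f"unknown interrupt kind {interrupt!r}")

    def draw(n: int) -> str:
        return "".join(rng.choice(list(SAFE_ALPHABET), size=n)) if n else ""

    linker_seq = list(draw(linker_len))
    if k is not None:
        linker_seq[k - 1 : k - 1 + len(motif_txt)] = list(motif_txt)
    suffix = draw(suffix_len) if linker_len > 0 else ""
    sequence = draw(pre_len) + "REG" + "".join(linker_seq) + suffix

    # geometry: coil prefix well apart, helix over REG + linker up to (and
    # including) the interruption motif, coil tail after
    helix_n = 3 + (helical_len if k is None else helical_len + len(motif_txt))
    helix_pts = helix_coords(helix_n)
    prefix_pts = _coil_line(
        pre_len, start=np.array([-12.0 - 3.8 * pre_len, 0.0, -12.0]),
        direction=np.array([1.0, 0.0, 0.0]),
    ) if pre_len else np.zeros((0, 3))
    tail_n = len(sequence) - pre_len - helix_n
    tail_pts = _coil_line(
        tail_n, start=np.array([12.0, 0.0, helix_pts[-1, 2] + 12.0]),
        direction=np.array([1.0, 0.0, 0.3]),
    ) if tail_n > 0 else np.zeros((0, 3))
    coords = np.vstack([prefix_pts, helix_pts, tail_pts])

    chain = ca_chain(coords, sequence, chain_id=chain_id, start_resseq=start_resseq)
    structure = Structure(name="synthetic_linker_protein", chains=[chain])

    anchor = MotifHit("REG", pre_len + 1, "REG")
    linker_start_idx = pre_len + 3  # 0-based index of the first linker residue
    if linker_len == 0:
        truth = LinkerReport(
            anchor=anchor, linker_start_resseq=None, linker_end_resseq=None,
            length=0, termination=Termination.CHAIN_END, chain_id=chain_id,
        )
    else:
        true_len = helical_len if k is not None else linker_len
        if k is not None:
            term = (
                Termination.PROLINE_INTERRUPTION
                if interrupt == "PxP"
                else Termination.GLY_RICH_INTERRUPTION
            )
        else:
            term = Termination.HELIX_BREAK
        truth = LinkerReport(
            anchor=anchor,
            linker_start_resseq=start_resseq + linker_start_idx if true_len else None,
            linker_end_resseq=(
                start_resseq + linker_start_idx + true_len - 1 if true_len else None
            ),
            length=true_len,
            termination=term,
            chain_id=chain_id,
        )
    return structure, sequence, truth


def gen_trajectory(
    ref: Structure,
    sigma_per_atom: float | np.ndarray,
    n_frames: int,
    dt_ns: float = 1.0,
    seed: int = 0,
    t0_ns: float = 0.0,
) -> Trajectory:
    """Reference-jittered trajectory: frame t = ref + i.i.d. N(0, σᵢ²) per
    coordinate; per-atom RMSF converges to √3·σᵢ."""
    if n_frames < 2:
        raise ValueError("n_frames must be ≥2")
    base = ref.coords()
    n_atoms = len(base)
    sigma = np.broadcast_to(np.asarray(sigma_per_atom, dtype=float), (n_atoms,))
    if np.any(sigma < 0):
        raise ValueError("sigma must be ≥0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(n_frames, n_atoms, 3)) * sigma[None, :, None]
    times = t0_ns + dt_ns * np.arange(n_frames)
    return Trajectory(frames=base[None] + noise, times=times, reference=ref)


def gen_mm_dataset(
    kcat: float,
    km: float,
    e0: float,
    s_grid,
    cv_noise: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> KineticsDataset:
    """Michaelis–Menten initial rates with multiplicative Gaussian noise,
    v = kcat·E0·S/(Km+S) · (1 + ε), ε ~ N(0, cv²), truncated at v ≥ 0."""
    if min(kcat, km, e0) <= 0:
        raise ValueError("kcat, Km and E0 must be positive")
    if cv_noise < 0:
        raise ValueError("cv_noise must be ≥0")
    s = np.asarray(s_grid, dtype=float)
    v = michaelis_menten(s, kcat, km, e0)
    if cv_noise > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, cv_noise, size=len(s)))
    v = np.maximum(v, 0.0)
    return KineticsDataset(substrate=s, rates=v, enzyme_conc=e0, label=label)


def gen_alignment(
    n_seqs: int,
    length: int,
    planted_motifs: list[tuple[str, int]] | None = None,
    sub_rate: float = 0.0,
    seed: int = 0,
    mutate_motifs: bool = False,
) -> Alignment:
    """Alignment with motifs planted at fixed 1-based columns of a random
    consensus; every row is an i.i.d. mutated copy (substitution to a
    uniformly random residue at ``sub_rate``, motif columns protected unless
    ``mutate_motifs``)."""
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be in [0, 1]")
    planted_motifs = planted_motifs or []
    rng = np.random.default_rng(seed)
    from .evolution import AMINO_ACIDS

    consensus = list(rng.choice(list(SAFE_ALPHABET), size=length))
    protected = np.zeros(length, dtype=bool)
    for motif, pos in planted_motifs:
        lo = pos - 1
        if lo < 0 or lo + len(motif) > length:
            raise ValueError(f"motif {motif!r} at column {pos} does not fit length {length}")
        if protected[lo : lo + len(motif)].any():
            raise ValueError("planted motifs overlap")
        consensus[lo : lo + len(motif)] = list(motif)
        protected[lo : lo + len(motif)] = True

    aas = list(AMINO_ACIDS)
    rows: list[str] = []
    for _ in range(n_seqs):
        row = list(consensus)
        mutate = rng.random(length) < sub_rate
        if not mutate_motifs:
            mutate &= ~protected
        for j in np.nonzero(mutate)[0]:
            row[j] = aas[rng.integers(20)]
        rows.append("".join(row))
    ids = [f"seq{i + 1}" for i in range(n_seqs)]
    return Alignment(ids=ids, rows=rows)
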