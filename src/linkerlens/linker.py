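"""Helix assignment, linker-interruption motif scanning and α-linker delimitation.

Bacterial exopolyphosphatases (PPX) connect their N-terminal catalytic domains
to the C-terminal domains through a single interdomain α-helix (the α-linker)
that begins immediately after a conserved Arg-Glu-Gly (REG) tripeptide. Its
length varies across species — ≈20 residues in Deinococcus versus ≈10 in
Thermales, where helix-breaking Pro-X-Pro or glycine-rich (GRGG-like) motifs
cut the helix short — and is the central structural variable this package
quantifies.

Helices are assigned from Cα geometry alone (P-SEA style): residue i is
flagged helical when d(Cα_i, Cα_{i+3}) ∈ [4.5, 5.9] Å and
d(Cα_i, Cα_{i+4}) ∈ [5.5, 6.9] Å; a run of ≥5 flagged residues plus the four
residues that complete the last flagged i..i+4 window forms a helix span.
An ideal α-helix (rise 1.5 Å, twist 100°, radius 2.3 Å) gives
d(i,i+3) = 5.05 Å and d(i,i+4) = 6.20 Å, comfortably inside both windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .structio import Chain

__all__ = [
    "HelixSpan",
    "MotifHit",
    "LinkerReport",
    "Termination",
    "assign_helices",
    "scan_motifs",
    "extract_linker",
    "HELIX_D13_WINDOW",
    "HELIX_D14_WINDOW",
]

HELIX_D13_WINDOW = (4.5, 5.9)  # Å, Cα(i)..Cα(i+3)
HELIX_D14_WINDOW = (5.5, 6.9)  # Å, Cα(i)..Cα(i+4)
MIN_HELIX_RUN = 5


class Termination(str, Enum):
    HELIX_BREAK = "helix_break"
    PROLINE_INTERRUPTION = "proline_interruption"
    GLY_RICH_INTERRUPTION = "gly_rich_interruption"
    CHAIN_END = "chain_end"


@dataclass(frozen=True)
class HelixSpan:
    chain_id: str
    start_resseq: int
    end_resseq: int
    start_index: int  # 0-based residue index within the chain
    end_index: int    # inclusive

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str  # REG | PxP | GLY_RICH
    position: int    # 1-based index of the first matched residue
    matched_text: str


@dataclass(frozen=True)
class LinkerReport:
    anchor: MotifHit
    linker_start_resseq: int | None
    linker_end_resseq: int | None
    length: int
    termination: Termination
    chain_id: str = ""

    def to_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "anchor_position": self.anchor.position,
            "anchor_text": self.anchor.matched_text,
            "linker_start_resseq": self.linker_start_resseq,
            "linker_end_resseq": self.linker_end_resseq,
            "length": self.length,
            "termination": self.termination.value,
        }


def assign_helices(chain: Chain) -> list[HelixSpan]:
    """Assign α-helix spans from Cα geometry.

    Returns maximal, non-overlapping spans sorted by start. Residues without
    a Cα atom are treated as non-helical (with a warning).
    """
    residues = chain.protein_residues()
    if len(residues) < MIN_HELIX_RUN:
        raise ValueError(f"chain {chain.id!r}: need ≥{MIN_HELIX_RUN} residues with Cα")

    ca = np.full((len(residues), 3), np.nan)
    for i, res in enumerate(residues):
        atom = res.ca
        if atom is None:
            warnings.warn(
                f"chain {chain.id!r} residue {res.resname}{res.resseq}: no Cα; "
                "treated as non-helical", stacklevel=2,
            )
        else:
            ca[i] = atom.coords

    n = len(residues)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        window = ca[i : i + 5]
        if np.any(np.isnan(window)):
            continue
        d13 = float(np.linalg.norm(ca[i + 3] - ca[i]))
        d14 = float(np.linalg.norm(ca[i + 4] - ca[i]))
        if HELIX_D13_WINDOW[0] <= d13 <= HELIX_D13_WINDOW[1] and (
            HELIX_D14_WINDOW[0] <= d14 <= HELIX_D14_WINDOW[1]
        ):
            flagged[i] = True

    spans: list[HelixSpan] = []
    i = 0
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1]:
            j += 1
        run_len = j - i + 1
        if run_len >= MIN_HELIX_RUN:
            end = min(j + 4, n - 1)  # complete the last flagged i..i+4 window
            spans.append(
                HelixSpan(
                    chain_id=chain.id,
                    start_resseq=residues[i].resseq,
                    end_resseq=residues[end].resseq,
                    start_index=i,
                    end_index=end,
                )
            )
        i = j + 1
    return spans


def scan_motifs(sequence: str) -> list[MotifHit]:
    """Scan a 1-letter sequence for REG, Pro-X-Pro and glycine-rich motifs.

    REG is an exact tripeptide match; PxP matches proline, any residue,
    proline; GLY_RICH reports any 4-residue window containing ≥3 glycines
    (the GRGG pattern and its relatives), at the window start. Overlapping
    hits are all reported; positions are 1-based.
    """
    seq = sequence.upper()
    if not all("A" <= ch <= "Z" for ch in seq):
        bad = next(ch for ch in seq if not ("A" <= ch <= "Z"))
        raise ValueError(f"sequence contains non-letter character {bad!r}")

    hits: list[MotifHit] = []
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if tri == "REG":
            hits.append(MotifHit("REG", i + 1, tri))
        if tri[0] == "P" and tri[2] == "P":
            hits.append(MotifHit("PxP", i + 1, tri))
    for i in range(len(seq) - 3):
        window = seq[i : i + 4]
        if window.count("G") >= 3:
            hits.append(MotifHit("GLY_RICH", i + 1, window))
    hits.sort(key=lambda h: (h.position, h.pattern_id))
    return hits


def _choose_anchor(
    reg_hits: list[MotifHit], helices: list[HelixSpan], chain: Chain
) -> MotifHit:
    """Pick the REG hit whose downstream helix overlap is largest; ties go to
    the smallest sequence position."""
    if len(reg_hits) == 1:
        return reg_hits[0]
    residues = chain.protein_residues()

    def downstream_overlap(hit: MotifHit) -> int:
        start_idx = hit.position + 2  # 0-based index of residue after REG
        best = 0
        for span in helices:
            if span.end_index >= start_idx:
                best = max(best, span.end_index - max(span.start_index, start_idx) + 1)
        return best if start_idx < len(residues) else 0

    return max(reg_hits, key=lambda h: (downstream_overlap(h), -h.position))


def extract_linker(
    chain: Chain,
    helices: list[HelixSpan] | None = None,
    sequence: str | None = None,
    include_anchor: bool = False,
) -> LinkerReport:
    """Delimit the interdomain α-linker anchored at the conserved REG motif.

    The linker is the helical stretch whose first residue immediately follows
    the REG anchor (or the nearest helix starting within 3 residues
    downstream), truncated at the first Pro-X-Pro or glycine-rich hit inside
    it. The REG residues themselves are not counted in the length unless
    ``include_anchor`` — the anchored-start convention makes a Pro-X-Pro
    block at the 11th position after REG yield a 10-residue linker.
    """
    residues = chain.protein_residues()
    seq = sequence if sequence is not None else chain.sequence()
    if len(seq) != len(residues):
        raise ValueError(
            f"sequence length {len(seq)} does not match chain residue count {len(residues)}"
        )
    hits = scan_motifs(seq)
    reg_hits = [h for h in hits if h.pattern_id == "REG"]
    if not reg_hits:
        raise ValueError("anchor not found: no REG motif in sequence")
    if helices is None:
        helices = assign_helices(chain)
    anchor = _choose_anchor(reg_hits, helices, chain)

    anchor_end_idx = anchor.position + 1  # 0-based index of the G of REG
    start_idx = anchor_end_idx + 1
    if start_idx >= len(residues):
        return LinkerReport(
            anchor=anchor, linker_start_resseq=None, linker_end_resseq=None,
            length=0, termination=Termination.CHAIN_END, chain_id=chain.id,
        )

    # the helix containing start_idx, else the nearest one starting within 3
    # residues downstream
    span = next(
        (s for s in helices if s.start_index <= start_idx <= s.end_index), None
    )
    if span is not None:
        lstart, lend = start_idx, span.end_index
    else:
        candidates = [
            s for s in helices if start_idx < s.start_index <= start_idx + 3
        ]
        if not candidates:
            return LinkerReport(
                anchor=anchor, linker_start_resseq=None, linker_end_resseq=None,
                length=0, termination=Termination.HELIX_BREAK, chain_id=chain.id,
            )
        span = min(candidates, key=lambda s: s.start_index)
        lstart, lend = span.start_index, span.end_index

    if include_anchor:
        lstart = anchor.position - 1  # count from the R of REG

    # truncate at the first interrupting motif inside the span
    termination = (
        Termination.CHAIN_END if lend == len(residues) - 1 else Termination.HELIX_BREAK
    )
    for hit in hits:
        if hit.pattern_id not in ("PxP", "GLY_RICH"):
            continue
        hit_idx = hit.position - 1
        if lstart <= hit_idx <= lend:
            lend = hit_idx - 1
            termination = (
                Termination.PROLINE_INTERRUPTION
                if hit.pattern_id == "PxP"
                else Termination.GLY_RICH_INTERRUPTION
            )
            break

    if lend < lstart:
        return LinkerReport(
            anchor=anchor, linker_start_resseq=None, linker_end_resseq=None,
            length=0, termination=termination, chain_id=chain.id,
        )
    return LinkerReport(
        anchor=anchor,
        linker_start_resseq=residues[lstart].resseq,
        linker_end_resseq=residues[lend].resseq,
        length=lend - lstart + 1,
        termination=termination,
        chain_id=chain.id,
    )
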