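"""Coordinate data model, PDB/FASTA I/O and atom selection.

The hierarchy is Structure -> Chain -> Residue -> Atom with author residue
numbering (the numbering printed in PDB columns 23-26), so residue ranges
like Ala300-Ala319 resolve to exactly the residues a structural biologist
would count (20, inclusive).

The PDB reader implements the fixed-column dialect (ATOM/HETATM, optional
MODEL/ENDMDL) with explicit alternate-location resolution: for each
(chain, resseq, icode, atom name) the conformer with the highest occupancy
is kept; ties go to the alphabetically first altloc identifier.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AtomSelection",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "resolve_selection",
    "read_fasta",
    "write_fasta",
    "PdbParseError",
    "ELEMENT_MASSES",
]

# IUPAC 2021 standard atomic weights (Da), conventional values.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "MN": 54.938, "CA": 40.078, "NA": 22.990, "K": 39.098,
    "CL": 35.45, "F": 18.998, "BR": 79.904, "I": 126.904, "CU": 63.546,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PdbParseError(ValueError):
    """Raised when a fixed-column PDB record cannot be parsed."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        self.element = self.element.strip().upper()

    @property
    def mass(self) -> float:
        m = ELEMENT_MASSES.get(self.element)
        if m is None:
            warnings.warn(
                f"unknown element {self.element!r} for atom {self.name!r}; "
                "assuming carbon mass", stacklevel=2,
            )
            return ELEMENT_MASSES["C"]
        return m

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    resname: str
    resseq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.id) != 1:
            raise ValueError(f"chain id must be a single character, got {self.id!r}")

    def sequence(self) -> str:
        """One-letter sequence over amino-acid residues, in chain order."""
        return "".join(r.one_letter for r in self.residues if not _is_het_residue(r))

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not _is_het_residue(r)]


@dataclass
class Structure:
    name: str
    chains: list[Chain] = field(default_factory=list)
    model_id: int = 1

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.name!r}")

    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for r in c.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        ats = self.atoms()
        if not ats:
            return np.zeros((0, 3))
        return np.vstack([a.coords for a in ats])


def _is_het_residue(res: Residue) -> bool:
    return bool(res.atoms) and all(a.is_hetatm for a in res.atoms)


@dataclass
class AtomSelection:
    """Declarative atom selection: a chain, an optional residue range or set,
    and an atom-level filter (`all`, `heavy`, or `ca`)."""

    chain_id: str
    resseq_range: tuple[int, int] | None = None  # inclusive
    resseq_set: frozenset[int] | None = None
    atom_filter: Literal["all", "heavy", "ca"] = "all"
    include_het: bool = False

    def __post_init__(self) -> None:
        if self.resseq_range is not None and self.resseq_set is not None:
            raise ValueError("give resseq_range or resseq_set, not both")
        if self.atom_filter not in ("all", "heavy", "ca"):
            raise ValueError(f"unknown atom filter {self.atom_filter!r}")


def resolve_selection(structure: Structure, sel: AtomSelection) -> list[Atom]:
    """Resolve a selection to an ordered atom list (chain order preserved).

    HETATM residues (ligands, ions, waters) are excluded unless
    ``sel.include_het``. An empty result is legal; an unknown chain is not.
    """
    chain = structure.chain(sel.chain_id)  # KeyError if absent
    out: list[Atom] = []
    for res in chain.residues:
        if not sel.include_het and _is_het_residue(res):
            continue
        if sel.resseq_range is not None:
            lo, hi = sel.resseq_range
            if not (lo <= res.resseq <= hi):
                continue
        if sel.resseq_set is not None and res.resseq not in sel.resseq_set:
            continue
        for atom in res.atoms:
            if sel.atom_filter == "heavy" and not atom.is_heavy:
                continue
            if sel.atom_filter == "ca" and atom.name != "CA":
                continue
            out.append(atom)
    return out


# ---------------------------------------------------------------------------
# PDB fixed-column I/O

def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    # two-letter elements keep their full symbol when it is a known element
    head = "".join(ch for ch in name if ch.isalpha())
    if len(head) >= 2 and head[:2].upper() in ELEMENT_MASSES and head[:2].upper() not in (
        "CA", "CD", "CE", "CG", "CB", "NA", "ND", "NE", "NZ", "OD", "OE", "OG",
        "SD", "SG", "HA", "HB",
    ):
        return head[:2].upper()
    return head[0].upper() if head else ""


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return {
            "record": line[0:6].strip(),
            "name": line[12:16].strip(),
            "altloc": line[16:17].strip(),
            "resname": line[17:20].strip(),
            "chain_id": line[21:22],
            "resseq": int(line[22:26]),
            "icode": line[26:27].strip(),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occupancy": float(line[54:60]) if line[54:60].strip() else 1.0,
            "bfactor": float(line[60:66]) if line[60:66].strip() else 0.0,
            "element": line[76:78].strip().upper() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc


def read_pdb_models(stream) -> list[Structure]:
    """Read all models from a PDB text stream; one Structure per model.

    Alternate locations are resolved per atom site: highest occupancy wins,
    ties go to the alphabetically first altloc.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    models: list[Structure] = []
    current_rows: list[dict] = []
    current_model_id = 1
    saw_model_record = False
    name = getattr(stream, "name", "pdb")

    def _flush() -> None:
        if current_rows:
            models.append(_build_structure(current_rows, name, current_model_id))

    for lineno, line in enumerate(stream, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current_rows:
                _flush()
                current_rows = []
            saw_model_record = True
            try:
                current_model_id = int(line[10:14])
            except (ValueError, IndexError):
                current_model_id = len(models) + 1
        elif rec == "ENDMDL":
            _flush()
            current_rows = []
            current_model_id = len(models) + 1
        elif rec in ("ATOM", "HETATM"):
            current_rows.append(_parse_atom_line(line, lineno))
        # TER / REMARK / END and anything else: ignored here
    _flush()
    if not models:
        raise PdbParseError("no ATOM/HETATM records found (empty or non-PDB input)")
    if not saw_model_record and len(models) == 1:
        models[0].model_id = 1
    return models


def read_pdb(stream, model: int = 1) -> Structure:
    """Read one model (the first by default) from a PDB text stream."""
    models = read_pdb_models(stream)
    for m in models:
        if m.model_id == model:
            return m
    if 1 <= model <= len(models):
        return models[model - 1]
    raise PdbParseError(f"model {model} not present ({len(models)} model(s) read)")


def _build_structure(rows: list[dict], name: str, model_id: int) -> Structure:
    # altloc resolution: key = full atom site identity
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for row in rows:
        key = (row["chain_id"], row["resseq"], row["icode"], row["name"])
        prev = best.get(key)
        if prev is None:
            best[key] = row
            order.append(key)
        else:
            if (row["occupancy"], _altloc_rank(row["altloc"])) > (
                prev["occupancy"], _altloc_rank(prev["altloc"])
            ):
                best[key] = row

    struct = Structure(name=name, model_id=model_id)
    chain_map: dict[str, Chain] = {}
    res_map: dict[tuple, Residue] = {}
    for key in order:
        row = best[key]
        cid = row["chain_id"]
        if cid not in chain_map:
            chain_map[cid] = Chain(id=cid)
            struct.chains.append(chain_map[cid])
        rkey = (cid, row["resseq"], row["icode"])
        if rkey not in res_map:
            res_map[rkey] = Residue(
                resname=row["resname"], resseq=row["resseq"], icode=row["icode"]
            )
            chain_map[cid].residues.append(res_map[rkey])
        element = row["element"] or _infer_element(row["name"])
        res_map[rkey].atoms.append(
            Atom(
                name=row["name"],
                element=element,
                coords=np.array([row["x"], row["y"], row["z"]]),
                occupancy=row["occupancy"],
                bfactor=row["bfactor"],
                is_hetatm=row["record"] == "HETATM",
            )
        )
    return struct


def _altloc_rank(altloc: str) -> int:
    # higher = preferred at equal occupancy: 'A' beats 'B' beats ... beats ''
    return 0 if altloc == "" else ord("Z") - ord(altloc) + 1


def _format_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: 1-2 char element symbols start in column 13
    # only when the name is 4 chars; otherwise column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"[:4]


def write_pdb(structures: Structure | Sequence[Structure], times_ns=None) -> str:
    """Serialize one or more models to fixed-column PDB text.

    With multiple models, MODEL/ENDMDL bracketing is emitted; ``times_ns``
    optionally adds one ``REMARK   6 TIME_NS`` line per model so trajectory
    readers can recover frame times.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    lines: list[str] = []
    for i, struct in enumerate(structures):
        if multi:
            lines.append(f"MODEL     {i + 1:>4}")
        if times_ns is not None:
            lines.append(f"REMARK   6 TIME_NS {float(times_ns[i]):.6f}")
        serial = 1
        for chain in struct.chains:
            if len(chain.id) != 1:
                raise ValueError(f"chain id {chain.id!r} is not a single character")
            for res in chain.residues:
                for atom in res.atoms:
                    record = "HETATM" if atom.is_hetatm else "ATOM  "
                    x, y, z = atom.coords
                    lines.append(
                        f"{record}{serial % 100000:>5} "
                        f"{_format_atom_name(atom.name, atom.element)}"
                        f"{'':1}{res.resname:<3} {chain.id}"
                        f"{res.resseq:>4}{res.icode or ' ':1}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                        f"          {atom.element:>2}"
                    )
                    serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(stream) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA text; whitespace in sequences is dropped."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[tuple[str, str]] = []
    header: str | None = None
    parts: list[str] = []
    for line in stream:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(parts)))
            header = line[1:].split()[0] if len(line) > 1 else ""
            parts = []
        elif line.strip():
            if header is None:
                raise ValueError("FASTA sequence data before any '>' header")
            parts.append(line.strip())
    if header is not None:
        records.append((header, "".join(parts)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], width: int = 60) -> str:
    out: list[str] = []
    for rid, seq in records:
        out.append(f">{rid}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    return "\n".join(out) + "\n"
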