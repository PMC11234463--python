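"""Published reference values used as analysis inputs.

These are the printed study values for bacterial exopolyphosphatases:
steady-state kinetic constants of the Deinococcus radiodurans enzyme (DrPPX)
and its engineered variants, and the crystallographic α-linker residue
ranges of the PPX homologs being compared. They serve as fixture inputs for
the efficiency arithmetic, the variant-ordering correlations and the
synthetic structural fixtures; nothing here is a computed output.
"""

from __future__ import annotations

__all__ = [
    "VARIANT_KINETICS",
    "LINKER_RANGES",
    "WT_KCAT",
    "WT_KM",
    "LINKER_VARIANT_SET",
]

# variant -> (kcat s⁻¹, Km µM, printed kcat/Km µM⁻¹·s⁻¹)
VARIANT_KINETICS: dict[str, tuple[float, float, float]] = {
    "DrPPX(WT)": (37.95, 16.68, 2.28),
    "N11A": (15.61, 20.98, 0.74),
    "S12A": (13.37, 74.86, 0.18),
    "H14A": (16.04, 44.22, 0.36),
    "K35A": (18.20, 64.99, 0.28),
    "S141A": (24.58, 25.58, 0.96),
    "R271A": (9.95, 79.44, 0.13),
    "D7A": (1.75, 35.10, 0.05),
    "E114A": (2.11, 46.17, 0.05),
    "D136A": (4.53, 44.36, 0.10),
    "E143A": (3.64, 84.23, 0.04),
    "NTD": (17.08, 109.1, 0.16),
    "+7AA": (16.36, 42.04, 0.39),
    "-5AA": (146.0, 12.4, 11.77),
    "-8AA": (277.7, 5.74, 48.38),
    "SL/PP": (49.8, 14.89, 3.34),
    "VQ/PP": (123.3, 11.86, 10.40),
    "LA/PP": (196.7, 4.96, 39.66),
}

WT_KCAT, WT_KM = VARIANT_KINETICS["DrPPX(WT)"][:2]

# homolog -> (first residue, last residue) of the α-linker, author numbering
LINKER_RANGES: dict[str, tuple[int, int]] = {
    "DrPPX": (300, 319),  # Ala300–Ala319, 20 residues
    "AtPPX": (298, 306),  # Gly298–Ser306, 9 residues
    "EcPPX": (296, 310),  # Ala296–Lys310, 15 residues
    "AbPPX": (296, 310),  # 15 residues
    "KpPPX": (296, 307),  # Ala296–Gly307, 12 residues
    "HpPPX": (285, 296),  # Gly285–Leu296, 12 residues
}

# DrPPX α-linker-length variant set: (variant, linker length in residues)
# WT linker is 20; −5AA/−8AA delete 5/8 residues; the double-proline variants
# interrupt the helix at positions 18 (SL/PP), 14 (VQ/PP) and 11 (LA/PP)
# counted from the REG anchor (substituted residue pairs 317/318, 313/314,
# 310/311 in a linker spanning residues 300–319).
LINKER_VARIANT_SET: list[tuple[str, int]] = [
    ("DrPPX(WT)", 20),
    ("-5AA", 15),
    ("-8AA", 12),
    ("SL/PP", 17),
    ("VQ/PP", 13),
    ("LA/PP", 10),
]
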