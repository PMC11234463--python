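#!/usr/bin/env python
"""Buried dimer interface area as a function of chain packing.

Verifies the Shrake–Rupley surface against the analytic isolated-atom sphere,
then sweeps the axis separation of a packed two-helix toy dimer to show the
monotone decay of the ½ΔSASA buried area — the quantity that distinguishes
the loose long-linker Deinococcus dimer (≈1136 Å² reported from its crystal
structure) from the compact short-linker dimers. Writes
results/interfaces.tsv.

To reproduce the crystal-dimer number itself, point the same call at a local
copy of the deposited structure:

    from linkerlens.structio import read_pdb, AtomSelection, resolve_selection
    from linkerlens.interface import interface_area
    s = read_pdb(open("8jgo.pdb").read())
    a = resolve_selection(s, AtomSelection("A", atom_filter="heavy"))
    b = resolve_selection(s, AtomSelection("B", atom_filter="heavy"))
    print(interface_area(a, b).area)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from linkerlens.interface import interface_area, sasa
from linkerlens.structio import Atom
from linkerlens.synthdata import helix_coords

OUT = Path(__file__).resolve().parent.parent / "results"


def carbon_helix(n, dx=0.0):
    return [Atom("C", "C", p + np.array([dx, 0.0, 0.0])) for p in helix_coords(n)]


def main() -> None:
    single = sasa([Atom("C", "C", [0.0, 0.0, 0.0])]).total
    print(f"isolated carbon SASA: {single:.2f} Å² (analytic 4π(1.70+1.4)² = 120.76)")

    rows = []
    reference = carbon_helix(20)
    for sep in (6.0, 8.0, 10.0, 14.0, 20.0, 30.0, 50.0):
        res = interface_area(reference, carbon_helix(20, dx=sep))
        rows.append({"axis_separation_A": sep,
                     "buried_area_A2": round(res.area, 1),
                     "sasa_AB_A2": round(res.sasa_AB, 1)})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "interfaces.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    assert df.buried_area_A2.is_monotonic_decreasing
    print(
        "\nBuried interface decays monotonically with separation and is zero "
        "once the probe-inflated surfaces no longer touch — looser packing, "
        "smaller interface."
    )


if __name__ == "__main__":
    main()
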