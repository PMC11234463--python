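#!/usr/bin/env python
"""Catalytic efficiency across DrPPX variants and fitter validation.

Recomputes kcat/Km for all 18 published DrPPX variants from their printed
constants, then validates the Michaelis–Menten fitter by recovering the
wild-type parameters from 100 seeded synthetic datasets with 5%
multiplicative noise. Writes results/kinetics.tsv and
results/mm_recovery.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from linkerlens.datasets import VARIANT_KINETICS, WT_KCAT, WT_KM
from linkerlens.kinetics import efficiency, fit_mm
from linkerlens.synthdata import gen_mm_dataset

OUT = Path(__file__).resolve().parent.parent / "results"
S_GRID = [1, 2, 5, 10, 20, 50, 100, 200, 400]  # µM
E0 = 0.1  # µM


def main() -> None:
    rows = [
        {"variant": label, "kcat_per_s": kcat, "km_uM": km,
         "efficiency_per_uM_s": round(efficiency(kcat, km), 2),
         "published": printed}
        for label, (kcat, km, printed) in VARIANT_KINETICS.items()
    ]
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "kinetics.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    exact = (table.efficiency_per_uM_s.round(2) - table.published).abs()
    print(f"\nmax |recomputed − published| efficiency: {exact.max():.3f}")

    fits = [
        fit_mm(gen_mm_dataset(WT_KCAT, WT_KM, E0, S_GRID, 0.05, seed=s))
        for s in range(1, 101)
    ]
    kcats = np.array([f.kcat for f in fits])
    kms = np.array([f.km for f in fits])
    recovery = pd.DataFrame([{
        "n_replicates": len(fits),
        "kcat_true": WT_KCAT, "kcat_mean": round(kcats.mean(), 3),
        "kcat_sd": round(kcats.std(ddof=1), 3),
        "km_true": WT_KM, "km_mean": round(kms.mean(), 3),
        "km_sd": round(kms.std(ddof=1), 3),
    }])
    recovery.to_csv(OUT / "mm_recovery.tsv", sep="\t", index=False)
    print(recovery.to_string(index=False))
    print(
        f"\nMean recovered kcat deviates from the generating value by "
        f"{abs(kcats.mean() - WT_KCAT) / WT_KCAT:.2%} under 5% noise."
    )


if __name__ == "__main__":
    main()
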