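#!/usr/bin/env python
"""Linker-region conservation profile and length-vs-efficiency correlation.

Generates a synthetic linker-region alignment in which the REG anchor is
invariant and a Pro-X-Pro block is planted in a thermophile-like subset of
sequences, profiles per-column information content and motif prevalence,
then quantifies the negative relationship between α-linker length and
catalytic efficiency across the DrPPX variant series. Writes
results/conservation.tsv and results/correlations.tsv.
"""

from pathlib import Path

import pandas as pd

from linkerlens.datasets import LINKER_VARIANT_SET, VARIANT_KINETICS
from linkerlens.evolution import (
    Alignment,
    conservation_profile,
    correlate,
    motif_prevalence,
)
from linkerlens.synthdata import gen_alignment

OUT = Path(__file__).resolve().parent.parent / "results"
N_SEQS = 42
WIDTH = 30
REG_COL = 4


def main() -> None:
    # Deinococcus-like block: REG anchor, intact downstream linker columns
    deino = gen_alignment(N_SEQS // 2, WIDTH, [("REG", REG_COL)],
                          sub_rate=0.08, seed=11)
    # Thermales-like block: same anchor, Pro-X-Pro planted 11 columns in
    thermo = gen_alignment(N_SEQS - N_SEQS // 2, WIDTH,
                           [("REG", REG_COL), ("PLP", REG_COL + 3 + 10)],
                           sub_rate=0.08, seed=12)
    aln = Alignment(deino.ids + [f"t{i}" for i in range(thermo.n_seqs)],
                    deino.rows + thermo.rows)

    prof = conservation_profile(aln)
    cols = pd.DataFrame({
        "column": range(1, aln.width + 1),
        "info_bits": prof.info_content.round(3),
        "top_residue": [
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in prof.freqs.argmax(axis=1)
        ],
    })
    OUT.mkdir(exist_ok=True)
    cols.to_csv(OUT / "conservation.tsv", sep="\t", index=False)
    reg_bits = prof.info_content[REG_COL - 1 : REG_COL + 2]
    print(cols.to_string(index=False))
    print(f"\nREG columns carry {reg_bits.round(2)} bits (maximum 4.32).")
    for pattern in ("REG", "PxP"):
        frac, _ = motif_prevalence(aln, pattern)
        print(f"prevalence of {pattern}: {frac:.2f}")

    lengths = [length for _, length in LINKER_VARIANT_SET]
    effs = [VARIANT_KINETICS[v][2] for v, _ in LINKER_VARIANT_SET]
    res = correlate(lengths, effs)
    corr = pd.DataFrame([{
        "pair": "linker_length_vs_efficiency",
        "n": res.n, "slope": round(res.slope, 3),
        "pearson_r": round(res.pearson_r, 3),
        "spearman_rho": round(res.spearman_rho, 3),
    }])
    corr.to_csv(OUT / "correlations.tsv", sep="\t", index=False)
    print(corr.to_string(index=False))
    print(
        "\nCatalytic efficiency falls as the α-linker lengthens "
        f"(Spearman ρ = {res.spearman_rho:.2f} across the variant series)."
    )


if __name__ == "__main__":
    main()
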