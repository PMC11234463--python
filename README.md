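# linkerlens

Bacterial exopolyphosphatases (PPX) hydrolyze inorganic polyphosphate
(polyP) processively from its terminus. Their N-terminal catalytic domains
and C-terminal domains are joined by a single interdomain α-helix — the
**α-linker** — that begins immediately after a conserved Arg-Glu-Gly (REG)
tripeptide. The linker's length varies across species (≈20 residues in
*Deinococcus*, ≈10 in *Thermales*, where helix-breaking Pro-X-Pro or
glycine-rich GRGG motifs cut it short) and sets how tightly the two domain
groups pack: longer linkers give looser dimers with smaller buried
interfaces, more mobile polyP-binding loops, and lower catalytic
efficiency. `linkerlens` implements the full quantitative chain from
structure to kinetics for anyone studying this relationship:

* **α-linker delimitation** from Cα geometry — residue *i* is helical when
  d(Cα*ᵢ*, Cα*ᵢ*₊₃) ∈ [4.5, 5.9] Å and d(Cα*ᵢ*, Cα*ᵢ*₊₄) ∈ [5.5, 6.9] Å —
  anchored at the REG motif and truncated at Pro-X-Pro / glycine-rich hits;
* **buried dimer interface area** by Shrake–Rupley SASA,
  area = (SASA_A + SASA_B − SASA_AB)/2;
* **trajectory statistics**: last-*T* windowing, Kabsch RMSD,
  RMSF*ᵢ* = √⟨|r*ᵢ*(t) − r̄*ᵢ*|²⟩ with per-residue averaging, mass-weighted
  center-of-mass distances, and heavy-atom contact counts at a strict
  < 5 Å cutoff (distinct target atoms, not pairs);
* **Michaelis–Menten kinetics**: initial rates from absorbance traces via a
  phosphate standard curve, multistart nonlinear least-squares fits of
  v = k_cat·E₀·S/(K_m + S), and catalytic efficiency k_cat/K_m (µM⁻¹ s⁻¹);
* **conservation profiling** of aligned linker regions (per-column residue
  frequencies and information content, IC = log₂20 − H) and linker-length vs
  property correlations (OLS, Pearson, Spearman);
* a **seeded synthetic-data module** that emulates every input — ideal
  helices, linker proteins with planted interruptions, jittered
  trajectories with known fluctuation scale, noisy kinetics, motif-planted
  alignments — so the entire pipeline runs and is tested without any
  downloads.

## Worked example

```python
from linkerlens import linker, synthdata
from linkerlens.kinetics import fit_mm, efficiency

# a Deinococcus-style chain: coil, REG anchor, 20-residue helical linker
structure, seq, truth = synthdata.gen_linker_protein(
    pre_len=8, linker_len=20, seed=11, start_resseq=289)
report = linker.extract_linker(structure.chains[0])
print(report.length, report.linker_start_resseq, report.linker_end_resseq)
# 20 300 319   — the 20-residue linker spanning residues 300–319

# block the helix with Pro-X-Pro at the 11th position after REG
structure, seq, _ = synthdata.gen_linker_protein(
    8, 20, "PxP", 11, seed=12)
print(linker.extract_linker(structure.chains[0]).length)
# 10   — the Thermales-style short linker

# fit synthetic wild-type kinetics (kcat 37.95 s⁻¹, Km 16.68 µM, 5% noise)
data = synthdata.gen_mm_dataset(37.95, 16.68, 0.1,
                                [1, 2, 5, 10, 20, 50, 100, 200, 400],
                                cv_noise=0.05, seed=1)
fit = fit_mm(data)
print(round(fit.kcat, 2), round(fit.km, 2), round(fit.efficiency, 2))
# 38.54 17.08 2.26   — parameters recovered within noise

print(round(efficiency(277.7, 5.74), 2))
# 48.38   — catalytic efficiency of the short-linker −8AA variant
```

The numbered drivers under `analysis/` run the full study on synthetic
fixtures and write TSV tables to `results/`:

```bash
python analysis/01_linker_lengths.py        # homolog linker lengths 20/9/15/15/12/12
python analysis/02_interface_burial.py      # buried area vs dimer packing
python analysis/03_trajectory_stats.py      # windowing, RMSF vs √3σ, CoM, contacts
python analysis/04_kinetics.py              # efficiency table + fitter recovery
python analysis/05_conservation_correlation.py  # logo profile + length correlation
```

`pipeline.run_study` drives the same computations from a single YAML config
(see `tests/test_pipeline.py` for a complete example) and writes
`report.json` plus byte-stable TSV tables.

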