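# Methods

## Scope and model

`linkerlens` quantifies one structural variable — the length of the
interdomain α-helical linker (α-linker) in bacterial exopolyphosphatases —
and the properties it co-varies with: buried dimer interface area,
polyP-binding-pocket dynamics, and Michaelis–Menten catalytic efficiency.
Structures are treated as rigid atom hierarchies with author residue
numbering; dynamics enter only through externally supplied (or synthetic)
trajectories; kinetics are steady-state initial rates. Nothing here runs
molecular dynamics, refines crystal structures, predicts structures, or
builds alignments — those stages produce this package's *inputs*.

## α-linker delimitation

Secondary structure is assigned from Cα geometry alone (in the spirit of
P-SEA): residue *i* is flagged helical when d(Cαᵢ, Cαᵢ₊₃) ∈ [4.5, 5.9] Å
**and** d(Cαᵢ, Cαᵢ₊₄) ∈ [5.5, 6.9] Å. A run of ≥5 flagged residues, plus
the four residues completing the last flagged i..i+4 window, forms a helix
span. An ideal α-helix (rise 1.5 Å, twist 100°, radius 2.3 Å) scores
d(i,i+3) = 5.05 Å and d(i,i+4) = 6.20 Å, near the centre of both windows;
an extended chain (3.8 Å Cα spacing) fails at 11.4 Å. A Cα-only criterion
was chosen over hydrogen-bond-based assignment (DSSP) because synthetic and
Cα-only inputs must be assignable, and because only helix/non-helix
distinctions matter here.

The α-linker is the helical stretch whose first residue immediately follows
the conserved REG anchor (or the nearest helix starting within 3 residues
downstream), truncated at the first Pro-X-Pro or glycine-rich hit inside it.
Conventions:

* **Anchor exclusion.** The REG residues are not counted in the linker
  length. This makes a Pro-X-Pro block at the 11th position after REG yield
  a 10-residue linker, matching how the short thermophile linkers are
  counted; `include_anchor=True` flips the convention.
* **Multiple REG hits.** The hit with the largest downstream helix overlap
  wins; ties go to the smallest residue number.
* **Glycine-rich threshold.** ≥3 glycines in any 4-residue window (reported
  at the window start) — GRGG and its single-substitution relatives.
* **Lengths are inclusive residue counts** under author numbering, so the
  span 300–319 counts 20.

## Buried interface area

SASA is Shrake–Rupley with a deterministic golden-angle Fibonacci lattice
(default 960 points per atom — bit-stable across runs, no RNG), probe
1.4 Å, Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; unknown
elements fall back to 1.70 Å with a warning). Hydrogens must be excluded by
the caller; mixing implicit- and explicit-hydrogen conventions silently
shifts areas, so their presence is an error rather than a filter. The
buried interface is ½(SASA_A + SASA_B − SASA_AB), clamped at zero, the
convention used by interface servers. Per-atom areas are summed with
compensated summation so the result is exactly symmetric in chain order.
Because published server numbers depend on an unpublished radii set, crystal
dimer areas recomputed here should be read with a ±15% band.

## Trajectory statistics

* **Windowing** keeps frames with t ≥ t_end − T, both endpoints inclusive:
  a 0–1000 ns run sampled every 1 ns yields 101 frames for T = 100 ns
  (1001 at 0.1 ns), and k independent runs pool to k × that count.
* **RMSD** uses the closed-form Kabsch superposition (SVD with reflection
  guard); collinear references proceed with a warning.
* **RMSF** is computed about the *time-averaged* position after Kabsch
  fitting all frames to frame 1 over the selection (`superpose=False`
  disables the fit). Printed RMSF formulas in the source literature for
  this analysis carry a garbled normalization (a 1/T prefactor over an
  atom-indexed sum); the standard time-average definition is implemented
  rather than a literal reading. Per-residue RMSF is the arithmetic mean of
  member-atom RMSFs.
* **CoM distance** is mass-weighted by default (masses from a fixed
  IUPAC-2021 element table; unknown elements assume carbon with a warning);
  a geometric-centroid flag exists.
* **Contacts** count distinct *target* atoms with at least one source atom
  strictly closer than 5.0 Å — atoms, not pairs, matching how
  domain–domain and polyP–loop contacts are reported. Overlapping
  selections are an error because the quantity is undefined when an atom is
  on both sides.

Trajectories are multi-model PDB (with `REMARK 6 TIME_NS` per frame) or
in-memory arrays; no binary trajectory format is required.

## Kinetics

Initial rates: least-squares slope of absorbance vs time (s) over a window
(default: first 20% of the trace or first 10 points, whichever is larger),
divided by the standard-curve slope (AU per µM Pi); negative slopes clamp
to zero with a warning. The Michaelis–Menten fit parameterizes
(Vmax, Km), minimizes unweighted squared residuals (the common
graphing-software default; a 1/v² weighting flag is available) from a
multistart grid — Vmax ∈ {max v, 2·max v} × Km ∈ S-quartiles, plus a
Lineweaver–Burk linearization seed — keeping the best SSR, ties to the
smaller Km. SDs come from the asymptotic covariance s²(JᵀJ)⁻¹. kcat =
Vmax/E₀ requires the assay enzyme concentration; when only published
constants are available the package reproduces the efficiency arithmetic
kcat/Km (treated as µM⁻¹·s⁻¹ — published tables sometimes print the unit
with the inverse dropped, but the values are ratios) rather than re-fitting
raw traces whose E₀ is given only as a range. Fits where all S lie below
the fitted Km flag Vmax as poorly identified.

## Conservation and correlation

Per-column residue frequencies exclude gaps from the denominator (logo
convention); information content is log₂20 − H in bits, zero for all-gap
columns; no small-sample correction is applied (configurable later if
needed — profiles here are read qualitatively). Motif prevalence applies
the same REG/PxP/glycine-rich scanner to de-gapped rows. Correlations
report OLS slope/intercept, Pearson r (with a two-sided t-test p-value,
reported but not relied on at n = 6) and Spearman ρ.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed) using NumPy's PCG64;
identical calls are bit-identical, and every generator returns its ground
truth:

* `build_helix` / `gen_linker_protein` — Cα-only ideal geometry: enough for
  helix assignment, superposition, RMSF, CoM and contacts. No side chains,
  no real coil geometry (coil segments are straight traces placed clear of
  the helix), and detectability requires ≥6 helical linker residues (the
  5-residue minimum run), so sub-6-residue linkers report as absent.
* `gen_trajectory` — i.i.d. Gaussian jitter of σ per coordinate about a
  fixed reference, so per-atom RMSF → √3·σ analytically. Real MD has
  correlated, anisotropic, slowly-converging fluctuations; passing the
  analytic-limit tests validates the *estimator*, not any biology of a
  specific enzyme.
* `gen_mm_dataset` — exact Michaelis–Menten curves with multiplicative
  Gaussian noise (CV 5% as the study condition), truncated at v ≥ 0. The
  standard recovery fixture uses the published wild-type constants
  (kcat 37.95 s⁻¹, Km 16.68 µM) on the assay grid S = {1, 2, 5, 10, 20,
  50, 100, 200, 400} µM with E₀ = 0.1 µM.
* `gen_alignment` — a random consensus with motifs planted at fixed
  columns and i.i.d. substitution elsewhere; no phylogenetic correlation
  between rows.

Synthetic structural fixtures therefore demonstrate the pipeline's
correctness and its published-value arithmetic; conclusions about real PPX
structures require the deposited coordinates as input.

## Numerical choices and problem sizes

Float summation in SASA totals uses `math.fsum` (order-independent).
Default analysis sizes — 100 kinetic replicates, 5000-frame RMSF
convergence checks, 1001-frame windows, 200 random contact instances — were
chosen so each stage's statistical tolerance (3% on mean kcat, 3% on RMSF)
is comfortably resolved while the full suite runs in seconds. TSV outputs
use fixed float formats (2 decimals for kinetics, 1 for areas, 3 for
distances) so repeated runs are byte-identical.

## Known limitations

* Helix assignment is Cα-geometric; kinked or π-bulged helices may split
  into two spans where hydrogen-bond criteria would not.
* The altloc rule (highest occupancy, ties alphabetical) and model-1
  default follow common practice; deposits analyzed under other conventions
  may differ at the margin.
* PDB output is fixed-column only (no mmCIF), chain ids one character.
* The interface calculation reports area only — no dissociation energetics
  or interface residue classification.
* `fit_mm` assumes a single active enzyme species and no substrate
  inhibition; global fits across variants are out of scope.
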