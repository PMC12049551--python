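# Methods

## Scope and model

`fluorosite` scores protein residues for covalent fluorophore labeling
and residue pairs for FRET assays. The statistical core is a naïve
Bayes ratio: for each structural/sequence parameter with value *s* at a
residue, the parameter score PS(s) = P(s|l)/P(s) compares the value's
frequency among successfully labeled residues (l) with its frequency
over all residues. The prior P(l) is not estimated — published labeling
data reports almost exclusively successes, so the prior is
unidentifiable, and it only rescales the ranking. Selected parameter
scores (one per category, assumed weakly dependent across categories)
combine into the label score LS as their geometric mean. LS is a
comparative figure, not a probability.

## Parameter registry

Twenty-eight per-residue parameters in four categories:

* **SE, solvent exposure (#1–#12)** — relative ASA (Wilke/Tien max-ASA
  normalization, constants hard-coded), absolute and side-chain ASA,
  half-sphere exposure counts at 10 and 13 Å (plane normal to Cα→Cβ;
  glycine gets a virtual Cβ from ideal tetrahedral geometry),
  coordination number, and three surface-burial depths (Cα, Cβ, mean
  over residue atoms). ASA uses an own Shrake–Rupley implementation
  with deterministic golden-spiral dot spheres (default 960 dots,
  probe 1.4 Å) so results are bit-reproducible; the exposed dots double
  as the molecular-surface cloud for the burial depths, which subtract
  the atom's solvent-sphere radius so surface residues score ≈ 0.
* **CS, conservation (#13–#17)** — ConSurf score and grade parsed from
  a grades file (sign convention: negative = conserved), or an offline
  MSA fallback: per-column Shannon entropy, z-scored and signed the
  same way; variant count and cysteine occurrence among homologs come
  from the same alignment.
* **SS, secondary structure (#18–#24)** — own Kabsch–Sander
  assignment: amide H placed along the preceding C=O, electrostatic
  H-bond energy with the −0.5 kcal/mol cutoff, n-turn/bridge patterns
  → 8-state classes reducible to 3-state; plus φ/ψ, segment length,
  boundary distance and a loop flag. An external DSSP file can replace
  the internal assignment; mdtraj's DSSP is used as an independent
  cross-check in tests only.
* **CR, cysteine resemblance (#25–#28)** — amino-acid identity, mass
  and volume deltas vs cysteine (fixed tables), charge class.

Nine of these are canonical named parameters at fixed ids (#1, #4,
#11, #13, #16, #17, #18, #25, #27); the rest are same-category
companions implemented per their registry docstrings and flagged
`interpretation` in the definitions sidecar.

## Training and diagnostics

Numeric parameters are histogrammed on fixed per-parameter bin edges
(declared in the registry); labeled and background histograms always
share edges. Bins with P(s)=0 are excluded (missing, not infinite);
P(s|l)=0 gives PS=0 with a one-count upper bound as its error. Errors
follow Poisson counting statistics, σ_sl = √(P(s|l)/n_l), propagated
into σ_PS = PS·√(σ_sl²/P² + σ_s²/P²).

Diagnostics per parameter: mean-square deviation of PS from 1, Gini
coefficient (rank form, identical to the pairwise mean-absolute-
difference form), and Shannon entropy of the normalized PS divided by
ln(n bins) so H=1 is uninformative. Pairwise parameter correlations use
Pearson (numeric–numeric), one-way intraclass correlation ICC(1)
(categorical–numeric; the between-group mean square uses the standard
Σnᵢ(x̄ᵢ−x̄)²/(k−1) form) and Cramer's V (categorical–categorical). A
parameter set's joined correlation is the 2-norm √(Σ r²) over its six
pairs (an un-squared variant is available behind a flag). Set quality is
measured by a Welch-style t value between labeled and background LS
means, the dynamic range SD(ln LS), and the enhancement slope m from a
least-squares fit of ln(P(LS|l)/P(LS)) against ln LS on geometric bins
[1.5^i, 1.5^{i+1}), i ∈ {−12,…,11}, skipping empty bins. Bootstrap
confidence envelopes resample the labeled records with replacement and
use lower/upper-percentile rules so two replicates give the min/max
envelope exactly.

## Label and FRET scores

LS is the geometric mean of the selected PS values; the default
selection is #11/#13/#18/#25 (one per category, enforced unless
overridden). Out-of-range numeric values clamp to edge bins. The
missing-value policy defaults to "strict" (any missing selected
parameter fails the residue, LS = 0); "reduce" averages the available
ones and records n_used. FS and FSΔ follow the formulas in the README;
the sensitivity factor (1 − 2|½ − E|) peaks at E = 0.5, i.e. inter-dye
distance at the Förster radius. Pair screening keeps pairs with
geometric-mean LS ≥ 1 by default, scores them with the SSM estimator,
then refines the top 300 with the grid AV and re-ranks. Pairs with high
FS in both conformations but FSΔ ≤ 0.05 are reported separately as
negative-control candidates.

## Distance estimators

**Grid accessible volume.** Dye centers are placed on a cubic grid
(default 1.0 Å) around the attachment Cβ. A point is allowed iff (a) no
protein atom is within (atom vdW + largest dye radius) of it, and (b) a
geodesic path of length ≤ linker length connects it to the attachment
through sterically passable cells. Path passability uses half the
linker width measured to atom centers: adding atom vdW there would seal
the covalently attached linker inside its own residue's clearance zone.
For the same reason the attachment atom is excluded from clash tests
and a small seed sphere (max(1.5·spacing, 2 Å)) around the attachment is
always passable — without it, fine grids isolate the seed cell. Geodesic
distances come from Dijkstra on the grid (scikit-image MCP_Geometric).
The mean dye position is the centroid of allowed points; an empty AV is
flagged, not raised.

**Spherical-sector model (SSM).** The AV is approximated by a
spherical sector. With d′ the center of mass of protein atoms within an
effective radius R̃ of the attachment, the mean-position offset is
d = (1 − ¾·R̃/|d′|)·d′ — anti-parallel to d′ whenever |d′| < ¾R̃
(displaced away from the blocking mass), exact in the hemisphere limit
(|d′| = 3R̃/8 ⇒ |d| = 3R̃/8), zero at the root |d′| = ¾R̃ and for
symmetric occlusion (d′ ≈ 0). The effective radius is
R̃ = R + ε + (dye radius + 1.7 Å): ε (default 0.5 Å) is the fluorophore
core correction, and the dye-center clash distance term keeps the sector
model consistent with the grid AV, which stores dye *centers* excluded
within (vdW + dye radius) of atoms. Omitting that term leaves a
systematic shortfall equal to the clash distance (benchmark pair RMSD
3.7 Å vs 2.4 Å with it). The SSM is two to three orders of magnitude
faster than the grid AV and is the screening estimator.

**FRET-averaged distances.** Because FRET efficiency averaging over the
two volumes weights short inter-dye distances more, the mean-position
distance R_MP is converted to the efficiency-averaged distance with
R⟨E⟩ = R_MP + a·exp(−R_MP/b). The constants are calibrated once per
dye pair against the grid-AV oracle (isotropic efficiency average over
the two point clouds, converted back through the Förster relation) and
shipped as defaults; `calibrate_correction` re-fits them for any dye.
Shipped dye presets cover the common pairs with Förster radii 51, 58
and 65 Å plus a generic 50 Å pair; linker length/width and dye radii
are FPS-class values, overridable per dye.

## Synthetic data

All tests and benchmarks run on generated structures; nothing is
downloaded. Peptide fixtures (helix φ=−57°/ψ=−47°, antiparallel sheet,
extended coil) are built by NeRF chain extension with ideal bond
geometry, so the Kabsch–Sander assignment has real hydrogen bonds to
find. Globules place one 5-atom residue (N, Cα, C, O, Cβ, random
orientation) per jittered cubic-lattice site inside a sphere; the
default 5.0 Å spacing is tuned to protein-like packing, giving ~30%
of residues relative ASA < 0.1 (a buried core) and an exposed surface
stratum. Wall and shell fixtures provide half-space blocking and full
enclosure for AV tests. Synthetic label databases sample residues with
probability proportional to planted per-parameter multipliers (uniform
multipliers = null pipeline) and carry a 90% cysteine / 10%
unnatural-amino-acid mutation mix. A synthetic ConSurf-like annotation
generator feeds the conservation parameters offline.

What these fixtures do *not* emulate: real side chains and rotamers,
chain connectivity in globules, correlated parameter structure of real
proteins, and any photophysics. Passing tests therefore demonstrate the
correctness of the estimators and statistics, not field performance on
real structures.

## Benchmark and problem sizes

The distance benchmark uses 10 seeded globules (110 residues), 10
exposed-residue pairs each, and 5 dye variants spanning linker lengths
10–20 Å with dye radii 3–5 Å — 500 pair evaluations, each with both
estimators. The SSM tracks the grid AV at ~1.5–2.4 Å RMSD depending on
seed, within the ±3 Å the two-volume approach itself carries; the
Cβ distance misses the grid mean-position distance by up to ~15 Å at
20 Å linker length, which is why the bare Cβ estimator is only a rough
first look.

## Numerical choices and edge cases

* Golden-spiral dots (no RNG) make SASA deterministic; doubling the
  dot count moves per-residue ASA by < 2%.
* Ranking ties break by (chain, residue number, icode) ascending.
* Residues lacking backbone atoms get secondary structure "?" and NaN
  dihedrals; non-standard residues map to parent amino acids (MSE→MET
  etc.) or are excluded from scoring.
* Log statistics exclude LS = 0 (counted and reported); the enhancement
  slope requires ≥ 2 populated bins and is NaN otherwise.
* All stochastic operations take explicit seeds; fixture generation is
  byte-reproducible.

## Known limitations

* The single-volume AV variant uses the largest dye radius
  (conservative); the three-radius weighted variant is not implemented.
* Two-structure FSΔ matches residues by (chain, number, icode) identity
  only — no sequence alignment between conformations.
* The 28-parameter registry implements companions-by-name where the
  canonical definitions were not fixed; these are flagged
  `interpretation` in the definitions sidecar.
* Grid AV accuracy is limited by the 1.0 Å default spacing (halving it
  moves mean positions by < 0.5 Å on fixtures).
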