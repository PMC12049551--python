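# fluorosite

Systematic selection of protein residues for covalent fluorophore
labeling, and rational design of FRET assays.

Biophysical assays — single-molecule FRET above all — require attaching
organic dyes to specific residues, usually by mutating a surface residue
to cysteine and coupling a maleimide dye. Picking those residues is
traditionally trial and error: a bad site kills expression, labels
poorly, or perturbs function. `fluorosite` ranks every residue of a
structure with a single quantitative metric and extends the ranking to
residue *pairs* for FRET experiments, including fast and accurate
prediction of inter-dye distances.

## The model

For each residue, up to 28 structural/sequence parameters are computed
in four categories: conservation (CS), solvent exposure (SE), secondary
structure (SS) and cysteine resemblance (CR). For a parameter value *s*,
the **parameter score** is the odds ratio

    PS(s) = P(s | labeled) / P(s)

estimated by binning a database of successfully labeled residues against
the background of all residues (a naïve Bayes treatment; the
unknowable prior P(labeled) is deliberately dropped). One parameter per
category — by default mean surface distance (#11), conservation score
(#13), DSSP secondary structure (#18) and amino-acid identity (#25) —
is combined into the **label score**

    LS = (PS₁ · PS₂ · PS₃ · PS₄)^(1/4),

the geometric mean, so LS > 1 marks residues over-represented among
successfully labeled sites. For FRET pairs,

    FS  = √(LSᵢ·LSⱼ) · (1 − 2·|½ − E|)            (one structure)
    FSΔ = √(LSᵢᴬLSᵢᴮ) · √(LSⱼᴬLSⱼᴮ) · |Eᴬ − Eᴮ|   (two conformations)

where E is the predicted FRET efficiency, E = 1/(1 + (R/R₀)⁶).
Inter-dye distances come from three estimators: the bare Cβ–Cβ distance,
a grid-based accessible-volume (AV) simulation, and the fast
**spherical-sector model** (SSM) that approximates the AV mean position
in closed form from the center of mass d′ of the blocking atoms within
linker reach: d = (1 − ¾·R̃/|d′|)·d′. The standard workflow screens all
pairs with the SSM and refines the best 300 with the grid AV.

## Worked example

Score a synthetic test structure with a uniform (PS ≡ 1) trained model,
shipped fixture generators standing in for downloads:

```bash
fluorosite fixtures --kind globule --n-residues 110 --seed 1 -o globule.pdb
fluorosite score globule.pdb --scores trained.json --policy reduce -o run/
```

The `score` command prints a JSON summary such as

```json
{
  "n_residues": 110,
  "n_failed": 0,
  "ls_median": 1.0,
  "ls_mean": 1.0,
  "top10": [{"residue": "A1", "LS": 1.0}, ...]
}
```

With a uniform model every residue's LS is exactly 1 — the null
baseline. Training on a real (or synthetic, `generate_label_database`)
database of labeled residues produces non-uniform PS bins, and the same
command then ranks residues: LS ≈ 2 means the residue's parameter values
are, on geometric average, twice as common among successfully labeled
sites as in the background; LS < 1 flags residues unlikely to label
well. `run/label_scores.pdb` carries LS in the B-factor column for
color-mapping in any structure viewer, and `fluorosite fret` screens
residue pairs and writes FS/FSΔ matrices.

From Python:

```python
import fluorosite as fs

model = fs.read_structure("protein.pdb")
model = fs.preprocess_structure(model, keep_chains=["A"])
table = fs.build_parameter_table(model, annotations={"consurf": "grades.txt"})
trained = fs.ParameterScoreModel.from_json("trained.json")
results = fs.compute_label_score(table, trained)
best = fs.rank_residues(results, top_fraction=0.10)
```

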