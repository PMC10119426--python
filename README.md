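# qsarkit

A 2D/3D-QSAR toolkit for small-molecule activity modelling:

- **chem_io** — SDF (V2000) / MOL2 / XYZ structure readers, activity tables
  (`compound_id,ic50_uM` CSV), the `6 − log10(IC50 µM)` response transform,
  and reproducible train/test splitting.
- **descriptors** — nitrogen counts (NN), one-shot Sanderson
  electronegativity-equalization partial charges with minimum-oxygen-charge
  descriptor (MPCO), principal-axis van der Waals shadow ratios (YZS/YZR),
  and resonance-energy reductions (MREB) over user-supplied density /
  resonance-integral matrices; descriptor-matrix assembly with provenance.
- **hm** — heuristic stepwise multilinear model search (exhaustive best pair,
  greedy forward additions under a pairwise collinearity cap), with R², S²,
  F, per-coefficient t and leave-one-out R²cv, plus the reference
  five-descriptor linear activity equation.
- **gep** — gene-expression-programming symbolic regression over the function
  set `+ − * / Inv Cos Tan`: Karva encoding/decoding, guarded evaluation,
  elite-roulette selection, mutation / one-point / two-point / gene
  recombination and IS / RIS / gene transposition, and an infix parser with a
  documented precedence convention (unary functions bind tighter).
- **comsia** — CoMSIA-style 3D-QSAR: Kabsch template alignment, five Gaussian
  similarity-index fields (steric, electrostatic, hydrophobic, H-bond
  donor/acceptor) on a lattice, PLS1 (NIPALS) with leave-one-out q² and
  optimal-component selection, field contribution percentages, contour masks,
  and OpenDX/CSV grid export.
- **validation** — external validation R²ext (pass iff > 0.5), SEE, F,
  Pearson r, MAE/RMSE.
- **synthetic** — generators for planted-linear descriptor matrices,
  symbolic-regression targets, and aligned toy molecule series with
  field-model activities, plus the packaged 50-compound activity fixture.

## CLI

The console script `qsar` exposes each stage:

```bash
qsar simulate planted-linear --seed 1 --out run/sim
qsar descriptors --structures mols.sdf --provided quantum.csv --out matrix.csv
qsar hm --matrix matrix.csv --activity activity.csv --max-size 5 --out hm.json
qsar gep --matrix matrix.csv --activity activity.csv --config gep.yaml --seed 7 --out gep.json
qsar comsia --structures mols.sdf --activity activity.csv --template 14 \
    --map map.csv --spacing 2.0 --alpha 0.3 --max-comp 10 --out comsia.json
qsar validate --train train_preds.csv --test test_preds.csv --out report.json
qsar run --config pipeline.yaml --seed 1 --out run/
```

Exit codes: 0 success, 2 input error, 3 numerical failure.

## Conventions worth knowing

- IC50 values are micromolar throughout; the response is `6 − log10(IC50)`.
- Shadow ratio: rasterized union of projected vdW discs divided by the
  enclosing rectangle (extents include radii); default resolution 0.05 Å.
- CoMSIA defaults (all configurable): attenuation α = 0.3 Å⁻², grid spacing
  2 Å, margin 4 Å, unit probe weights; steric atom weight `r_vdw³`,
  electrostatic weight = partial charge, hydrophobic/D/A weights from a
  small packaged per-element table.
- Leave-one-out q² references each held-out compound to its training fold's
  mean (a mean-only predictor scores exactly 0); the stepwise R²cv uses the
  conventional overall-mean PRESS/TSS.
- GEP hyperparameter defaults follow common GEP practice (population 500,
  head 10, mutation 0.044, ...) and are all configurable; evaluation guards
  division/Inv singularities and saturates at ±10⁶.
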