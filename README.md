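# gnmhot

Hot-spot residue identification from the high-frequency normal modes of a
Gaussian network model (GNM), with a Gaussian naive Bayes (GNB) classifier
and the classical fluctuation-threshold baselines.

## The problem

Protein–protein interaction *hot spots* are the few interface residues that
contribute most of the binding free energy (conventionally > 2 kcal/mol).
They can be predicted from the *unbound* structure alone, because they tend
to sit in tightly packed regions whose intrinsic dynamics differ from the
rest of the chain. The GNM captures those dynamics cheaply: each residue is
a node at its Cα position, every pair within a cutoff `R_C` is connected by
an identical spring, and the whole model is the Kirchhoff matrix

```
Γ_ij = −1              if i ≠ j and R_ij ≤ R_C
Γ_ij = 0               if i ≠ j and R_ij > R_C
Γ_ii = −Σ_{j≠i} Γ_ij   (the contact degree)
```

i.e. the graph Laplacian of the Cα contact graph. Its eigendecomposition
`Γ = U Λ Uᵀ` yields normal modes; the *fast* modes (largest eigenvalues
`λ`) describe localized fluctuations, and per-residue mean square
fluctuations over a mode subset are

```
MSF_i = c · Σ_k λ_k⁻¹ u_ki² / Σ_k λ_k⁻¹ ,    c = 3 k_B T / γ .
```

`gnmhot` goes one step beyond thresholding MSF: it feeds the raw fast-mode
components themselves — one mode (`single_mode`) or the top *m* modes
(`top_m`), each in a sliding sequence window — into a from-scratch GNB
classifier `ŷ = argmax_y P(y) ∏_i N(x_i; μ_yi, σ_yi²)`, evaluated under
chain-grouped cross-validation and ranked by the F1 measure
`F1 = 2·sen·pre/(sen+pre)`, the right summary for a ~4%-positive dataset.
The MSF-threshold baselines (constant 0.005 and length-scaled 6/N) and an
MSDF (mean square distance fluctuation) ranking score are included for
comparison.

Because curated hot-spot benchmarks require structure downloads and
binding-energy labels, the package ships a synthetic generator: compact
self-avoiding Cα walks with protein-like contact density, plus labels
planted from the chains' own fast-mode MSF and corrupted with flip noise —
a fully reproducible testbed with known ground truth.

## Worked example

```bash
python examples/03_cross_validation_and_grid.py
```

```
6-fold CV at the planted cutoff 7.0 A: sen=0.3232 pre=0.5048 F1=0.3941
(each fold holds out whole chains, so no residue of a test chain
 ever appears in training)

cutoff grid ranked by CV F1:
 rank  cutoff scheme  i_or_m  sw    sen    spe    pre    acc     f1
    1     7.0  top_m       3   1 0.3232 0.9458 0.5048 0.8549 0.3941
    2     6.5  top_m       3   1 0.2073 0.9531 0.4304 0.8442 0.2798
    3     7.5  top_m       3   1 0.1768 0.9541 0.3973 0.8406 0.2447
    4     8.0  top_m       3   1 0.1463 0.9552 0.3582 0.8370 0.2078
    5     6.0  top_m       3   1 0.1402 0.9562 0.3538 0.8370 0.2009
```

The benchmark plants labels on the top-4% MSF residues of each chain at a
7.0 Å cutoff and flips 10% of them. Cross-validated F1 peaks exactly at the
planted cutoff — the grid search recovers the contact scale that generated
the signal — and sen/pre say the classifier recovers about a third of the
true hot spots, with half of its calls correct, far above the ~0.07 F1 a
label permutation achieves. The other examples cover the mode spectrum and
MSF (`01`), feature encoding and the GNB model (`02`), and the threshold
baselines (`04`).

## Command line

A thin CLI wraps the library for shell use:

```bash
gnmhot simulate  --outdir data --n-chains 30 --seed 0      # synthetic benchmark
gnmhot modes     --config config.yaml --outdir out         # eigenvalues, modes, MSF per chain
gnmhot evaluate  --config config.yaml --outdir out         # CV grid search, ranked CSV
gnmhot baselines --config config.yaml --outdir out         # MSF-threshold comparison table
```

Each command writes CSV output plus a `manifest.json` (seed, grids,
version) from which the run is exactly reproducible. The YAML config format
is documented in `gnmhot/cli.py`; users with a real benchmark point
`pdb_dir`/`chain_map` at their own PDB files and `label_file` at a
`chain residue label` text file.

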