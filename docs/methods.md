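# Methods

## Model

The Gaussian network model treats a protein chain as `N` nodes at the Cα
positions, joined by identical harmonic springs for every pair within a
cutoff `R_C`. Fluctuations are assumed isotropic and Gaussian, so the
model is fully specified by the Kirchhoff matrix `Γ` (graph Laplacian of
the contact graph) and the statistical mechanics reduces to linear algebra
on its spectrum `Γ = U Λ Uᵀ`:

* cross-correlations `⟨ΔR_i·ΔR_j⟩ = c [Γ⁺]_ij` with `c = 3 k_B T / γ`,
  where `Γ⁺` is the pseudo-inverse over non-null modes;
* mean square fluctuations over a mode subset `K`:
  `MSF_i = c Σ_{k∈K} λ_k⁻¹ u_ki² / Σ_{k∈K} λ_k⁻¹`;
* mean square distance fluctuations
  `D_ij = C_ii + C_jj − 2 C_ij` (symmetric, zero diagonal, non-negative).

Null modes (`λ ≈ 0`) are rigid-body degrees of freedom, one per connected
component of the contact graph; they are excluded from every fluctuation
quantity and requesting one raises an error. *Fast-mode rank* `r` always
means the `r`-th largest eigenvalue (hm1 = fastest).

Hot-spot identification then proceeds along two routes:

1. **Threshold baselines.** A residue is called a hot spot when its
   normalized MSF (`MSF/c`) over the top `k` fast modes strictly exceeds a
   threshold — the constant 0.005, or the length-scaled `6/N`. Since each
   normalized single-mode profile sums to 1, `6/N > 0.005` exactly when
   `N < 1200`, so on such chains the length-scaled prediction set nests
   inside the constant one. The MSDF route returns a per-residue ranking
   score (row-wise `max`, or `mean` over partners `j ≠ i`) rather than
   labels, because the published residue-selection rule is not fully
   specified; labeling is left to a user-chosen quantile.
2. **Classifier.** The raw fast-mode components are features: scheme
   `single_mode` uses the `i`-th fastest eigenvector, `top_m` the `m`
   fastest; a sliding window of odd size `sw` adds the components of
   sequence neighbours, mode-major (all window slots of mode 1, then mode
   2, ...). A Gaussian naive Bayes model fits class priors from training
   frequencies and per-class, per-feature means and population variances;
   prediction is the argmax of `log P(y) + Σ_i log N(x_i; μ_yi, σ_yi²)`,
   with exact ties assigned to the negative class.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `cutoff` (`R_C`) | 7.0 Å (grid 6.0–8.0, step 0.1) | contact distance; boundary counts as contact |
| `scale` (`c`) | 1.0 | `3 k_B T / γ`; cancels in normalized MSF and is irrelevant to classification |
| `zero_tol` | 1e-10 × λ_max | relative null-space tolerance |
| mode rank/count | 1–20 | fast modes used as features |
| window `sw` | 1–21, odd | sliding-window width in retained-sequence positions |
| `var_smoothing` | 1e-9 × max feature variance | variance floor; keeps all-constant features (e.g. padded columns) finite |
| CV folds | 10 | chains per fold differ by ≤ 1 |

## Numerical choices

* **Contact boundary.** A pair exactly at `R_C` counts as a contact; the
  defining case split is ambiguous at the boundary and this choice is the
  common GNM convention, with measure-zero effect on real coordinates.
* **Eigenvector signs** are arbitrary; they are fixed by requiring the
  largest-magnitude component to be positive (ties: lowest index), so that
  signed features are reproducible across platforms. Degenerate
  eigenvalues keep the sorted order of the decomposition and are noted in
  logs; mode identity under degeneracy is intrinsically ill-defined.
* **Log-domain scoring** in the classifier: products of hundreds of
  densities underflow, so scores are summed in log space and posteriors
  normalized with log-sum-exp. Equivalence with the linear-domain product
  is part of the test contract.
* **Priors are learned**, not forced uniform — the decision rule includes
  `P(y)` and the data are heavily imbalanced.
* **Terminus handling** for windows: out-of-chain slots are zero-padded by
  default (keeps the feature dimension constant, as naive Bayes requires);
  `edge="drop"` is available to discard incomplete windows instead.
* **Zero-denominator metrics** (e.g. precision with no positive
  predictions) are reported as 0 with a flag rather than NaN, so grid
  ranking never crashes.
* **Micro-averaged CV**: confusion counts are pooled over folds and the
  five indices computed once, the only scheme in which sen/spe/pre/acc/F1
  stay mutually consistent with a single set of counts. The fold
  partition is a seeded shuffle with round-robin assignment; with 32
  chains and 10 folds, sizes are 3 or 4.
* **Grid ties** sort by F1 descending, then sensitivity descending, then
  cell lexicographic, making ranked tables deterministic.

## Synthetic benchmark

`SyntheticSpec` generates compact self-avoiding random walks: exact 3.8 Å
Cα–Cα virtual bonds, a 4.0 Å excluded-volume radius for non-consecutive
pairs, and a hard confinement sphere whose volume matches mean protein
packing (~120 Å³ per residue). That density puts the mean 7 Å contact
number in the protein-like 4–14 band. Defaults — 30 chains of 80–200
residues, hot-spot quantile 0.96 (~4% positives, matching the class
balance of curated hot-spot sets), flip noise 0.1 — define the study
conditions used throughout the tests and the acceptance script.

Labels are planted from each chain's own normalized MSF over the
`planted_modes` fastest modes at `planted_cutoff`, then flipped
independently with probability η. Planting from MSF (not raw components)
gives both the classifier and the MSF-threshold baselines recoverable
signal, enabling comparative experiments. The planted settings default to
`R* = 7.0 Å` — the standard GNM cutoff — and `m* = 3` fast modes, typical
of the fast-mode hot-spot literature. Everything is deterministic given
`(seed, chain index)`; fixture PDB files are byte-identical across runs.

What the generator does *not* emulate: real secondary structure, side
chains, sequence-dependent packing, interface geometry, or labels derived
from binding experiments. Passing tests therefore demonstrate that the
pipeline recovers a planted dynamics signal under realistic contact
density and label noise — not that it attains any particular accuracy on
experimental hot-spot data. For real data the `evaluate` CLI path accepts
user-supplied PDB files and labels.

## Problem sizes

The test suite and acceptance script run the full pipeline at desk scale:
30 chains (~4,300 residues) for the signal-recovery experiment, a
21-point cutoff grid with the planted `top_m` scheme over 20 replicate
datasets for cutoff recovery, and 200 label permutations for the null
distribution. The complete suite runs in a few minutes on one CPU; the
full 2-scheme × 21-cutoff × 11-window × 20-mode grid of a real study is a
straightforward (if hours-long) `evaluate` run and is not exercised in
tests.

## Known limitations

* The GNM is isotropic; no anisotropic (3N × 3N Hessian) variant.
* `γ` is uniform and not fitted to B-factors; `c` defaults to 1.
* The MSDF baseline stops at a ranking score (see above).
* Multi-model PDB files use one model (default: the first); chain choice
  per structure is explicit, since benchmark chain selections are not
  derivable from the structures themselves.
* Class imbalance is handled only through the metric (F1); no resampling
  or reweighting.
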