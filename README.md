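# hicpoly

Chromatin structure estimation from Hi-C contact maps. The package
combines:

- **`hicpoly.preprocess`** — contact-map I/O (dense text / binary,
  optional cooler container), extraction of fixed-size genomic regions
  (25.6 Mb → 512 bins at 50 kb), normalization (first off-diagonal mean
  0.1, unit main diagonal), genomic-distance normalization
  (observed-over-expected), compartment PC1, contact-probability scaling
  curves, and 2× coarsening.
- **`hicpoly.simulator`** — a grid-based heteropolymer Monte Carlo
  simulator: Gaussian-chain bonds plus a grid co-occupancy pair
  potential parameterized by an interaction matrix `U = L + T`
  (symmetric low-rank term plus symmetric Toeplitz term). Contact maps
  are ensemble averages of the same-cell indicator. The sampling kernel
  is numba-compiled; the grid origin is re-randomized every sweep.
- **`hicpoly.max_entropy`** — iterative maximum-entropy fitting of
  `chi` (with `L = Psi chi Psi^T` for per-bead label tracks `Psi`) and
  the per-distance Toeplitz values so the simulated map reproduces a
  target map's type–type co-contact sums and per-diagonal means.
- **`hicpoly.synthetic`** — synthetic training-data generation: seeded
  fixture pools of (L, T) parameters, per-rank kernel density estimates
  over pool eigenvalue spectra, and sampling of new parameter sets whose
  simulated contact maps form (H, U) training pairs.
- **`hicpoly.gnn`** — a graph-attention network that predicts (L, T)
  from a 100 kb contact map: edge-conditioned dynamic attention layers,
  a bilinear epigenetic head (`Z W Z^T`, upsampled 2× to 50 kb) and a
  Toeplitz genomic-distance head. The eigenvector node features are
  sign-symmetrized per column, so predictions are exactly invariant to
  eigenvector sign flips. Implemented with a small NumPy reverse-mode
  autodiff engine (`hicpoly.gnn.autodiff`) — no deep-learning framework
  required.
- **`hicpoly.metrics`** — stratum-adjusted correlation coefficient
  (SCC), HiC-Spector Laplacian-eigenvector score, PC1 correlation, RMSE
  of distance-normalized maps, and upper-triangle Pearson correlation
  for distance matrices.
- **`hicpoly.pipeline` / `hicpoly.cli`** — end-to-end orchestration of
  the two estimation routes: the maximum-entropy route (iterative fit +
  final simulation) and the network route (one-shot parameter
  prediction + exactly one simulation).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the slower end-to-end checks
(ideal-chain statistics, maximum-entropy parameter recovery at m = 64,
network training on ≥ 64 synthetic pairs); the remaining files are fast
unit/property tests.

## CLI

```bash
hicpoly preprocess chrom_map.txt outdir/ --pc1 --scaling
hicpoly simulate params.npz sim_map.txt --n-structures 5000 --seed 1
hicpoly me-fit target_map.txt run_me/ --epsilon 1e-2 --max-iter 20
hicpoly gen-data run_train/ --n-samples 128 --seed 1
hicpoly predict target_map.txt run_train/weights.npz params_hat.npz
hicpoly evaluate map_a.txt map_b.txt --h 5 --scc-k 100 --kappa 10
```

Run configs are YAML (`RunConfig`); flags override file values. Every
run archives its config next to its outputs.

## Conventions

- Energies are in kT; `U` entries are interpreted directly in kT.
  Negative `U_ij` attracts, positive repels.
- Pair energies count unordered pairs `i < j` once; self-pairs are
  excluded.
- Compartment PC1 is computed on the column-mean-centered
  distance-normalized map via SVD (first right-singular vector scaled by
  its singular value, largest-magnitude entry positive).
- 50 kb → 100 kb coarsening sums 2×2 blocks (conserves counts).
- SCC defaults: smoothing half-width h = 5, max stratum K = 100 bins,
  HiCRep-style rank-transformed variance-stabilized weights.
  HiC-Spector default κ = 10.
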