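# Methods

## Model

An MR scan measures the image `u ∈ C^{N×N}` in K-space through a unitary
Fourier encoding `F` (`FᴴF = I`, zero frequency at the grid center); an
accelerated scan keeps only the subset Ω of locations given by a sampling
mask, `F_p = P_Ω F`. Reconstruction solves

```
min_{u, W_b ∈ Λ}  ‖F_p u − f‖₂² + α ‖W_b W_a u‖₁
```

`W_a` is the fixed undecimated 2×2 Haar frame; `W_b` is a data-driven
frame of 16 filters of 4×4, constrained to the tight-frame class Λ.
Tightness is structural, not incidental: every analysis operator here is
periodic correlation with a bank of real p×p kernels that are the rows of
an orthogonal p²×p² matrix scaled by 1/p, which makes `WᴴW = I` exact (the
Fourier symbol `Σ_m |ĥ_m|²` is identically 1). That gives three things at
once: perfect reconstruction, energy preservation, and closed-form
least-squares updates throughout the solver.

The equivalent convolutional view — the composition is the bank of all
cross-correlations `b_m ⋆ a_n ⋆ u` — is how the code implements the
two-layer transform: the adaptive bank acts channel-wise on the
fixed-layer coefficient stack, so nested coefficients have shape
`(m_b, m_a, N, N)`.

## Algorithm

Three nested Bregman levels, each splitting off one difficulty:

* **Outer** (`n_outer`, default 10): `c ← c + F_p u − f` feeds the data
  residual back; this is what drives `‖F_p u − f‖/‖f‖` toward zero
  despite the regularizer biasing `u` smooth.
* **Mid** (`n_mid`, default 3): splits `u_a = W_a u` with Bregman
  variable `d` and coupling weight `μ`. The `u`-update solves the normal
  equation `F_pᴴ(F_p u − f + c) + μ W_aᴴ(W_a u − u_a + d) = 0` exactly in
  K-space: with `S = F W_aᴴ(u_a − d)` and `S₀ = f − c`,
  `Fu = S` off Ω and `Fu = (S₀ + μS)/(1 + μ)` on Ω. The weight placement
  follows from the objective in which μ multiplies the coupling term (the
  same convention the `u_a`-update uses); the residual of the normal
  equation is checked to 1e-8 in the tests. In the μ→0 limit the sampled
  locations are set to the (Bregman-corrected) measurements; μ→∞ ignores
  the data in favor of the frame coupling.
* **Inner** (`n_inner`, default 5): splits `v = W_b u_a` with Bregman
  variable `e`. Per pass: `v = shrink(W_b u_a + e, t)`; every
  `filter_update_every`-th pass `W_b` is relearned (below); then
  `u_a = (μ(W_a u + d) + W_bᴴ(v − e))/(1 + μ)`, which is the exact
  minimizer because `W_bᴴW_b = I`; finally `e ← e + W_b^old u_a^old − v`,
  i.e. the Bregman residual of the v-subproblem, evaluated with the
  pre-update bank and `u_a` (the cached analysis from the v-step). `e` is
  kept, not reprojected, when `W_b` changes.

The mid-level order is inner loop → `u`-update → `d`-update; iteration
counts are caps, with an outer-level stop when the relative change of `u`
falls below `tol` (default 1e-4). Initialization: `u⁰ = F_pᴴ f`
(zero-filled), `u_a = W_a u⁰`, `c = d = e = 0`, `W_b` from the
deterministic separable Haar patch basis (a DCT-II initializer is
available; both are orthogonal, hence tight). Non-finite values in any
iterate raise a divergence error naming the level and iteration.

### Filter learning

With patches `P` (one vectorized p×p patch per pixel of every fixed-layer
channel, periodic wrap — the same geometry as the analysis operator) and
targets `C = v − e`, the update solves `min ‖W P − C‖_F` over `W = (1/p)O`,
`O` orthogonal: the orthogonal Procrustes problem, solved by
`W = (1/p)UVᵀ` from the SVD of `Re(C Pᴴ)`. The real part keeps filters
real on complex data (a real bank can only fit the real-aligned component
of the cross-covariance). Sign conventions are pinned inside the SVD
(flipping paired singular vectors leaves `W` unchanged); the solution is
unique whenever the cross-matrix has distinct nonzero singular values.
All-zero input keeps the previous bank and warns. Deterministic filter
*ordering* (low-pass first, then by |DC| response) is applied only to the
constructed initial banks — reordering a Procrustes solution would change
its objective value.

### Thresholds and defaults

The method's original update rule uses threshold `t = 1/α`; the analytic
minimizer of `‖W_b u_a − v + e‖² + α‖v‖₁` is `t = α/2`. Both are
implemented (`shrink_threshold_mode`), with the original form as default. When `α` is
not given it is chosen so the effective threshold equals 0.02 × the
99th-percentile magnitude of the nested coefficients of the zero-filled
image — a scale-free default that behaves consistently across phantom
intensities. `μ` defaults to 1. The one-layer baseline (DDTF) reuses the
identical machinery with an identity fixed layer and a 64-filter 8×8
adaptive bank.

Because shrinkage, the Fourier operators and the real-filtered frames are
all phase-equivariant, the whole pipeline commutes with a global phase
rotation of the data — a property test asserts this to 1e-8.

## Sampling masks

The mask generators are parameterized constructions; they target a
realized sampling ratio of 1/R rather than any particular historical bit
pattern:

* **radial**: rasterized diameters through the K-space center. Default
  angle layout is the golden-angle sequence `θ_i = i·π(√5−1)/2 mod π` —
  the standard incremental radial ordering, whose spoke sets are nested so
  coverage is nondecreasing in spoke count (equispaced rasterized spokes
  are not monotone: line length depends on angle). Equispaced and jittered
  layouts are options.
* **variable density**: fully sampled central square (4% of the grid area
  by default) plus Bernoulli tails with probability `∝ (1 − r/r_max)³`;
  the amplitude is bisected against the realized count for a fixed uniform
  field, so the realized ratio matches 1/R to within one grid location.
* **cartesian lines**: fully sampled center band plus random phase-encode
  lines.

## Phantoms and simulated acquisition

Complex phantoms are a piecewise-smooth magnitude in [0, 1] (Shepp–Logan
ellipses; graded-intensity disks; multi-scale resolution bars emulating a
physical scanner phantom) times a phase model (zero, linear ramp, or a
seeded Gaussian-smoothed random field spanning ±π/2 — the smooth phase
variation of real receive fields). Acquisition takes the unitary DFT, adds
complex Gaussian noise in K-space (where MR noise enters physically),
with σ quoted relative to the peak K-space magnitude, then applies the
mask. Default noise is zero; tests that need noise add it explicitly.

What the generator does *not* emulate: multi-coil sensitivity encoding,
off-resonance and motion artifacts, Rician magnitude statistics after coil
combination, and anatomical texture. Passing tests therefore demonstrate
the solver's correctness and its behavior on piecewise-smooth complex
images, not clinical image quality.

## Metrics

PSNR `= 20 log₁₀(max(u₀)√Q / ‖u₀ − û‖₂)` with Q the pixel count and the
peak taken from the reference (a fixed dynamic range is optional);
relative error `‖u₀ − û‖₂/‖u₀‖₂`; SSIM as the mean over all fully
interior uniform 8×8 windows of `l^a c^b s^g` with unit exponents,
biased window moments and constants `C₁=(0.01L)²`, `C₂=(0.03L)²`,
`C₃=C₂/2` from the reference dynamic range. Complex images are reduced to
magnitude first. The SSIM implementation is cross-checked in the tests
against both a dense brute-force oracle and scikit-image at matched
settings.

## Problem sizes and numerical choices

The test suite and the acceptance script run at 64×64 for solver-behavior
checks and one full 128×128, R = 4 reconstruction with default iteration
counts for the quality comparison; 256×256 works identically but is
slower, so the smaller grids are used as the routine verification sizes.
Degenerate inputs are handled explicitly: empty masks (pure frame
synthesis branch), all-zero filter-learning input (bank kept, warning),
zero-norm references (metric errors), `shrink(·, 0)` returned bit-exact.
Determinism: all randomness flows from explicit seeds
(`numpy.random.default_rng`), experiment manifests record the full config,
and metrics CSVs are written with `repr` so reruns are byte-identical.

## Known limitations

Single-channel 2-D Cartesian data only (no NUFFT/gridding, no
SENSE/GRAPPA); one undecimated level per frame layer; the adaptive layer
learns a tight (not general) dictionary; convergence of the three-level
scheme is empirical (monotone PSNR traces), not proven; the default α
heuristic assumes the zero-filled image is a reasonable scale reference,
which can fail at extreme accelerations.
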