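# trims — two-layer tight-frame sparsifying reconstruction for CS-MRI

Compressed-sensing MRI accelerates scanning by acquiring only a fraction of
K-space (the 2-D spatial-frequency domain) and recovering the image by
exploiting its sparsity under a suitable transform. `trims` implements a
two-layer tight-frame sparsifying reconstruction: the complex image `u` is
sparsified by the *composition* of a fixed shift-invariant Haar tight frame
`W_a` and a data-driven tight frame `W_b` learned from the data being
reconstructed,

```
min_{u, W_b ∈ Λ}  ‖F_p u − f‖₂² + α ‖W_b W_a u‖₁
```

where `F_p` is the undersampled unitary Fourier encoding, `f` the measured
K-space data, and Λ the set of tight frames (filter banks satisfying the
unitary extension principle, `WᴴW = I`). The fixed layer captures generic
piecewise smoothness with 2×2 Haar filters; the adaptive layer — 16 filters
of 4×4, relearned during the iteration by an SVD-based orthogonal
Procrustes update — tailors the sparsity to the image at hand. Because both
layers are tight, every subproblem of the solver has a closed form.

The problem is solved by a three-level Bregman iteration:

1. **outer** — Bregman variable `c` adds the K-space data residual back,
   progressively restoring detail lost to regularization;
2. **mid** — assistant variable `u_a = W_a u` with Bregman variable `d`;
   the `u`-update is an exact K-space filling: off the sampling set
   `Fu = S`, on it `Fu = (S₀ + μS)/(1+μ)` with `S = F W_aᴴ(u_a − d)` and
   `S₀ = f − c`;
3. **inner** — nested variable `v = W_b u_a` with Bregman variable `e`:
   complex soft-thresholding `v = shrink(W_b u_a + e, t)` (ISTA step), the
   SVD filter update of `W_b`, and the component-wise least-squares
   `u_a = (μ(W_a u + d) + W_bᴴ(v − e))/(1+μ)`.

The package also provides the one-layer data-driven tight frame baseline
(DDTF: identity fixed layer, 64 learned filters of 8×8), undersampling-mask
generators (golden-angle radial spokes, 2-D variable-density random,
Cartesian lines), synthetic complex phantoms, and PSNR / relative error /
SSIM metrics.

## Worked example

Simulate a fourfold-accelerated variable-density acquisition of a 128×128
complex head phantom and compare three reconstructions
(`python examples/03_trims_reconstruction.py`, a couple of minutes on one
CPU):

```
acquired 25.0% of K-space (R = 4)

method       PSNR (dB)   rel err    SSIM
zero-filled      21.31    0.3510  0.4044
ddtf             26.24    0.1989  0.7333
trims            28.86    0.1471  0.9280
```

The zero-filled inverse FFT of the undersampled data is the floor: aliasing
from the missing 75% of K-space costs it ~21 dB. The one-layer learned
frame removes much of that aliasing; the two-layer model adds ~2.6 dB more
and raises SSIM to 0.93 — the nested sparsification recovers edges and fine
structure the single layer leaves blurred, while training only 16 small
filters instead of 64 large ones.

Other entry points: `examples/` contains one short script per capability;
the `trims` command exposes `phantom`, `mask`, `recon`, `metrics` and
`sweep` subcommands over YAML experiment configs (`trims recon --help`).

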