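"""Reconstruct an undersampled phantom: zero-filling vs one-layer vs two-layer.

Simulates a fourfold-accelerated variable-density acquisition of a complex
head phantom and compares the zero-filled baseline, the one-layer
data-driven tight frame (DDTF), and the two-layer method (TRIMS).
Runtime: a couple of minutes at 128x128 on one CPU.
"""

import numpy as np

from trims import (
    PhantomSpec,
    ReconParams,
    ddtf_reconstruct,
    make_phantom,
    make_variable_density_mask,
    simulate_acquisition,
    trims_reconstruct,
    zero_filled_reconstruct,
)
from trims.metrics import evaluate

img = make_phantom(PhantomSpec(kind="shepp_logan", n=128, phase_model="smooth_random", seed=7))
mask = make_variable_density_mask(128, acceleration=4.0, seed=7)
f = simulate_acquisition(img, mask)
gt = np.abs(img)
print(f"acquired {100 * mask.sampling_ratio:.1f}% of K-space (R = 4)\n")

rows = [("zero-filled", evaluate(gt, np.abs(zero_filled_reconstruct(f))))]
for name, method in (("ddtf", ddtf_reconstruct), ("trims", trims_reconstruct)):
    res = method(f, ReconParams(), ground_truth=img)
    rows.append((name, evaluate(gt, np.abs(res.image))))

print(f"{'method':<12}{'PSNR (dB)':>10}{'rel err':>10}{'SSIM':>8}")
for name, rep in rows:
    print(f"{name:<12}{rep.psnr_db:>10.2f}{rep.rel_err:>10.4f}{rep.ssim:>8.4f}")
# Higher PSNR/SSIM and lower relative error mean the iterative methods have
# restored detail the zero-filled inverse FFT loses to undersampling.
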