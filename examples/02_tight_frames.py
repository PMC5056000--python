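"""Tight-frame operators: the fixed Haar bank and the SVD filter update.

Shows the perfect-reconstruction property W^H W = I of the undecimated
frames and the orthogonality-constrained (Procrustes) learning step that
recovers a planted bank exactly from its own coefficients.
"""

import numpy as np
from scipy.stats import ortho_group

from trims import haar_fixed_bank, init_adaptive_bank, update_filters_svd

rng = np.random.default_rng(0)

haar = haar_fixed_bank()
x = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
err = np.linalg.norm(haar.synthesize(haar.analyze(x)) - x) / np.linalg.norm(x)
print(f"fixed Haar bank: {haar.m} filters of {haar.p}x{haar.p}, "
      f"round-trip error {err:.2e} (tight frame => ~machine precision)")

adaptive = init_adaptive_bank(4)
print(f"adaptive init: {adaptive.m} filters of 4x4, UEP residual {adaptive.uep_residual:.2e}")

# plant a random tight frame, generate coefficients from it, and relearn it
w0 = ortho_group.rvs(16, random_state=1) / 4
patches = rng.normal(size=(16, 200)) + 1j * rng.normal(size=(16, 200))
recovered = update_filters_svd(patches, w0 @ patches)
print(f"planted-frame recovery error: {np.abs(recovered.matrix - w0).max():.2e} "
      "(the SVD update solves the constrained least squares exactly)")
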