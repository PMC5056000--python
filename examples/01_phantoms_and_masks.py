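"""Build a synthetic complex MR phantom and the standard undersampling masks.

A complex phantom (piecewise-smooth magnitude times a smooth phase) is the
stand-in for a scanned image; the masks decide which K-space locations a
scan at acceleration R would actually acquire.
"""

import numpy as np

from trims import (
    PhantomSpec,
    make_phantom,
    make_radial_mask,
    make_variable_density_mask,
)

phantom = make_phantom(PhantomSpec(kind="shepp_logan", n=128, phase_model="smooth_random", seed=0))
print(f"phantom: {phantom.shape}, magnitude in [{np.abs(phantom).min():.2f}, "
      f"{np.abs(phantom).max():.2f}], phase span {np.ptp(np.angle(phantom)):.2f} rad")

radial = make_radial_mask(128, num_spokes=32)
vd = make_variable_density_mask(128, acceleration=4.0, seed=0)
print(f"radial 32 spokes: sampling ratio {radial.sampling_ratio:.4f} "
      f"(nominal R ~ {radial.acceleration:.1f})")
print(f"variable density R=4: sampling ratio {vd.sampling_ratio:.4f} "
      "(fully sampled center, random tails)")
# Each ratio is the fraction of K-space actually measured: 0.25 at R=4 means
# the scan is four times faster than a Nyquist acquisition.
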