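"""Synthetic complex-valued MR phantoms and retrospective K-space simulation.

Scanned MR images are complex valued: a piecewise-smooth magnitude
modulated by a smooth phase set by field inhomogeneity and coil geometry.
The generators here emulate that structure — a Shepp–Logan head phantom,
graded-intensity disks, and multi-scale resolution bars (line pairs, like
the etched structures of a physical scanner phantom) — with a selectable
phase model, and simulate the acquisition by taking the unitary DFT,
adding complex Gaussian noise in K-space (where MR noise actually enters)
and applying an undersampling mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .sampling import KSpaceData, SamplingMask, apply_undersampling, forward_fourier

__all__ = ["PhantomSpec", "make_phantom", "simulate_acquisition"]

# Modified Shepp–Logan ellipse table: (intensity, a, b, x0, y0, phi_deg)
# on the [-1, 1]^2 field of view.
_SHEPP_LOGAN = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


@dataclasses.dataclass
class PhantomSpec:
    """Recipe for a deterministic synthetic complex MR image.

    ``noise_sigma`` is the K-space complex-Gaussian standard deviation as
    a fraction of the peak K-space magnitude (scale-free); it is applied
    by :func:`simulate_acquisition`, not baked into the image.
    """

    kind: str = "shepp_logan"  # shepp_logan | piecewise_disks | resolution_bars
    n: int = 128
    phase_model: str = "smooth_random"  # zero | linear | smooth_random
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n % 2 or self.n < 8:
            raise ValueError("grid size must be even and >= 8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def _shepp_logan(n: int) -> np.ndarray:
    x, y = np.meshgrid(np.linspace(-1, 1, n), np.linspace(1, -1, n))
    img = np.zeros((n, n))
    for amp, a, b, x0, y0, phi in _SHEPP_LOGAN:
        t = np.deg2rad(phi)
        xr = (x - x0) * np.cos(t) + (y - y0) * np.sin(t)
        yr = -(x - x0) * np.sin(t) + (y - y0) * np.cos(t)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += amp
    img = np.clip(img, 0.0, None)
    return img / img.max()


def _piecewise_disks(n: int) -> np.ndarray:
    x, y = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n))
    img = np.zeros((n, n))
    centers = [(-0.5, -0.5), (0.5, -0.5), (-0.5, 0.5), (0.5, 0.5), (0.0, 0.0)]
    radii = [0.32, 0.26, 0.2, 0.14, 0.4]
    levels = [0.3, 0.5, 0.7, 0.9, 1.0]
    for (cx, cy), r, lev in sorted(zip(centers, radii, levels), key=lambda z: -z[1]):
        img[(x - cx) ** 2 + (y - cy) ** 2 <= r**2] = lev
    return img


def _resolution_bars(n: int) -> np.ndarray:
    img = np.zeros((n, n))
    band = n // 5
    periods = [2, 4, 8, 16]  # line-pair widths in pixels, fine to coarse
    # four horizontal bands of vertical line pairs at different scales
    for i, period in enumerate(periods):
        top = int((i + 0.5) * n / (len(periods) + 1))
        stripes = (np.arange(n) // period) % 2 == 0
        img[top : top + band // 2, n // 8 : n - n // 8] = stripes[n // 8 : n - n // 8]
    return img


def _phase(spec: PhantomSpec) -> np.ndarray:
    n = spec.n
    if spec.phase_model == "zero":
        return np.zeros((n, n))
    if spec.phase_model == "linear":
        x, y = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n))
        return np.pi * (0.5 * x + 0.3 * y)
    if spec.phase_model == "smooth_random":
        rng = np.random.default_rng(spec.seed)
        field = gaussian_filter(rng.normal(size=(n, n)), sigma=n / 8, mode="wrap")
        peak = np.abs(field).max()
        return 0.5 * np.pi * field / peak if peak > 0 else field
    raise ValueError(f"unknown phase model '{spec.phase_model}'")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Complex phantom image: magnitude in [0, 1] times the phase model."""
    builders = {
        "shepp_logan": _shepp_logan,
        "piecewise_disks": _piecewise_disks,
        "resolution_bars": _resolution_bars,
    }
    if spec.kind not in builders:
        raise ValueError(f"unknown phantom kind '{spec.kind}'")
    magnitude = builders[spec.kind](spec.n)
    return magnitude * np.exp(1j * _phase(spec))


def simulate_acquisition(
    image: np.ndarray,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> KSpaceData:
    """Retrospectively undersampled K-space data for a known image.

    Takes the unitary DFT of the image, adds i.i.d. complex Gaussian noise
    with standard deviation ``noise_sigma`` times the peak K-space
    magnitude, and zeroes the unsampled locations.  The caller keeps the
    ground-truth image for evaluation.
    """
    kspace = forward_fourier(image)
    if kspace.shape != mask.grid.shape:
        raise ValueError("image and mask shapes differ")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma * np.abs(kspace).max()
        noise = rng.normal(size=kspace.shape) + 1j * rng.normal(size=kspace.shape)
        kspace = kspace + scale * noise / np.sqrt(2.0)
    data = apply_undersampling(kspace, mask)
    return KSpaceData(values=data.values, mask=mask, noise_sigma=noise_sigma)
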