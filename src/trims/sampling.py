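"""K-space encoding operators and undersampling mask generation.

MRI acquires data in K-space, the 2-D spatial-frequency domain.
Compressed-sensing MRI undersamples K-space below the Nyquist rate; this
module provides the centered unitary Fourier encoding pair, the sampling
projection, and generators for the standard undersampling patterns
(radial spokes, 2-D variable-density random, Cartesian phase-encode
lines).  All grids are square N x N with N even and the zero frequency at
the grid center (``fftshift`` convention).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path

import numpy as np

__all__ = [
    "MaskScheme",
    "SamplingMask",
    "KSpaceData",
    "forward_fourier",
    "inverse_fourier",
    "apply_undersampling",
    "make_radial_mask",
    "make_variable_density_mask",
    "make_cartesian_mask",
    "full_mask",
    "save_mask",
    "load_mask",
]


class MaskScheme(str, enum.Enum):
    """Undersampling pattern families."""

    RADIAL = "radial"
    VARIABLE_DENSITY_2D = "variable_density_2d"
    CARTESIAN_LINES = "cartesian_lines"
    FULL = "full"


@dataclasses.dataclass
class SamplingMask:
    """Boolean K-space selection grid Omega.

    ``grid[i, j]`` is True where the K-space location is sampled; the zero
    frequency sits at index (N//2, N//2).  ``acceleration`` is the nominal
    undersampling factor R; ``sampling_ratio`` is the realized fraction of
    sampled locations (approximately 1/R).
    """

    grid: np.ndarray
    scheme: MaskScheme
    acceleration: float
    sampling_ratio: float = dataclasses.field(init=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        self.grid = grid
        self.sampling_ratio = float(grid.sum()) / grid.size
        if self.scheme == MaskScheme.FULL and self.sampling_ratio != 1.0:
            raise ValueError("scheme 'full' requires a fully-True grid")

    @property
    def n(self) -> int:
        return self.grid.shape[0]


@dataclasses.dataclass
class KSpaceData:
    """Undersampled K-space measurements f with their mask.

    ``values`` is zero wherever ``mask.grid`` is False (zero-filled
    convention for the adjoint F_p^H).
    """

    values: np.ndarray
    mask: SamplingMask
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=complex)
        if values.shape != self.mask.grid.shape:
            raise ValueError("K-space values and mask shapes differ")
        if np.any(values[~self.mask.grid] != 0):
            raise ValueError("values must be zero at unsampled locations")
        self.values = values

    def zero_filled(self) -> np.ndarray:
        """Zero-filled reconstruction F_p^H f (inverse DFT of masked data)."""
        return inverse_fourier(self.values)


def _check_square_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={x.ndim}")
    if x.shape[0] != x.shape[1]:
        raise ValueError(f"expected a square grid, got shape {x.shape}")
    return x


def forward_fourier(image: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT, F with F^H F = I.

    A constant image of value 1 on an N x N grid maps to a single central
    coefficient of value N; energy is preserved (Parseval).
    """
    image = _check_square_2d(image).astype(complex, copy=False)
    n = image.shape[0]
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image))) / n


def inverse_fourier(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_fourier` (the adjoint F^H)."""
    kspace = _check_square_2d(kspace).astype(complex, copy=False)
    n = kspace.shape[0]
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace))) * n


def apply_undersampling(kspace: np.ndarray, mask: SamplingMask) -> KSpaceData:
    """Project full K-space onto the sampled subset Omega (zeros elsewhere)."""
    kspace = _check_square_2d(kspace)
    if kspace.shape != mask.grid.shape:
        raise ValueError("K-space and mask shapes differ")
    return KSpaceData(values=np.where(mask.grid, kspace, 0.0), mask=mask)


GOLDEN_ANGLE = np.pi * (np.sqrt(5.0) - 1.0) / 2.0


def make_radial_mask(
    n: int,
    num_spokes: int,
    seed: int | None = None,
    jitter: float = 0.0,
    angle_layout: str = "golden",
    half_spokes: bool = False,
) -> SamplingMask:
    """Union of ``num_spokes`` straight lines through the K-space center.

    The default ``angle_layout='golden'`` takes spoke i at the golden
    angle i * pi (sqrt(5)-1)/2 (mod pi), the standard incremental radial
    ordering: spoke sets are nested, so coverage is nondecreasing in the
    spoke count while angles stay near-uniform.  ``'equispaced'`` spreads
    the angles uniformly over [0, pi) instead (optionally jittered by a
    uniform fraction ``jitter`` of the spacing).  Lines are full
    diameters (``half_spokes`` switches to radii over [0, 2 pi)) and are
    rasterized onto the Cartesian grid; the center point is always
    sampled.
    """
    if n < 8:
        raise ValueError("grid size must be at least 8")
    if num_spokes < 1:
        raise ValueError("num_spokes must be >= 1")
    if num_spokes > 4 * n:
        raise ValueError(f"num_spokes={num_spokes} exceeds grid capacity for n={n}")
    span = 2.0 * np.pi if half_spokes else np.pi
    if angle_layout == "golden":
        angles = (np.arange(num_spokes) * GOLDEN_ANGLE * (span / np.pi)) % span
    elif angle_layout == "equispaced":
        angles = np.arange(num_spokes) * span / num_spokes
    else:
        raise ValueError(f"unknown angle_layout '{angle_layout}'")
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        angles = angles + rng.uniform(-0.5, 0.5, num_spokes) * jitter * span / max(num_spokes, 1)
    cx = cy = n // 2
    grid = np.zeros((n, n), dtype=bool)
    # fine parametric sampling along each diameter, rounded to pixels
    t = np.arange(-n, n + 0.25, 0.25) if not half_spokes else np.arange(0, n + 0.25, 0.25)
    for theta in angles:
        xs = np.rint(cx + t * np.cos(theta)).astype(int)
        ys = np.rint(cy + t * np.sin(theta)).astype(int)
        keep = (xs >= 0) & (xs < n) & (ys >= 0) & (ys < n)
        grid[ys[keep], xs[keep]] = True
    grid[cy, cx] = True
    ratio = grid.sum() / grid.size
    return SamplingMask(
        grid=grid,
        scheme=MaskScheme.RADIAL,
        acceleration=1.0 / ratio,
        seed=seed,
    )


def make_variable_density_mask(
    n: int,
    acceleration: float,
    seed: int | None = None,
    center_fraction: float = 0.04,
    decay: float = 3.0,
) -> SamplingMask:
    """2-D variable-density random mask at nominal acceleration R.

    A central square holding ``center_fraction`` of the grid area is fully
    sampled; outside it, locations are kept by thresholding a uniform
    random field against a radially decaying polynomial profile
    ``(1 - r/r_max)**decay``.  The profile amplitude is calibrated by
    bisection against the realized count, so the realized sampling ratio
    matches 1/R to within one grid location of the closest achievable.
    """
    if n < 8 or n % 2:
        raise ValueError("grid size must be even and >= 8")
    if acceleration < 1.0:
        raise ValueError("acceleration must be >= 1")
    target = int(round(n * n / acceleration))
    cx = cy = n // 2
    half = max(1, int(round(n * np.sqrt(center_fraction) / 2)))
    center = np.zeros((n, n), dtype=bool)
    center[cy - half : cy + half, cx - half : cx + half] = True
    if acceleration == 1.0 or target >= n * n:
        return full_mask(n)
    if center.sum() > target:
        raise ValueError(
            f"fully sampled center block ({center.sum()} points) already exceeds "
            f"the sampling budget {target} at R={acceleration}"
        )
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - cy, xx - cx)
    profile = np.clip(1.0 - r / r.max(), 0.0, 1.0) ** decay
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n, n))

    def realized(amp: float) -> np.ndarray:
        return center | (u < np.clip(amp * profile, 0.0, 1.0))

    lo, hi = 0.0, 1.0
    while realized(hi).sum() < target and hi < 1e6:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid).sum() < target:
            lo = mid
        else:
            hi = mid
    grid = realized(hi)
    ratio = grid.sum() / grid.size
    if abs(ratio - 1.0 / acceleration) > 0.01:
        raise ValueError(
            f"calibration failed: realized ratio {ratio:.4f} vs target "
            f"{1.0 / acceleration:.4f}"
        )
    return SamplingMask(
        grid=grid,
        scheme=MaskScheme.VARIABLE_DENSITY_2D,
        acceleration=acceleration,
        seed=seed,
    )


def make_cartesian_mask(
    n: int,
    acceleration: float,
    seed: int | None = None,
    center_fraction: float = 0.08,
) -> SamplingMask:
    """1-D random phase-encode line mask (fully sampled readout direction)."""
    if acceleration < 1.0:
        raise ValueError("acceleration must be >= 1")
    num_lines = int(round(n / acceleration))
    num_center = max(1, int(round(n * center_fraction)))
    if num_center > num_lines:
        raise ValueError("center lines alone exceed the line budget")
    cy = n // 2
    lines = set(range(cy - num_center // 2, cy - num_center // 2 + num_center))
    rng = np.random.default_rng(seed)
    remaining = [i for i in range(n) if i not in lines]
    extra = rng.choice(remaining, size=num_lines - len(lines), replace=False)
    lines.update(int(i) for i in extra)
    grid = np.zeros((n, n), dtype=bool)
    grid[sorted(lines), :] = True
    return SamplingMask(
        grid=grid,
        scheme=MaskScheme.CARTESIAN_LINES,
        acceleration=acceleration,
        seed=seed,
    )


def full_mask(n: int) -> SamplingMask:
    """Fully sampled Nyquist mask (R = 1)."""
    return SamplingMask(
        grid=np.ones((n, n), dtype=bool), scheme=MaskScheme.FULL, acceleration=1.0
    )


def save_mask(mask: SamplingMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (0/255) with a JSON metadata sidecar."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(mask.grid.astype(np.uint8) * 255).save(path)
    meta = {
        "scheme": mask.scheme.value,
        "acceleration": mask.acceleration,
        "sampling_ratio": mask.sampling_ratio,
        "seed": mask.seed,
        "n": mask.n,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_mask(path: str | Path) -> SamplingMask:
    """Read a mask written by :func:`save_mask`."""
    from PIL import Image

    path = Path(path)
    grid = np.asarray(Image.open(path)) > 127
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SamplingMask(
        grid=grid,
        scheme=MaskScheme(meta["scheme"]),
        acceleration=meta["acceleration"],
        seed=meta["seed"],
    )
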