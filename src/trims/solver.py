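"""Three-level Bregman solver for two-layer tight-frame CS-MRI (TRIMS).

The reconstruction model sparsifies the image u with the composition of a
fixed shift-invariant Haar tight frame W_a and a data-driven tight frame
W_b learned during the iteration::

    min_{u, W_b}  || F_p u - f ||_2^2  +  alpha || W_b W_a u ||_1

F_p is the undersampled unitary Fourier encoding.  The solver splits the
problem with assistant variables u_a = W_a u and v = W_b u_a, each with
its own Bregman variable:

* level 1 (outer): adds the K-space data residual back via c,
* level 2 (mid): couples u to u_a with weight mu via d; the u-update is a
  closed-form K-space filling exploiting W_a^H W_a = I and F^H F = I,
* level 3 (inner): complex soft-thresholding of the nested coefficients
  (ISTA step), the SVD filter update of W_b, the component-wise
  least-squares u_a update, and the e Bregman update.

The one-layer data-driven tight frame baseline (DDTF) is the degenerate
case W_a = I with a 64-filter 8 x 8 adaptive bank learned on u directly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .frames import (
    FilterBank,
    delta_bank,
    extract_patches,
    haar_fixed_bank,
    init_adaptive_bank,
    update_filters_svd,
)
from .metrics import psnr, relative_error, ssim
from .sampling import KSpaceData, forward_fourier, inverse_fourier

log = logging.getLogger(__name__)

__all__ = [
    "ReconParams",
    "TRIMSState",
    "ReconResult",
    "DivergenceError",
    "shrink",
    "shrink_threshold",
    "update_u_kspace",
    "update_ua",
    "update_v",
    "update_adaptive_bank",
    "trims_reconstruct",
    "ddtf_reconstruct",
    "zero_filled_reconstruct",
]


class DivergenceError(RuntimeError):
    """Raised when an iterate becomes non-finite, naming level and iteration."""


@dataclasses.dataclass
class ReconParams:
    """Solver configuration.

    ``alpha`` is the sparsity weight; ``None`` selects it so the effective
    shrink threshold is 0.02 times the 99th-percentile nested-coefficient
    magnitude of the zero-filled image (scale-free across phantom
    intensities).  ``mu`` weights the W_a-coupling term of the mid level.
    ``shrink_threshold_mode`` chooses the threshold 1/alpha
    (``inverse_alpha``, the method's original update rule) or alpha/2
    (``scaled_alpha``, the analytic minimizer of the l1 subproblem).
    """

    alpha: float | None = None
    mu: float = 1.0
    n_outer: int = 10
    n_mid: int = 3
    n_inner: int = 5
    shrink_threshold_mode: str = "inverse_alpha"
    filter_update_every: int = 1
    tol: float = 1e-4
    seed: int = 0
    adaptive_filter_size: int | None = None
    adaptive_init: str = "haar"

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        for name in ("n_outer", "n_mid", "n_inner", "filter_update_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.shrink_threshold_mode not in ("inverse_alpha", "scaled_alpha"):
            raise ValueError(
                f"unknown shrink_threshold_mode '{self.shrink_threshold_mode}'"
            )


@dataclasses.dataclass
class TRIMSState:
    """All iterates of the three-level scheme.

    Shapes for an N x N image, fixed bank of m_a filters and adaptive bank
    of m_b filters: ``u`` (N, N); ``ua`` and ``d`` (m_a, N, N); ``v`` and
    ``e`` (m_b, m_a, N, N); ``c`` (N, N) supported on the sampling set.
    """

    u: np.ndarray
    ua: np.ndarray
    v: np.ndarray
    c: np.ndarray
    d: np.ndarray
    e: np.ndarray
    wa: FilterBank
    wb: FilterBank
    iteration: tuple[int, int, int] = (0, 0, 0)
    history: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ReconResult:
    """Reconstruction output: ``image`` is the final iterate ``state.u``."""

    image: np.ndarray
    state: TRIMSState
    params: ReconParams
    converged: bool
    metrics_trace: list


def shrink(x: np.ndarray, a: float) -> np.ndarray:
    """Complex soft-threshold sign(x) * max(0, |x| - a); phase preserved."""
    if a < 0:
        raise ValueError("shrink threshold must be nonnegative")
    x = np.asarray(x, dtype=complex)
    mag = np.abs(x)
    # multiplicative form x * max(0, 1 - a/|x|): exact identity at a = 0
    factor = np.maximum(1.0 - a / np.where(mag > 0, mag, 1.0), 0.0)
    return x * np.where(mag > 0, factor, 0.0)


def shrink_threshold(params: ReconParams) -> float:
    """Effective soft-threshold for the v-update under the configured mode."""
    if params.alpha is None:
        raise ValueError("alpha has not been resolved")
    if params.shrink_threshold_mode == "inverse_alpha":
        return 1.0 / params.alpha
    return params.alpha / 2.0


def _resolve_alpha(
    params: ReconParams, u0: np.ndarray, wa: FilterBank, wb: FilterBank
) -> ReconParams:
    """Fill in the scale-free default alpha from the zero-filled image."""
    if params.alpha is not None:
        return params
    coeffs = wb.analyze(wa.analyze(u0))
    p99 = float(np.percentile(np.abs(coeffs), 99))
    t = 0.02 * p99
    if t <= 0:
        alpha = 1.0
    elif params.shrink_threshold_mode == "inverse_alpha":
        alpha = 1.0 / t
    else:
        alpha = 2.0 * t
    return dataclasses.replace(params, alpha=alpha)


def _guard(name: str, array: np.ndarray, iteration: tuple[int, int, int]) -> None:
    if not np.all(np.isfinite(array.view(float))):
        outer, mid, inner = iteration
        raise DivergenceError(
            f"non-finite values in '{name}' at outer={outer}, mid={mid}, inner={inner}"
        )


def update_u_kspace(state: TRIMSState, f: KSpaceData, params: ReconParams) -> np.ndarray:
    """Closed-form K-space solution of the mid-level least-squares u-update.

    Solves  F_p^H (F_p u - f + c) + mu W_a^H (W_a u - u_a + d) = 0  exactly
    (the normal equation of the u subproblem) using W_a^H W_a = I: with
    S = F W_a^H (u_a - d) and S0 = f - c on the sampling set Omega,

        (F u)(k) = S(k)                          off Omega,
        (F u)(k) = (S0(k) + mu S(k)) / (1 + mu)  on Omega.

    Off Omega only the frame-coupling term acts; on Omega the measured
    data (Bregman-corrected by c) and the coupling are blended by mu.
    """
    if f.values.shape != state.u.shape:
        raise ValueError("K-space data and state geometry differ")
    mask = f.mask.grid
    s = forward_fourier(state.wa.synthesize(state.ua - state.d))
    s0 = np.where(mask, f.values - state.c, 0.0)
    k = np.where(mask, (s0 + params.mu * s) / (1.0 + params.mu), s)
    return inverse_fourier(k)


def update_ua(state: TRIMSState, params: ReconParams) -> np.ndarray:
    """Component-wise least-squares update of the assistant variable u_a:

    u_a = ( mu (W_a u + d) + W_b^H (v - e) ) / (1 + mu),

    valid because W_b^H W_b = I decouples the quadratic per component.
    """
    coupling = state.wa.analyze(state.u) + state.d
    fit = state.wb.synthesize(state.v - state.e)
    if fit.shape != coupling.shape:
        raise ValueError("stale geometry: v/e do not match the fixed-layer stack")
    return (params.mu * coupling + fit) / (1.0 + params.mu)


def update_v(state: TRIMSState, params: ReconParams) -> np.ndarray:
    """ISTA update of the nested coefficients: v = shrink(W_b u_a + e, t)."""
    return shrink(state.wb.analyze(state.ua) + state.e, shrink_threshold(params))


def update_adaptive_bank(state: TRIMSState, params: ReconParams) -> FilterBank:
    """Relearn W_b by the SVD tight-frame update on patches of u_a.

    Patches of every fixed-layer channel of u_a are matched against the
    corresponding vectors of v - e (the current sparse targets); the
    Procrustes solution keeps the bank tight.  e is retained unchanged
    across the bank update.
    """
    p = state.wb.p
    patches = np.hstack([extract_patches(ch, p) for ch in state.ua])
    targets = (state.v - state.e).reshape(state.wb.m, -1)
    return update_filters_svd(patches, targets, previous=state.wb)


def _log_metrics(
    state: TRIMSState,
    f: KSpaceData,
    outer: int,
    rel_change: float,
    ground_truth: np.ndarray | None,
) -> dict:
    fu = np.where(f.mask.grid, forward_fourier(state.u), 0.0)
    fnorm = np.linalg.norm(f.values)
    row: dict = {
        "outer_iter": outer,
        "data_residual": float(np.linalg.norm(fu - f.values) / fnorm) if fnorm else 0.0,
        "rel_change": rel_change,
        "sparsity": float(np.mean(np.abs(state.v) < 1e-6 * max(np.abs(state.v).max(), 1e-300))),
    }
    if ground_truth is not None:
        gt = np.abs(ground_truth)
        est = np.abs(state.u)
        row.update(
            psnr_db=psnr(gt, est), rel_err=relative_error(gt, est), ssim=ssim(gt, est)
        )
    state.history.append(row)
    log.info(
        "outer %d: data residual %.3e, sparsity %.3f%s",
        outer,
        row["data_residual"],
        row["sparsity"],
        f", PSNR {row['psnr_db']:.2f} dB" if "psnr_db" in row else "",
    )
    return row


def _reconstruct(
    f: KSpaceData,
    params: ReconParams,
    fixed_bank: FilterBank,
    adaptive_p: int,
    ground_truth: np.ndarray | None,
) -> ReconResult:
    mask = f.mask.grid
    u = f.zero_filled()
    wa = fixed_bank
    wb = init_adaptive_bank(adaptive_p, init=params.adaptive_init)
    params = _resolve_alpha(params, u, wa, wb)
    t = shrink_threshold(params)

    ua = wa.analyze(u)
    d = np.zeros_like(ua)
    v = np.zeros((wb.m, *ua.shape), dtype=complex)
    e = np.zeros_like(v)
    c = np.zeros_like(f.values)
    state = TRIMSState(u=u, ua=ua, v=v, c=c, d=d, e=e, wa=wa, wb=wb)

    converged = False
    inner_count = 0
    for outer in range(1, params.n_outer + 1):
        u_prev = state.u
        for mid in range(1, params.n_mid + 1):
            for inner in range(1, params.n_inner + 1):
                state.iteration = (outer, mid, inner)
                analyzed = state.wb.analyze(state.ua)  # pre-update bank and u_a
                state.v = shrink(analyzed + state.e, t)
                _guard("v", state.v, state.iteration)
                if inner_count % params.filter_update_every == 0:
                    state.wb = update_adaptive_bank(state, params)
                state.ua = update_ua(state, params)
                state.e = state.e + analyzed - state.v
                inner_count += 1
                _guard("u_a", state.ua, state.iteration)
                _guard("e", state.e, state.iteration)
            state.u = update_u_kspace(state, f, params)
            state.d = state.d + state.wa.analyze(state.u) - state.ua
            _guard("u", state.u, state.iteration)
            _guard("d", state.d, state.iteration)
        state.c = state.c + np.where(mask, forward_fourier(state.u), 0.0) - f.values
        _guard("c", state.c, state.iteration)
        denom = np.linalg.norm(u_prev)
        rel_change = float(np.linalg.norm(state.u - u_prev) / denom) if denom else np.inf
        _log_metrics(state, f, outer, rel_change, ground_truth)
        if rel_change < params.tol:
            converged = True
            break

    return ReconResult(
        image=state.u,
        state=state,
        params=params,
        converged=converged,
        metrics_trace=list(state.history),
    )


def trims_reconstruct(
    f: KSpaceData,
    params: ReconParams | None = None,
    ground_truth: np.ndarray | None = None,
) -> ReconResult:
    """Two-layer reconstruction: fixed 2 x 2 Haar frame composed with an
    adaptively learned 16-filter 4 x 4 tight frame."""
    params = params or ReconParams()
    return _reconstruct(
        f,
        params,
        fixed_bank=haar_fixed_bank(),
        adaptive_p=params.adaptive_filter_size or 4,
        ground_truth=ground_truth,
    )


def ddtf_reconstruct(
    f: KSpaceData,
    params: ReconParams | None = None,
    ground_truth: np.ndarray | None = None,
) -> ReconResult:
    """One-layer data-driven tight frame baseline: the fixed layer is the
    identity and a 64-filter 8 x 8 bank is learned on the image directly."""
    params = params or ReconParams()
    return _reconstruct(
        f,
        params,
        fixed_bank=delta_bank(),
        adaptive_p=params.adaptive_filter_size or 8,
        ground_truth=ground_truth,
    )


def zero_filled_reconstruct(f: KSpaceData) -> np.ndarray:
    """The non-iterative baseline F_p^H f."""
    return f.zero_filled()
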