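"""Experiment orchestration: single reconstructions and acceleration sweeps.

Every run is driven by an :class:`ExperimentConfig` and leaves behind a
manifest (config + package version + root seed) from which the result
directory can be regenerated bit-identically.  A sweep repeats the run
over a list of acceleration factors, deriving one mask seed per R from
the root seed, and tabulates PSNR / relative error / SSIM versus R.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import save_bank, save_magnitude_phase_nifti, write_metrics_csv
from .metrics import evaluate
from .phantoms import PhantomSpec, make_phantom, simulate_acquisition
from .sampling import (
    SamplingMask,
    full_mask,
    make_cartesian_mask,
    make_radial_mask,
    make_variable_density_mask,
    save_mask,
)
from .solver import (
    ReconParams,
    ReconResult,
    ddtf_reconstruct,
    trims_reconstruct,
    zero_filled_reconstruct,
)

__all__ = ["MaskConfig", "ExperimentConfig", "run_single", "run_sweep", "load_config"]

# acceleration factors of the standard sensitivity protocol
DEFAULT_ACCELERATIONS = (2.5, 4.0, 6.0, 8.0, 10.0)


@dataclasses.dataclass
class MaskConfig:
    """Mask scheme and parameters for one experiment."""

    scheme: str = "variable_density_2d"
    acceleration: float = 4.0
    num_spokes: int = 32
    center_fraction: float = 0.04
    decay: float = 3.0

    def build(self, n: int, seed: int | None) -> SamplingMask:
        if self.scheme == "variable_density_2d":
            return make_variable_density_mask(
                n,
                self.acceleration,
                seed=seed,
                center_fraction=self.center_fraction,
                decay=self.decay,
            )
        if self.scheme == "radial":
            return make_radial_mask(n, self.num_spokes, seed=seed)
        if self.scheme == "cartesian_lines":
            return make_cartesian_mask(n, self.acceleration, seed=seed)
        if self.scheme == "full":
            return full_mask(n)
        raise ValueError(f"unknown mask scheme '{self.scheme}'")


@dataclasses.dataclass
class ExperimentConfig:
    """Full recipe for one reconstruction experiment."""

    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    mask: MaskConfig = dataclasses.field(default_factory=MaskConfig)
    method: str = "trims"  # trims | ddtf | zero_filled
    recon: ReconParams = dataclasses.field(default_factory=ReconParams)
    output_dir: str = "trims_run"
    accelerations: tuple = DEFAULT_ACCELERATIONS

    def __post_init__(self) -> None:
        if self.method not in ("trims", "ddtf", "zero_filled"):
            raise ValueError(f"unknown method '{self.method}'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["accelerations"] = list(self.accelerations)
        d["version"] = __version__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d.pop("version", None)
        d["phantom"] = PhantomSpec(**d.get("phantom", {}))
        d["mask"] = MaskConfig(**d.get("mask", {}))
        d["recon"] = ReconParams(**d.get("recon", {}))
        d["accelerations"] = tuple(d.get("accelerations", DEFAULT_ACCELERATIONS))
        return cls(**d)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from YAML."""
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh) or {})


def _mask_seed(root_seed: int, acceleration: float) -> int:
    """Per-R mask seed derived from the root seed (kept below 2**31)."""
    return (root_seed * 1009 + int(round(acceleration * 10))) % (2**31 - 1)


def _run_method(method, f, params, ground_truth) -> ReconResult:
    if method == "trims":
        return trims_reconstruct(f, params, ground_truth=ground_truth)
    if method == "ddtf":
        return ddtf_reconstruct(f, params, ground_truth=ground_truth)
    # zero-filled: no iterations, metrics reported once
    image = zero_filled_reconstruct(f)
    report = evaluate(np.abs(ground_truth), np.abs(image))
    trace = [
        {
            "outer_iter": 0,
            "psnr_db": report.psnr_db,
            "rel_err": report.rel_err,
            "ssim": report.ssim,
        }
    ]
    return ReconResult(image=image, state=None, params=params, converged=True, metrics_trace=trace)


def run_single(config: ExperimentConfig, write: bool = True) -> ReconResult:
    """Generate phantom + mask + data, reconstruct, and write artifacts.

    Writes magnitude/phase NIfTIs, the per-iteration metrics CSV, the
    mask (PNG + JSON), the learned filter bank (HDF5), and a
    ``manifest.yaml`` sufficient to regenerate the directory exactly.
    """
    truth = make_phantom(config.phantom)
    seed = _mask_seed(config.recon.seed, config.mask.acceleration)
    mask = config.mask.build(config.phantom.n, seed)
    f = simulate_acquisition(
        truth, mask, noise_sigma=config.phantom.noise_sigma, seed=config.recon.seed
    )
    result = _run_method(config.method, f, config.recon, truth)

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        save_magnitude_phase_nifti(result.image, out / "recon")
        save_magnitude_phase_nifti(truth, out / "ground_truth")
        save_mask(mask, out / "mask.png")
        write_metrics_csv(result.metrics_trace, out / "metrics.csv")
        if result.state is not None:
            save_bank(result.state.wb, out / "adaptive_bank.h5")
    return result


def run_sweep(config: ExperimentConfig, write: bool = True, plot: bool = False):
    """Reconstruct at every acceleration in ``config.accelerations``.

    Returns the summary rows (method, R, sampling ratio, final PSNR /
    relative error / SSIM) and optionally writes ``summary.csv`` and a
    metrics-versus-R figure.
    """
    if not config.accelerations:
        raise ValueError("sweep requires at least one acceleration")
    rows = []
    for r in config.accelerations:
        sub = dataclasses.replace(
            config,
            mask=dataclasses.replace(config.mask, acceleration=float(r)),
            output_dir=str(Path(config.output_dir) / f"R{r:g}"),
        )
        result = run_single(sub, write=write)
        final = result.metrics_trace[-1]
        rows.append(
            {
                "method": config.method,
                "acceleration": float(r),
                "sampling_ratio": result_sampling_ratio(sub),
                "psnr_db": final["psnr_db"],
                "rel_err": final["rel_err"],
                "ssim": final["ssim"],
            }
        )
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        columns = ["method", "acceleration", "sampling_ratio", "psnr_db", "rel_err", "ssim"]
        with open(out / "summary.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns)
            for row in rows:
                writer.writerow(
                    [repr(row[c]) if isinstance(row[c], float) else row[c] for c in columns]
                )
        if plot:
            _plot_sweep(rows, out / "sweep.png")
    return rows


def result_sampling_ratio(config: ExperimentConfig) -> float:
    """Realized sampling ratio of the mask a config would generate."""
    seed = _mask_seed(config.recon.seed, config.mask.acceleration)
    return config.mask.build(config.phantom.n, seed).sampling_ratio


def _plot_sweep(rows: list[dict], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rs = [row["acceleration"] for row in rows]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, key, label in zip(
        axes, ("psnr_db", "rel_err", "ssim"), ("PSNR (dB)", "relative error", "SSIM")
    ):
        ax.plot(rs, [row[key] for row in rows], "o-")
        ax.set_xlabel("acceleration factor R")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
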