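"""Quality versus acceleration factor: the sensitivity sweep.

Reconstructs the same phantom at R = 2.5, 4, 6, 8 and 10 and tabulates
PSNR / relative error / SSIM per R — more acceleration means less data and
lower quality; the sweep quantifies the trade-off.
Uses a 64x64 grid and reduced iteration counts to stay quick.
"""

from trims.experiments import ExperimentConfig, MaskConfig, run_sweep
from trims.phantoms import PhantomSpec
from trims.solver import ReconParams

config = ExperimentConfig(
    phantom=PhantomSpec(n=64, seed=1),
    mask=MaskConfig(scheme="variable_density_2d"),
    method="trims",
    recon=ReconParams(n_outer=5, n_mid=2, n_inner=3),
    output_dir="scratch/sweep_example",
    accelerations=(2.5, 4.0, 6.0, 8.0, 10.0),
)
rows = run_sweep(config, write=False)
print(f"{'R':>5}{'ratio':>8}{'PSNR (dB)':>11}{'rel err':>9}{'SSIM':>7}")
for row in rows:
    print(f"{row['acceleration']:>5.1f}{row['sampling_ratio']:>8.3f}"
          f"{row['psnr_db']:>11.2f}{row['rel_err']:>9.4f}{row['ssim']:>7.3f}")
# PSNR falls and relative error rises with R: the cost of faster scanning.
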