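"""Stride-length estimation by drift-corrected double integration.

Builds a foot trajectory with exactly known per-cycle stride lengths,
injects a constant accelerometer bias, and shows that the zero-velocity
update (velocity forced to zero at each foot strike, linear drift
subtracted) keeps the error far below the 10% level at which the method is
considered usable.
"""

import numpy as np

from fogkit import SyntheticConfig, generate_trajectory, stride_length

cfg = SyntheticConfig(
    stride_length_mean=1.2, stride_length_sd=0.1, noise_sd=0.0, seed=11
)
recording, truth = generate_trajectory(cfg, accel_bias=0.05, n_cycles=50)
estimates = stride_length(recording, truth.step_times["left"], axis="x")

errors = np.abs(estimates - truth.stride_lengths) / truth.stride_lengths
print(f"true strides : {truth.stride_lengths[:5].round(3)} ... (50 cycles)")
print(f"estimates    : {estimates[:5].round(3)} ...")
print(f"mean abs error: {100 * errors.mean():.2f}% (bias 0.05 m/s^2 injected)")
print(
    "\nThe bias would accumulate to metres of spurious displacement per"
    "\ncycle without correction; the per-cycle ZUPT removes a constant"
    "\nbias exactly, leaving only quadrature error."
)
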