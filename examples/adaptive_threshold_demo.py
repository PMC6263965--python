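"""The two building blocks, in isolation.

1. Sliding-window segmentation: a rising force ramp is declared
   "continuous ascending" once 36 of the last 38 differences are
   positive; pure noise never escapes the unstable area.
2. CFAR threshold: from unstable-area (off-ground) samples the Rayleigh
   scale is estimated via sigma = mean * sqrt(2/pi) and the threshold
   T = sigma * sqrt(-2 ln p) makes noise exceed T with probability p.
"""

import numpy as np

from gaitcfar import (
    CfarParams,
    WindowParams,
    compute_threshold,
    estimate_sigma,
    label_series,
    resolve_pf,
    simulate_off_ground_noise,
)

params = WindowParams()  # asc 35/38, desc 36/40

ramp = np.linspace(0, 40, 300)
labels, events = label_series(ramp, params)
print(f"rising ramp: declared ascending at sample {events[0][0]} "
      f"(lag = limit + 1 = {params.asc_limit + 1} differences)")

noise = simulate_off_ground_noise(100_000, sigma=0.3, seed=1)
labels, events = label_series(noise, params)
print(f"100k off-ground noise samples: {len(events)} escapes from the unstable area")

sigma = estimate_sigma(noise)
p = resolve_pf(CfarParams())  # default false-alarm gain 20.5 -> p = 1/20.5
T = compute_threshold(sigma, p)
print(f"estimated sigma = {sigma:.4f} kgf (true 0.3)")
print(f"threshold T = {T:.4f} kgf at p = {p:.4f}")
print(f"fraction of noise above T = {np.mean(noise >= T):.4f} (nominal {p:.4f})")
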