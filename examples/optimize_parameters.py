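"""Traversing (exhaustive) parameter search.

Window sizes/limits are scored by the testing probability — the fraction
of known off-ground samples misclassified into a continuous area — and
the smallest zero-probability combination wins.  The false-alarm gain is
scored by mean agreement against reference-labelled training data.
"""

import logging

from gaitcfar import (
    SyntheticGaitSpec,
    grid_search_pf,
    grid_search_windows,
    simulate_off_ground_noise,
    simulate_recording,
)

logging.getLogger("gaitcfar.cfar").setLevel(logging.ERROR)

noise = simulate_off_ground_noise(200_000, sigma=0.3, seed=3)
result = grid_search_windows(
    noise,
    asc_limits=range(33, 38),
    asc_sizes=range(36, 41),
    desc_limits=range(34, 39),
    desc_sizes=range(38, 43),
)
print(f"window grid: {len(result.grid)} admissible combos, "
      f"{len(result.zero_set)} with zero testing probability")
s = result.selected
print(f"selected (smallest zero-probability combo): "
      f"asc {s.asc_limit}/{s.asc_size}, desc {s.desc_limit}/{s.desc_size}")

# a deliberately noisy trial (sigma = 4 kgf) so the gain actually matters:
# too small a gain lets noise cross the threshold, too large a gain clips
# the force humps late
lab = simulate_recording(
    SyntheticGaitSpec(speed_kmh=4.0, duration_s=8.0, fs=500.0, seed=4, noise_sigma_kgf=4.0)
)
best, table = grid_search_pf([(lab.recording, lab.truth)], pf_grid=[1.2, 2, 5, 20.5, 200, 5000])
print("\nfalse-alarm gain search (agreement vs reference labels):")
print(table.to_string(index=False))
print(f"best gain: {best:g} (threshold multiplier grows with the gain)")
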