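"""Cultural drift: smaller populations fluctuate and fix faster.

Tracks the frequency of one of two variants (initial frequency 0.5, no
innovation) in populations of different sizes. Drift is stronger in small
populations: trajectories hit 0 or 1 quickly, and fixation or loss are
equally likely.
"""

import numpy as np

from cultne import drift_trajectory

rng = np.random.default_rng(1)

for N in (10, 100, 1000):
    fixed = lost = 0
    absorbed_at = []
    for _ in range(500):
        f = drift_trajectory(N, 0.5, 100, rng)
        if f[-1] == 1.0:
            fixed += 1
        elif f[-1] == 0.0:
            lost += 1
        hit = np.flatnonzero((f == 0) | (f == 1))
        if hit.size:
            absorbed_at.append(hit[0])
    mean_t = np.mean(absorbed_at) if absorbed_at else float("nan")
    print(f"N={N:5d}: fixed {fixed:3d}/500, lost {lost:3d}/500, "
          f"absorbed {len(absorbed_at)}/500 within 100 generations "
          f"(mean absorption time {mean_t:.0f})")

print("Fixation and loss are symmetric from a 0.5 start; larger populations")
print("drift more slowly and rarely absorb within 100 generations.")
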