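"""Framewise displacement, spike flagging and the retention rule.

FD follows Jenkinson's RMS formulation: the frame-to-frame rigid
transform is averaged over an 80 mm sphere, so rotations and translations
land on one mm scale.  Volumes with FD > 0.2 mm get a spike regressor;
subjects with less than 4 minutes of clean data are excluded.
"""

import numpy as np

from mstconnect import (
    compute_fd_jenkinson,
    flag_spikes,
    build_spike_regressors,
    retention_decision,
)
from mstconnect.synthetic import simulate_motion

params = simulate_motion(n_volumes=310, scale=1.3, spike_rate=0.05, seed=7)
fd = compute_fd_jenkinson(params, head_radius=80.0)
flags = flag_spikes(fd, threshold=0.2)
spikes = build_spike_regressors(flags)
n_retained = int(len(fd) - flags.sum())
keep = retention_decision(n_retained, tr_seconds=1.6, min_minutes=4.0)

print(f"volumes: {len(fd)}, median FD {np.median(fd):.3f} mm, max FD {fd.max():.3f} mm")
print(f"flagged volumes (FD > 0.2 mm): {int(flags.sum())} -> {spikes.shape[1]} spike regressors")
print(f"retained {n_retained} volumes = {n_retained * 1.6:.0f} s -> {'keep' if keep else 'exclude'}")
# A pure-rotation example: a 0.01 rad z-rotation at 80 mm head radius is
# 80 * sqrt(4 (1 - cos 0.01) / 5) ~ 0.506 mm of RMS displacement.
p = np.zeros((2, 6))
p[1, 5] = 0.01
print(f"FD of a 0.01 rad z-rotation: {compute_fd_jenkinson(p)[1]:.4f} mm")
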