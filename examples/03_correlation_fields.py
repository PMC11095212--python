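"""Spatial correlation fields of a stream: polar vs nematic order.

For every same-frame cell pair the neighbor's position is expressed in the
focal cell's frame (front = heading, left = heading + 90 deg). The polar map
averages cos(dtheta): near zero in a balanced stream because antiparallel
pairs cancel parallel ones. The nematic map averages cos(2*dtheta): near +1,
exposing the bidirectional order that the polar statistic hides.
"""

import numpy as np

from oncomotion import (
    SyntheticRegimeConfig, build_pairs, compute_kinematics,
    nematic_correlation_map, polar_correlation_map, relative_position_map,
    simulate,
)

cfg = SyntheticRegimeConfig(regime="stream", n_cells=150, n_frames=60,
                            angular_noise_sigma_rad=0.3, seed=11)
tracks, _ = simulate(cfg)
samples = compute_kinematics(tracks, cfg.meta)
pairs = build_pairs(samples, r_max_um=150.0)
print(f"{len(pairs)} ordered same-frame pairs within 150 um")

polar = polar_correlation_map(pairs)     # extent +-100 um, 5 um bins
nematic = nematic_correlation_map(pairs)
relpos = relative_position_map(pairs)

c = nematic.centers
near_axis = (np.abs(c) <= 30)[:, None] & (np.abs(c) <= 10)[None, :]
print(f"near-axis polar mean   {np.nanmean(polar.stat[near_axis]):+.3f}  (~0: directions cancel)")
print(f"near-axis nematic mean {np.nanmean(nematic.stat[near_axis]):+.3f}  (>0.75: shared axis)")
print(f"relative-position map sums to {relpos.stat.sum():.12f}")
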