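"""Generate a synthetic stream movie and classify its migration pattern.

A "stream" is the bidirectional collective mode: half the cells move along
an axis, half against it. The classifier fits three circular models to the
pooled heading angles and reports Akaike weights; a weight near 1 is a
decisive call.
"""

from oncomotion import SyntheticRegimeConfig, classify, compute_kinematics, simulate

cfg = SyntheticRegimeConfig(
    regime="stream", n_cells=150, n_frames=60, frame_interval_min=10.0,
    mean_speed_um_per_h=12.0, angular_noise_sigma_rad=0.3, seed=7,
)
tracks, truth = simulate(cfg)
print(f"simulated {len(tracks)} tracks x {cfg.n_frames} frames ({cfg.regime})")

samples = compute_kinematics(tracks, cfg.meta)
print(f"kinematics table: {len(samples)} cell-time samples, "
      f"mean speed {samples.speed_um_per_h.mean():.2f} um/h")

result = classify(samples.theta_rad.dropna().to_numpy())
print(f"\nlabel: {result.label} (decisive: {result.decisive})")
for fit in result.fits:
    mu = f"{fit.mu_rad:.3f}" if fit.mu_rad is not None else "  -  "
    print(f"  {fit.model:6s} AW={fit.akaike_weight:.4f}  mu={mu}  AIC={fit.aic:.1f}")
# The stream model should carry essentially all the Akaike weight, and its
# fitted axis should sit near the generator's 0 rad base direction.
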