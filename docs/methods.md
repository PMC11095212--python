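# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `oncomotion`, in the order the pipeline applies them.

## Track ingest and retention

Input is the Spots table of the Fiji TrackMate CSV dialect (`TRACK_ID`,
`FRAME`, `POSITION_X`, `POSITION_Y`); the v7 variant with up to three
auxiliary header rows is auto-detected by attempting a numeric parse of the
rows after the header. Positions may arrive in pixels (converted with the
pixel size, 0.415 µm for the 20× setup this emulates) or in µm (dialect
flag). Frames are 0-based; time is `t = frame × Δt` with Δt the frame
interval in minutes (typical acquisitions: 10, 5 or 1.5 min). Tracks with
fewer than `min_points = 10` samples are discarded — short tracks are
dominated by detection noise and linking errors. "At least 10" is read
inclusively: a 10-spot track survives.

Duplicate (track, frame) pairs are a hard error; non-monotone frames are
repaired by sorting (logged). Any z coordinate is ignored: the analysis is
strictly 2-D. Zones of interest come from a `coordinates.json` file
(axis-aligned rectangles or general polygons, vertices in µm, unique names);
point-in-zone tests are boundary-inclusive, ties broken by file order.
Polygon geometry is delegated to shapely.

## Smoothing and kinematics

Coordinates are smoothed with a discrete Gaussian kernel,
`w_k ∝ exp(−k²/2σ²)` for `k = −h..h`, default σ = 2 frames over a 9-point
stencil (h = 4, i.e. ±2σ). σ is dimensionless in frame units: the stencil
pairs with σ to cover ±2σ in samples regardless of Δt. At track ends the
truncated window is renormalized to unit mass — no padding, no shortening —
so per-frame statistics stay aligned across cells. Constant tracks are
preserved exactly; affine tracks are preserved away from the ends (kernel
symmetry).

Velocities are central differences on the smoothed positions,
`v(tᵢ) = (x_{i+1} − x_{i−1}) / (t_{i+1} − t_{i−1})`, one-sided at the ends,
scaled to µm h⁻¹. Smoothing before differencing is deliberate: raw
single-particle positions carry detection jitter that differencing would
amplify. Headings are θ = atan2(v_y, v_x) ∈ (−π, π]; zero-speed samples get
θ = NaN and are excluded from all angular statistics (their count is
reported).

Detection gaps: a single missed frame is bridged (the true time difference
enters the velocity denominator); gaps of two or more frames split the
track, and each segment is re-checked against `min_points`. Bridging across
long gaps would manufacture spuriously straight, fast steps.

## Pattern classification

Pooled per-sample headings within a window/zone (no per-cell averaging) are
fit by maximum likelihood to three circular models: wrapped normal (flock,
2 parameters), equal-weight antiparallel wrapped-normal mixture with shared
σ (stream, 2 parameters, axis identifiable mod π), and uniform (swarm,
0 parameters, log-likelihood −n ln 2π in closed form). AIC = 2k − 2ℓ and
Akaike weights `exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)` rank the models; the label is the
argmax weight, "decisive" flags a weight ≥ 0.9, and a tie within 1e-9
returns "indeterminate".

Numerics of the wrapped normal: for σ < 1.5 the Gaussian-image sum is used
with the image count chosen so the neglected tail is below 1e-12; for larger
σ the Fourier series `(1/2π)(1 + 2Σ_p e^{−σ²p²/2} cos p(θ−μ))` converges in
a handful of terms and is used instead. Both branches agree to machine
precision at the crossover.

Optimization is L-BFGS-B over (μ, log σ), initialized at the circular mean
and circular standard deviation √(−2 ln R̄); the stream fit additionally
starts from the doubled-angle axial mean `½ arg Σ e^{2iθ}` plus eight
deterministic restarts on a μ grid over [0, π), since the mixture likelihood
can be multimodal in μ. Everything is deterministic given the data.

Dispersion is constrained to σ ∈ [1e-3, 2] for the flock model and
σ ∈ [1e-3, 1] for the stream model. The floor avoids degenerate spikes. The
caps are essential, not cosmetic: as σ → ∞ both peaked models converge to
the uniform density, so without a cap their maximized likelihood can never
fall below the swarm model's and genuinely disordered headings could never
receive a decisive swarm weight. Each cap is placed where the model's order
parameter on its own harmonic (e^{−σ²/2} for the flock peak, e^{−2σ²} for
the stream's antiparallel pair) drops to e⁻² ≈ 0.14 — beyond that the
"pattern" the model claims is no longer visually or physically meaningful,
and the uniform model is the honest description. A consequence embraced as
correct behavior: data drawn from a very dispersed unimodal law (σ ≈ 3) is
labeled swarm.

AIC rather than AICc: per-zone heading counts are in the hundreds to
thousands, where the small-sample correction is negligible. A caveat stated
plainly: pooled headings are serially correlated within a cell (smoothing
alone correlates ~9 neighboring frames), while the likelihood treats them
as independent. This inflates evidence against the uniform model in very
short windows; analysis windows of ≥ 6 h at 10-min sampling keep the effect
well below the decision threshold (measured in the test suite), and shorter
windows should be interpreted with care.

## Spatial correlation fields

For each ordered same-frame pair (i, j) with both headings defined and
separation ≤ `r_max` (default 150 µm, configurable to ∞), the neighbor
offset is rotated into the focal frame: front = component along the focal
heading, left = component along the heading rotated +90° (mathematical
orientation, applied consistently to image coordinates). Δθ = θⱼ − θᵢ
wrapped to (−π, π]. Pairs pool over all frames of the window (and zone, when
given).

Grids default to ±100 µm extent at 5 µm bins with `min_count = 10` per bin
(covering several cell diameters at meaningful occupancy; a cell is ≈ 20 µm,
the default annotation radius 10 µm being half the detector blob size).
Three statistics share identical pair sets and count grids: polar
correlation (bin mean of cos Δθ), nematic correlation (bin mean of cos 2Δθ;
+1 for parallel *and* antiparallel pairs, the stream signature), and the
relative-position frequency map, normalized by total in-grid pairs (a
per-µm² density variant is available behind a flag). Velocity-vector
histograms bin (v_x, v_y) over all cell-time samples, normalized to total
frequency 1, with out-of-range samples clipped into edge bins. All four
fields are invariant under global rigid rotation, asserted numerically in
the tests.

## Synthetic data generator

The generator emulates 2-D adherent-cell tracks at the acquisition settings
above (default field 850.19 × 850.19 µm, Δt = 10 min, pixel 0.415 µm) with
prescribed — not emergent — heading statistics, because tests need exact
ground truth. An optional Vicsek-style alignment interaction was considered
and rejected for the default path for that reason.

Per cell: a base heading (flock — the shared μ; stream — μ or μ+π, assigned
to a uniformly random half of cells; swarm — uniform), plus angular noise.
Flock/stream noise is a stationary AR(1) process with marginal sd
`angular_noise_sigma_rad` (default 0.3) and fixed per-frame autocorrelation
0.7 — headings fluctuate with short memory but keep the regime's marginal
law. Swarm headings follow a wrapped random walk with uniform initial
condition and a large per-frame step (`swarm_diffusion_rad_per_frame`,
default 2.0 — cells repolarize within about one frame, as disordered
migration shows); the uniform law is exactly stationary under additive
circular noise, and the fast mixing keeps one cell's successive headings
nearly independent, which is what makes pooled-likelihood classification of
swarms well behaved.

Speeds are lognormal with mean `mean_speed_um_per_h` (default 12, in the
range reported for dense glioma cultures) and coefficient of variation 0.3 —
right-skewed and positive like measured speed histograms. Zero noise and
zero cv produce exactly straight tracks at exactly the mean speed.
Boundaries reflect (dish geometry): positions fold back and the base
heading mirrors. Detections drop independently with a configurable
probability (≤ 0.5). Everything is deterministic given the seed; identical
configs yield byte-identical fixtures, written in the same CSV dialect the
ingest module reads (positions in pixels), plus a ground-truth JSON and a
config echo.

`density_series` maps cell densities to regimes (default: at or below the
range midpoint → swarm, above → stream), emulating the observed low-density
dispersal vs high-density bidirectional organization at desk scale (50 vs
400 cells in-field rather than 10⁵-scale seeding); per-fixture seeds are
`base seed + index`. Perturbation events switch regime, mean speed, or
angular noise at a given frame, emulating treatment additions mid-movie.

## Pipeline and reporting

A run is a YAML-loadable `RunConfig`. Windows are closed-open [t₀, t₁) in
hours and must not overlap; zone membership is evaluated per sample, so one
track can contribute to several zones over time (matching pooled per-zone
heading analysis). Each (window, zone) cell reports track/sample counts,
pooled mean speed, the ranked three-model classification, and optionally the
four gridded fields (CSV matrix + JSON sidecar per statistic). Reports carry
a SHA-256 hash of the canonical config serialization and the package
version; no timestamps enter the report, so re-runs are byte-comparable.
`compare_runs` aligns two reports cell-by-cell and returns mean-speed deltas
and label changes, for untreated-vs-treated style contrasts.

## What the synthetic tests do and do not show

Passing tests demonstrate that the estimators recover known ground truth
under the generator's assumptions: prescribed heading laws, lognormal
speeds, independent dropout, reflecting walls, no cell division, death,
shape change, or cell-cell mechanics. Real movies violate several of these
(interacting cells, drift, segmentation errors, density inhomogeneity), so
test recovery rates are an upper bound on real-data performance, not an
estimate of it. Quantities reported by the acceptance script are computed at
desk scale — e.g. 12 simulated movies per regime at 150 cells × 60 frames,
chosen as the package's own standard problem size — and regenerate from
scratch on every run.

## Known limitations

- Classification assumes iid headings; heavily autocorrelated short windows
  overstate evidence (see above).
- The stream model fixes the mixture at 50/50; strongly unbalanced
  bidirectional flows will drift toward the flock model.
- Only three candidate models; no time-resolved hidden-state segmentation.
- 2-D only; no time-lagged correlations; no continuum (Toner–Tu) fits.
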