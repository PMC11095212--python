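# oncomotion

Trajectory analytics for collective cell migration in time-lapse microscopy,
built around the quantitative phenotype of **oncostreams** — elongated,
fascicle-like assemblies of glioma cells that migrate bidirectionally along a
shared axis. The package takes single-particle tracking exports (the Fiji
TrackMate CSV dialect), reconstructs per-cell kinematics, and answers the
question *how* a population moves: as a **flock** (one shared direction), a
**stream** (two antiparallel directions — the oncostream signature), or a
**swarm** (no preferred direction).

## What it computes

Each cell *i* contributes a velocity **v**ᵢ = c (cos θ, sin θ), with speed
*c* and heading θ estimated by central differences on positions smoothed with
a discrete Gaussian kernel (σ = 2 frames, 9-point stencil). Pooled headings
within a zone or time window are then fit by maximum likelihood to three
circular models:

- flock — wrapped normal `f(θ) = Σₖ N(θ + 2πk; μ, σ²)`, 2 parameters;
- stream — symmetrized wrapped normal `½ f_WN(θ; μ, σ) + ½ f_WN(θ; μ+π, σ)`,
  2 parameters, axis μ ∈ [0, π);
- swarm — uniform `1/2π`, 0 parameters.

Models are compared with Akaike weights
`AWᵢ = exp(−Δᵢ/2) / Σⱼ exp(−Δⱼ/2)`, `Δᵢ = AICᵢ − min AIC`; a weight near 1
is a decisive call. Spatial organization is mapped in the focal cell's frame
(front = heading, left = heading + 90°): the polar correlation `⟨cos Δθ⟩`
and the nematic correlation `⟨cos 2Δθ⟩` per relative-position bin, plus
neighbor relative-position frequency maps and velocity-vector histograms.
A self-propelled-particle generator produces movies in all three regimes
with known ground truth, so the whole pipeline is testable without
microscopy data.

## Worked example

```python
from oncomotion import SyntheticRegimeConfig, classify, compute_kinematics, simulate

cfg = SyntheticRegimeConfig(regime="stream", n_cells=150, n_frames=60,
                            frame_interval_min=10.0, mean_speed_um_per_h=12.0,
                            angular_noise_sigma_rad=0.3, seed=7)
tracks, truth = simulate(cfg)
samples = compute_kinematics(tracks, cfg.meta)
result = classify(samples.theta_rad.dropna().to_numpy())
print(result.label, result.best.akaike_weight)
```

Running this (it is `examples/01_simulate_and_classify.py`) prints:

```
simulated 150 tracks x 60 frames (stream)
kinematics table: 9000 cell-time samples, mean speed 11.10 um/h
label: stream (decisive: True)
  stream AW=1.0000  mu=3.137  AIC=11446.2
  flock  AW=0.0000  mu=1.772  AIC=33083.8
  swarm  AW=0.0000  mu=  -    AIC=33081.8
```

The stream model takes essentially all the Akaike weight and recovers the
generator's migration axis (3.137 ≡ 0 mod π, the axis is π-periodic). The
mean speed sits just under the generator's 12 µm h⁻¹ because smoothing
attenuates per-frame heading noise. The other examples walk the CSV
ingest/filter stages, the correlation fields, the windowed zone pipeline,
and the seeding-density contrast (sparse cultures swarm, dense cultures
stream).

There is also a thin CLI:

```bash
oncomotion simulate --regime stream --n-cells 150 --frames 60 --seed 7 --out movie/
oncomotion run --config run.yaml
oncomotion classify --input out/kinematics.csv --zones coordinates.json
```

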