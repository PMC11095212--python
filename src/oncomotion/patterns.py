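"""Classification of collective-migration patterns from heading angles.

Pooled heading angles θ within a zone are fit by maximum likelihood to three
circular models and compared with Akaike weights:

* **flock** — wrapped normal (a single preferred direction), 2 parameters
  (mean heading μ, dispersion σ);
* **stream** — symmetrized wrapped normal, the equal mixture
  ½ f_WN(θ; μ, σ) + ½ f_WN(θ; μ+π, σ), i.e. two antiparallel peaks sharing
  a dispersion, 2 parameters (axis μ ∈ [0, π), σ);
* **swarm** — the uniform density 1/(2π) on the circle, 0 parameters.

The peaked models' dispersion is constrained (flock σ ≤ 2, stream σ ≤ 1,
floor 1e-3 rad): the floor avoids degenerate likelihood spikes and the caps
keep flock/stream identifiable against the uniform alternative — at the cap
each model's order parameter is e⁻² ≈ 0.14, essentially no preferred
orientation — so genuinely disordered headings are credited to the swarm
model instead of an arbitrarily flat "peaked" fit.

With AIC_i = 2k_i − 2ℓ_i and Δ_i = AIC_i − min_j AIC_j, the Akaike weight is
AW_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2); the label is the argmax weight, and a
maximum weight ≥ 0.9 is flagged decisive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "AngularModelFit",
    "ClassificationResult",
    "wrapped_normal_pdf",
    "density_flock",
    "density_stream",
    "fit_flock",
    "fit_stream",
    "fit_swarm",
    "akaike_weights",
    "classify",
]

TWO_PI = 2.0 * math.pi
SIGMA_FLOOR = 1e-3  # rad; avoids degenerate likelihood spikes
# Dispersion caps for the peaked models. Without a cap the wrapped normal
# nests the uniform density (sigma -> inf), the flock/stream MLE
# log-likelihood can never fall below the swarm's, and uniform headings
# could never earn a decisive swarm weight. Each model keeps its relevant
# order parameter e^{-(k sigma)^2/2} above e^-2 (k = harmonic carrying the
# pattern: 1 for the flock peak, 2 for the stream's antiparallel pair), so
# fits at the cap still encode a real orientation and anything more
# dispersed is credited to the uniform model.
SIGMA_MAX_FLOCK = 2.0
SIGMA_MAX_STREAM = 1.0
_TAIL_TOL = 1e-12
# Direct Gaussian-image sum converges fast for small sigma, the Fourier
# (Jacobi-theta) series for large sigma; crossover near sigma = 1.5.
_SERIES_CROSSOVER = 1.5


@dataclass(frozen=True)
class AngularModelFit:
    """One fitted circular model with its information-criterion bookkeeping."""

    model: str  # "flock" | "stream" | "swarm"
    mu_rad: float | None
    sigma_rad: float | None
    loglik: float
    n_params: int
    aic: float
    akaike_weight: float | None = None


@dataclass(frozen=True)
class ClassificationResult:
    label: str  # "flock" | "stream" | "swarm" | "indeterminate"
    fits: tuple[AngularModelFit, ...]  # ranked by descending weight
    n: int
    decisive: bool  # max Akaike weight >= 0.9

    @property
    def best(self) -> AngularModelFit:
        return self.fits[0]


def wrapped_normal_pdf(theta, mu: float, sigma: float):
    """Wrapped normal density on the circle.

    For sigma below ~1.5 the density is summed over Gaussian images
    f(θ) = Σ_k N(θ − 2πk; μ, σ²) with K adapted so the neglected tail is
    below 1e-12; for larger sigma the Fourier series
    f(θ) = (1/2π)(1 + 2 Σ_p e^{−σ²p²/2} cos p(θ−μ)) converges in a few
    terms and is used instead. Both integrate to 1 over (−π, π].
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    theta = np.asarray(theta, dtype=float)
    d = np.mod(theta - mu + math.pi, TWO_PI) - math.pi  # wrap to (-pi, pi]
    if sigma < _SERIES_CROSSOVER:
        # images beyond |d + 2πk| > sigma*sqrt(2 ln(1/tol)) are negligible
        reach = sigma * math.sqrt(-2.0 * math.log(_TAIL_TOL))
        K = max(1, int(math.ceil((reach + math.pi) / TWO_PI)))
        k = np.arange(-K, K + 1)
        z = d[..., None] + TWO_PI * k
        out = np.exp(-(z**2) / (2.0 * sigma**2)).sum(axis=-1) / (sigma * math.sqrt(TWO_PI))
    else:
        P = max(1, int(math.ceil(math.sqrt(-2.0 * math.log(_TAIL_TOL)) / sigma)))
        p = np.arange(1, P + 1)
        out = (1.0 + 2.0 * (np.exp(-0.5 * (sigma * p) ** 2) * np.cos(d[..., None] * p)).sum(axis=-1)) / TWO_PI
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def density_flock(theta, mu: float, sigma: float):
    """Unimodal (wrapped normal) heading density — the flock model."""
    return wrapped_normal_pdf(theta, mu, sigma)


def density_stream(theta, mu: float, sigma: float):
    """Bimodal antiparallel heading density — the stream model.

    Equal mixture of wrapped normals at μ and μ+π with shared σ; π-periodic,
    so the axis parameter lives in [0, π).
    """
    return 0.5 * wrapped_normal_pdf(theta, mu, sigma) + 0.5 * wrapped_normal_pdf(
        theta, mu + math.pi, sigma
    )


def _check_sample(thetas) -> np.ndarray:
    t = np.asarray(thetas, dtype=float).ravel()
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite headings")
    return t


def _circular_mean_and_R(t: np.ndarray) -> tuple[float, float]:
    z = np.exp(1j * t).mean()
    return float(np.angle(z)), float(np.abs(z))


def _sigma_from_R(R: float, sigma_max: float) -> float:
    # circular standard deviation sqrt(-2 ln R), clipped away from 0/inf
    R = min(max(R, 1e-12), 1.0 - 1e-12)
    return float(np.clip(math.sqrt(-2.0 * math.log(R)), SIGMA_FLOOR, sigma_max))


def _mle(
    density, t: np.ndarray, mu0: float, sigma0: float, sigma_max: float
) -> tuple[float, float, float]:
    def nll(params):
        mu, log_sigma = params
        f = density(t, mu, math.exp(log_sigma))
        return -np.sum(np.log(np.maximum(f, 1e-300)))

    res = optimize.minimize(
        nll,
        x0=[mu0, math.log(max(sigma0, SIGMA_FLOOR))],
        method="L-BFGS-B",
        bounds=[(mu0 - math.pi, mu0 + math.pi), (math.log(SIGMA_FLOOR), math.log(sigma_max))],
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"circular MLE failed: {res.message}; last iterate {res.x}")
    mu, log_sigma = res.x
    return float(mu), float(math.exp(log_sigma)), float(-res.fun)


def fit_flock(thetas) -> AngularModelFit:
    """Maximum-likelihood wrapped-normal fit (single preferred direction).

    Initialized at the circular mean and circular standard deviation
    sqrt(−2 ln R̄) of the sample.
    """
    t = _check_sample(thetas)
    mu0, R = _circular_mean_and_R(t)
    mu, sigma, ll = _mle(density_flock, t, mu0, _sigma_from_R(R, SIGMA_MAX_FLOCK), SIGMA_MAX_FLOCK)
    mu = float(np.mod(mu + math.pi, TWO_PI) - math.pi)  # report in (-pi, pi]
    return AngularModelFit("flock", mu, sigma, ll, 2, 2 * 2 - 2 * ll)


def fit_stream(thetas, n_restarts: int = 8) -> AngularModelFit:
    """Maximum-likelihood symmetrized wrapped-normal fit (antiparallel axis).

    Initialized from the doubled-angle (axial) circular mean
    ½·arg Σ e^{2iθ}, with additional deterministic restarts on a μ grid over
    [0, π) to escape local optima of the mixture likelihood.
    """
    t = _check_sample(thetas)
    z2 = np.exp(2j * t).mean()
    mu0 = float(np.angle(z2)) / 2.0 % math.pi
    sigma0 = min(_sigma_from_R(float(np.abs(z2)), 2.0) / 2.0, SIGMA_MAX_STREAM)
    starts = [mu0] + [k * math.pi / n_restarts for k in range(n_restarts)]
    best: tuple[float, float, float] | None = None
    for m0 in starts:
        cand = _mle(density_stream, t, m0, max(sigma0, 0.05), SIGMA_MAX_STREAM)
        if best is None or cand[2] > best[2]:
            best = cand
    mu, sigma, ll = best
    mu = mu % math.pi  # axis identifiable only mod pi
    return AngularModelFit("stream", mu, sigma, ll, 2, 2 * 2 - 2 * ll)


def fit_swarm(thetas) -> AngularModelFit:
    """Uniform-heading model: closed form, loglik = −n ln 2π, no parameters."""
    t = _check_sample(thetas)
    ll = -t.size * math.log(TWO_PI)
    return AngularModelFit("swarm", None, None, ll, 0, -2 * ll)


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights exp(−Δ_i/2)/Σ exp(−Δ_j/2), Δ_i = AIC_i − min AIC."""
    aics = np.asarray(aics, dtype=float)
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def classify(thetas, n_min: int = 30) -> ClassificationResult:
    """Fit all three circular models and label the sample by Akaike weight.

    Requires at least ``n_min`` finite headings. The label is the model with
    the largest weight; a top weight within 1e-9 of the runner-up yields
    "indeterminate". ``decisive`` flags a top weight >= 0.9.
    """
    t = _check_sample(thetas)
    if t.size < n_min:
        raise ValueError(f"need >= {n_min} headings for classification, got {t.size}")
    fits = [fit_flock(t), fit_stream(t), fit_swarm(t)]
    w = akaike_weights([f.aic for f in fits])
    fits = [replace(f, akaike_weight=float(wi)) for f, wi in zip(fits, w)]
    fits.sort(key=lambda f: -f.akaike_weight)
    if fits[0].akaike_weight - fits[1].akaike_weight < 1e-9:
        label = "indeterminate"
    else:
        label = fits[0].model
    return ClassificationResult(label, tuple(fits), t.size, fits[0].akaike_weight >= 0.9)
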