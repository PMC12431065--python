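"""Synthetic gap cubes with the statistical structure the method assumes.

The generator emulates the operational archive the pipeline was built for:
a 5-day, ~422-step index series per pixel composed of a slow trend plus an
annual seasonal cycle, spatially clustered dynamics (contiguous zones of
pixels sharing one seasonal regime, plus AR(1) per-pixel deviations),
observation noise at the radiometric scale, and cloud-like missingness —
spatially contiguous disk-shaped blobs per date plus a few fully missing
dates — leaving roughly 38% of dates valid per pixel.

Ground truth (noise-free signal, noisy observations, cluster labels, mask)
is kept alongside the masked cube so every pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import GapCube
from .statespace import StateSpaceParams, build_state_space

__all__ = [
    "SyntheticSpec",
    "SyntheticCube",
    "simulate_truth",
    "simulate_from_statespace",
    "apply_cloud_mask",
    "make_synthetic_cube",
    "mask_series_blocks",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the synthetic cube generator."""

    ny: int = 20
    nx: int = 20
    T: int = 422
    step_days: float = 5.0
    season: int = 73  # annual cycle in 5-day steps
    n_clusters: int = 3
    base_level: float = 0.4
    seasonal_amplitude: float = 0.25
    trend_slope_per_step: float = 1.5e-4
    ar_coef: float = 0.7
    ar_scale: float = 0.03  # stationary SD of the per-pixel AR(1) deviation
    obs_noise_sd: float = 0.0104  # radiometric observation scale
    valid_fraction: float = 0.38
    blob_radius: float = 5.0  # mean cloud-disk radius in pixels
    partial_fraction: float = 0.15  # share of dates with partial (blob) cover
    partial_valid: float = 0.5  # per-pixel valid probability on partial dates
    n_full_missing: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.valid_fraction < 1.0):
            raise ValueError("valid_fraction must lie in (0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        for name in ("ar_scale", "obs_noise_sd", "seasonal_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticCube:
    """Generator output: masked cube plus full ground truth."""

    cube: GapCube  # masked noisy observations
    truth: np.ndarray  # (T, ny, nx) noise-free signal
    observations: np.ndarray  # (T, ny, nx) truth + observation noise, gap-free
    labels: np.ndarray  # (ny, nx) true cluster label per pixel
    mask: np.ndarray  # (T, ny, nx) True where the cube kept the value


def simulate_truth(spec: SyntheticSpec, seed: int | None = None):
    """Noise-free spatio-temporal signal plus true cluster labels.

    Cluster zones are nearest-centre (Voronoi) regions of random centres, so
    they are spatially contiguous. Each cluster has its own seasonal phase
    (evenly spaced around the cycle), amplitude and trend perturbation; each
    pixel adds a stationary AR(1) deviation around its cluster signal.
    Returns ``(truth, labels)``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ny, nx, T = spec.ny, spec.nx, spec.T
    K = spec.n_clusters

    centres = np.column_stack([rng.uniform(0, ny, K), rng.uniform(0, nx, K)])
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy[..., None] - centres[:, 0]) ** 2 + (xx[..., None] - centres[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1)

    t = np.arange(T)
    phases = 2.0 * np.pi * np.arange(K) / K
    amps = spec.seasonal_amplitude * rng.uniform(0.8, 1.2, K)
    slopes = spec.trend_slope_per_step * rng.uniform(0.5, 1.5, K) * rng.choice([-1, 1], K)
    cluster_signal = np.empty((K, T))
    for k in range(K):
        cluster_signal[k] = (
            spec.base_level
            + slopes[k] * (t - T / 2)
            + amps[k] * np.sin(2.0 * np.pi * t / spec.season + phases[k])
        )

    truth = np.empty((T, ny, nx))
    innov_sd = spec.ar_scale * np.sqrt(max(1.0 - spec.ar_coef**2, 0.0))
    for iy in range(ny):
        for ix in range(nx):
            dev = np.empty(T)
            dev[0] = rng.normal(0.0, spec.ar_scale) if spec.ar_scale > 0 else 0.0
            eps = rng.normal(0.0, innov_sd, T) if innov_sd > 0 else np.zeros(T)
            for i in range(1, T):
                dev[i] = spec.ar_coef * dev[i - 1] + eps[i]
            truth[:, iy, ix] = cluster_signal[labels[iy, ix]] + dev
    return np.clip(truth, -1.0, 1.0), labels


def simulate_from_statespace(
    params: StateSpaceParams,
    T: int,
    seed: int = 0,
    level0: float = 0.4,
    slope0: float = 0.0,
    seasonal_amplitude: float = 0.0,
):
    """Forward-simulate one series from the structural state-space model.

    Draws the level/slope/seasonal disturbances and the observation noise at
    the parameterised scales and iterates the transition equations. Returns
    ``(observations, states)`` where ``states`` is the (T, s+1) latent
    trajectory; the observable signal is ``states[:, 0] + states[:, 2]``.
    With all scales zero the evolution is deterministic.
    """
    rng = np.random.default_rng(seed)
    system = build_state_space(params)
    m = system.state_dim
    v1, v2, v3, v4 = params.variances()
    sd = np.sqrt([v1, v2, v3, v4])

    alpha = np.zeros(m)
    alpha[0] = level0
    alpha[1] = slope0
    if seasonal_amplitude > 0:
        # s-1 most recent values of a period-s sinusoid; any s consecutive
        # values of it sum to zero, so the recursion continues it exactly.
        j = np.arange(m - 2)
        alpha[2:] = seasonal_amplitude * np.sin(2.0 * np.pi * (-j) / params.s)

    states = np.empty((T, m))
    y = np.empty(T)
    for t in range(T):
        states[t] = alpha
        y[t] = alpha[0] + alpha[2] + (rng.normal(0.0, sd[3]) if sd[3] > 0 else 0.0)
        from .statespace import _f_dot_vec

        alpha = _f_dot_vec(alpha)
        if sd[0] > 0:
            alpha[0] += rng.normal(0.0, sd[0])
        if sd[1] > 0:
            alpha[1] += rng.normal(0.0, sd[1])
        if sd[2] > 0:
            alpha[2] += rng.normal(0.0, sd[2])
    return y, states


def mask_series_blocks(
    T: int,
    missing_fraction: float,
    mean_block: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Temporally contiguous missingness pattern for a single series.

    Draws random blocks (mean length ``mean_block`` steps) until the target
    fraction of dates is masked. Returns a boolean array, True = missing.
    """
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    missing = np.zeros(T, dtype=bool)
    target = int(round(missing_fraction * T))
    guard = 0
    while missing.sum() < target and guard < 10_000:
        guard += 1
        start = rng.integers(0, T)
        length = 1 + rng.poisson(max(mean_block - 1.0, 0.0))
        missing[start : start + length] = True
    # Trim overshoot from the last block's tail to land near the target.
    excess = missing.sum() - target
    if excess > 0:
        idx = np.nonzero(missing)[0][::-1][:excess]
        missing[idx] = False
    return missing


def apply_cloud_mask(truth: np.ndarray, spec: SyntheticSpec, seed: int | None = None):
    """Cloud-like missingness mirroring whole-tile weather plus local blobs.

    Cloud fields are usually much larger than a small study tile, so most
    dates are either clear (all pixels valid) or overcast (all missing) for
    the whole grid; a minority (``partial_fraction``) are partially covered
    by random disk blobs, and ``n_full_missing`` dates are forced fully
    missing. The clear/overcast split is calibrated so the mean per-pixel
    valid fraction lands on ``spec.valid_fraction``, and because only the
    partial dates differentiate pixels, the per-pixel valid counts stay
    tightly dispersed — the regime the weighted-correlation clustering
    expects. Raises when the target fraction is unreachable.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    T, ny, nx = truth.shape
    if spec.n_full_missing >= T:
        raise ValueError("cannot fully mask every date")
    # Valid fraction needed on the dates that are not forced fully missing:
    v_rest = spec.valid_fraction * T / (T - spec.n_full_missing)
    if v_rest >= 1.0:
        raise ValueError("target valid fraction unreachable given full-missing dates")
    p_partial = spec.partial_fraction
    p_clear = v_rest - p_partial * spec.partial_valid
    p_overcast = 1.0 - p_clear - p_partial
    if -1e-9 < p_clear < 0.0:
        p_clear = 0.0
    if -1e-9 < p_overcast < 0.0:
        p_overcast = 0.0
    if p_clear < 0.0 or p_overcast < 0.0:
        raise ValueError(
            "target valid fraction unreachable with the configured partial-date share"
        )
    # Expected disks per partial date so a pixel survives with probability
    # partial_valid. A random disk (radius factor U(0.5, 1.5), E[f^2]=13/12,
    # centre uniform over the extended domain) covers a given pixel with
    # probability a; K ~ Poisson(lam) disks leave it clear w.p. exp(-lam a).
    r = spec.blob_radius
    a = (13.0 / 12.0) * np.pi * r**2 / ((ny + 2 * r) * (nx + 2 * r))
    if a <= 0.0 and p_partial > 0.0:
        raise ValueError("zero-area blobs cannot produce partial dates")
    lam = -np.log(spec.partial_valid) / a if p_partial > 0.0 else 0.0

    mask = np.ones((T, ny, nx), dtype=bool)  # True = valid
    yy, xx = np.mgrid[0:ny, 0:nx]
    full_missing = rng.choice(T, size=spec.n_full_missing, replace=False)
    # Stratified date-type composition (0 clear, 1 overcast, 2 partial) in
    # random temporal order, so the realised valid fraction hits the target
    # instead of drifting with date-level sampling noise.
    T_rest = T - spec.n_full_missing
    n_clear = int(round(p_clear * T_rest))
    n_partial = int(round(p_partial * T_rest))
    n_clear = min(n_clear, T_rest)
    n_partial = min(n_partial, T_rest - n_clear)
    kinds_rest = np.r_[
        np.zeros(n_clear, int),
        np.full(n_partial, 2),
        np.ones(T_rest - n_clear - n_partial, int),
    ]
    rng.shuffle(kinds_rest)
    kind = np.empty(T, dtype=int)
    rest_dates = np.setdiff1d(np.arange(T), full_missing)
    kind[rest_dates] = kinds_rest
    kind[full_missing] = 1
    for t in range(T):
        if t in full_missing or kind[t] == 1:
            mask[t] = False
            continue
        if kind[t] == 0:
            continue
        for _ in range(rng.poisson(lam)):
            cy = rng.uniform(-r, ny + r)
            cx = rng.uniform(-r, nx + r)
            rr = r * rng.uniform(0.5, 1.5)
            mask[t][(yy - cy) ** 2 + (xx - cx) ** 2 <= rr * rr] = False
    return mask


def make_synthetic_cube(spec: SyntheticSpec | None = None, seed: int | None = None) -> SyntheticCube:
    """Full generator: truth, noisy observations, cloud mask, gap cube."""
    spec = spec or SyntheticSpec()
    base_seed = spec.seed if seed is None else seed
    truth, labels = simulate_truth(spec, seed=base_seed)
    rng = np.random.default_rng(base_seed + 10_000)
    noise = rng.normal(0.0, spec.obs_noise_sd, truth.shape) if spec.obs_noise_sd > 0 else 0.0
    observations = np.clip(truth + noise, -1.0, 1.0)
    mask = apply_cloud_mask(truth, spec, seed=base_seed + 20_000)
    values = np.where(mask, observations, np.nan)
    time_days = np.arange(spec.T, dtype=float) * spec.step_days
    cube = GapCube(values=values, time_days=time_days)
    return SyntheticCube(
        cube=cube, truth=truth, observations=observations, labels=labels, mask=mask
    )
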