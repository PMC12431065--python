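"""Structural state-space model and missing-data Kalman filter / RTS smoother.

The per-pixel index series is modelled as level + slope + seasonal + noise:

    y_t     = L_t + S_t + eta4,        eta4 ~ N(0, theta4^2)   (observation)
    L_{t+1} = L_t + beta_t + eta1,     eta1 ~ N(0, theta1^2)   (level)
    beta_{t+1} = beta_t + eta2,        eta2 ~ N(0, theta2^2)   (slope)
    S_{t+1} = -sum_{j=1}^{s-1} S_{t+1-j} + eta3                (seasonal)

with seasonal period ``s`` (73 steps = one year at a 5-day cadence). The
state vector is ``[L, beta, S_t, S_{t-1}, ..., S_{t-s+2}]`` of dimension
``s + 1``. Missing dates are handled by prediction-only steps, so the filter
fills whole cloud blocks while its posterior variance grows through the gap;
the RTS smoother then conditions each date on the full series.

Disturbance scales follow the operational parameterisation: the level scale
is 0.07 x-bar / 3 (an empirical NDVI-derived process level rescaled from a
15-day to a 5-day step), the slope scale one fifth of that, the seasonal
scale a fixed 0.0011, and the observation scale a fixed 0.0104 propagated
from the +/-1.5% radiometric accuracy of the L2A product. These are treated
as standard deviations and squared when building covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import GapCube

__all__ = [
    "StateSpaceParams",
    "StateSpaceSystem",
    "KFImputation",
    "derive_noise_params",
    "build_state_space",
    "kalman_filter",
    "rts_smooth",
    "smooth_series",
    "impute_kf",
    "reliability",
]

#: Default seasonal disturbance scale (fixed experimentally upstream).
THETA3_DEFAULT = 0.0011
#: Default observation-error scale propagated from radiometric accuracy.
THETA4_DEFAULT = 0.0104
#: Default relative radiometric accuracy of the reflectance product.
EPSILON_DEFAULT = 0.015
#: Annual cycle at a 5-day cadence.
SEASON_DEFAULT = 73

_INIT_VAR = 1e2  # diffuse prior variance (index^2 units)
_Z_95 = 1.959963984540054  # Gaussian 97.5% quantile


@dataclass(frozen=True)
class StateSpaceParams:
    """Disturbance scales and structure of the seasonal state-space model.

    ``theta1..theta4`` are the level, slope, seasonal and observation
    disturbance scales in index units (standard deviations unless
    ``as_variance``), ``s`` the seasonal period in time steps, ``epsilon``
    the relative radiometric accuracy used when the observation scale is
    re-derived, and ``series_mean`` the x-bar the level scale was derived
    from.
    """

    theta1: float
    theta2: float
    theta3: float = THETA3_DEFAULT
    theta4: float = THETA4_DEFAULT
    s: int = SEASON_DEFAULT
    epsilon: float = EPSILON_DEFAULT
    series_mean: float = float("nan")
    as_variance: bool = False

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3", "theta4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.s < 2:
            raise ValueError("seasonal period s must be >= 2")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")

    @property
    def state_dim(self) -> int:
        return self.s + 1

    def variances(self) -> tuple[float, float, float, float]:
        """Disturbance variances (squares of the scales unless ``as_variance``)."""
        th = (self.theta1, self.theta2, self.theta3, self.theta4)
        if self.as_variance:
            return th
        return tuple(t * t for t in th)  # type: ignore[return-value]


def derive_noise_params(
    series: np.ndarray,
    epsilon: float = EPSILON_DEFAULT,
    s: int = SEASON_DEFAULT,
    theta3: float = THETA3_DEFAULT,
    theta4: float | None = None,
    use_rms: bool = False,
    recompute_theta4: bool = False,
) -> StateSpaceParams:
    """Derive per-series disturbance scales from the observed values.

    The level scale is ``0.07 * xbar / 3`` where ``xbar`` is the mean of the
    valid observations (their root-mean-square with ``use_rms``), the slope
    scale one fifth of the level scale, and the seasonal and observation
    scales fixed constants. ``recompute_theta4`` replaces the propagated
    observation constant with ``epsilon / sqrt(2) * (1 - mean(y^2))`` — one
    reading of the radiometric propagation — instead of the default 0.0104.
    """
    series = np.asarray(series, dtype=float)
    valid = series[np.isfinite(series)]
    if valid.size < 2:
        raise ValueError("need at least 2 valid values to derive noise parameters")
    xbar = float(np.sqrt(np.mean(valid**2)) if use_rms else valid.mean())
    theta1 = 0.07 * xbar / 3.0
    theta2 = theta1 / 5.0
    if theta4 is None:
        if recompute_theta4:
            theta4 = epsilon / np.sqrt(2.0) * (1.0 - float(np.mean(valid**2)))
        else:
            theta4 = THETA4_DEFAULT
    return StateSpaceParams(
        theta1=abs(theta1),
        theta2=abs(theta2),
        theta3=theta3,
        theta4=theta4,
        s=s,
        epsilon=epsilon,
        series_mean=xbar,
    )


@dataclass
class StateSpaceSystem:
    """Matrices of the linear-Gaussian system built from the parameters."""

    transition: np.ndarray  # (m, m)
    observation: np.ndarray  # (m,)
    state_cov: np.ndarray  # (m, m) diagonal
    obs_var: float
    params: StateSpaceParams

    @property
    def state_dim(self) -> int:
        return self.transition.shape[0]


def build_state_space(params: StateSpaceParams) -> StateSpaceSystem:
    """Assemble transition matrix, observation vector and noise covariances.

    The level row implements ``L_{t+1} = L_t + beta_t``, the slope row keeps
    ``beta`` constant, the first seasonal row sums the seasonal block with a
    minus sign and the remaining seasonal rows shift it; the observation
    vector reads ``L_t + S_t``. The disturbance covariance is diagonal with
    the level, slope and seasonal variances in its first three entries.
    """
    m = params.state_dim
    s = params.s
    F = np.zeros((m, m))
    F[0, 0] = 1.0
    F[0, 1] = 1.0
    F[1, 1] = 1.0
    F[2, 2:m] = -1.0  # s-1 seasonal states
    for i in range(3, m):
        F[i, i - 1] = 1.0
    Z = np.zeros(m)
    Z[0] = 1.0
    Z[2] = 1.0
    v1, v2, v3, v4 = params.variances()
    Q = np.zeros((m, m))
    Q[0, 0], Q[1, 1], Q[2, 2] = v1, v2, v3
    return StateSpaceSystem(transition=F, observation=Z, state_cov=Q, obs_var=v4, params=params)


# -- structured products with the sparse transition matrix -----------------


def _f_dot(M: np.ndarray) -> np.ndarray:
    """F @ M using the known sparsity of the transition matrix, O(m^2)."""
    out = np.empty_like(M)
    out[0] = M[0] + M[1]
    out[1] = M[1]
    out[2] = -M[2:].sum(axis=0)
    out[3:] = M[2:-1]
    return out


def _f_dot_vec(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v)
    out[0] = v[0] + v[1]
    out[1] = v[1]
    out[2] = -v[2:].sum()
    out[3:] = v[2:-1]
    return out


def _fpft(P: np.ndarray) -> np.ndarray:
    """F @ P @ F.T for symmetric P, via two structured products."""
    A = _f_dot(P)  # F P
    return _f_dot(A.T)  # F (F P)^T = F P^T F^T = F P F^T


@dataclass
class FilterResult:
    """Forward-pass output: filtered and one-step-ahead moments per date."""

    filtered_mean: np.ndarray  # (T, m)
    filtered_cov: np.ndarray  # (T, m, m)
    predicted_mean: np.ndarray  # (T, m) prior to the update at t
    predicted_cov: np.ndarray  # (T, m, m)
    observed: np.ndarray  # (T,) bool
    system: StateSpaceSystem

    def signal_mean(self, which: str = "filtered") -> np.ndarray:
        mu = self.filtered_mean if which == "filtered" else self.predicted_mean
        return mu[:, 0] + mu[:, 2]

    def signal_var(self, which: str = "filtered") -> np.ndarray:
        P = self.filtered_cov if which == "filtered" else self.predicted_cov
        return P[:, 0, 0] + P[:, 2, 2] + 2.0 * P[:, 0, 2]


def _initial_state(
    series: np.ndarray, system: StateSpaceSystem
) -> tuple[np.ndarray, np.ndarray]:
    """Diffuse prior: level at the first valid observation, the rest zero."""
    m = system.state_dim
    a0 = np.zeros(m)
    valid = series[np.isfinite(series)]
    if valid.size:
        a0[0] = valid[0]
    P0 = np.eye(m) * _INIT_VAR
    return a0, P0


def kalman_filter(
    series: np.ndarray,
    system: StateSpaceSystem,
    init_state: np.ndarray | None = None,
    init_cov: np.ndarray | None = None,
) -> FilterResult:
    """Forward filtering pass with prediction-only steps at missing dates.

    ``series`` is aligned to the cube time axis with NaN marking missing
    entries; infinite values are rejected. Covariances are kept symmetric;
    within an all-missing block the predicted signal variance is
    non-decreasing.
    """
    series = np.asarray(series, dtype=float)
    if np.any(np.isinf(series)):
        raise ValueError("series contains non-finite (infinite) observations")
    T = series.shape[0]
    m = system.state_dim
    observed = np.isfinite(series)

    a, P = _initial_state(series, system)
    if init_state is not None:
        a = np.asarray(init_state, dtype=float).copy()
    if init_cov is not None:
        P = np.asarray(init_cov, dtype=float).copy()

    Z = system.observation
    Q = system.state_cov
    r = system.obs_var

    fm = np.empty((T, m))
    fP = np.empty((T, m, m))
    pm = np.empty((T, m))
    pP = np.empty((T, m, m))

    for t in range(T):
        pm[t] = a
        pP[t] = P
        if observed[t]:
            PZ = P[:, 0] + P[:, 2]  # P @ Z for Z = e0 + e2
            S = PZ[0] + PZ[2] + r
            K = PZ / S
            v = series[t] - (a[0] + a[2])
            a = a + K * v
            P = P - np.outer(K, PZ)
            P = 0.5 * (P + P.T)
        fm[t] = a
        fP[t] = P
        # time update to t+1
        a = _f_dot_vec(a)
        P = _fpft(P) + Q
        P = 0.5 * (P + P.T)

    return FilterResult(
        filtered_mean=fm,
        filtered_cov=fP,
        predicted_mean=pm,
        predicted_cov=pP,
        observed=observed,
        system=system,
    )


@dataclass
class SmootherResult:
    """Backward-pass output: full-series posterior moments per date."""

    smoothed_mean: np.ndarray  # (T, m)
    smoothed_cov: np.ndarray  # (T, m, m)
    system: StateSpaceSystem

    def signal_mean(self) -> np.ndarray:
        return self.smoothed_mean[:, 0] + self.smoothed_mean[:, 2]

    def signal_var(self) -> np.ndarray:
        P = self.smoothed_cov
        return P[:, 0, 0] + P[:, 2, 2] + 2.0 * P[:, 0, 2]


def rts_smooth(filt: FilterResult) -> SmootherResult:
    """Rauch-Tung-Striebel backward pass over the filter output.

    Conditions every date on the whole series; smoothed variances of the
    signal never exceed the filtered ones, and at the last date smoothed and
    filtered moments coincide.
    """
    fm, fP = filt.filtered_mean, filt.filtered_cov
    pm, pP = filt.predicted_mean, filt.predicted_cov
    T, m = fm.shape
    sm = np.empty_like(fm)
    sP = np.empty_like(fP)
    sm[-1] = fm[-1]
    sP[-1] = fP[-1]
    for t in range(T - 2, -1, -1):
        # Predicted moments for t+1 from the filter at t:
        ap = _f_dot_vec(fm[t])
        Pp = _fpft(fP[t]) + filt.system.state_cov
        Pp = 0.5 * (Pp + Pp.T)
        FPf = _f_dot(fP[t])  # F @ Pf; J = Pf F^T Pp^{-1} = solve(Pp, FPf)^T
        J = np.linalg.solve(Pp, FPf).T
        sm[t] = fm[t] + J @ (sm[t + 1] - ap)
        sP[t] = fP[t] + J @ (sP[t + 1] - Pp) @ J.T
        sP[t] = 0.5 * (sP[t] + sP[t].T)
    return SmootherResult(smoothed_mean=sm, smoothed_cov=sP, system=filt.system)


def smooth_series(series: np.ndarray, system: StateSpaceSystem, **kw) -> SmootherResult:
    """Convenience: filter then RTS-smooth one series."""
    return rts_smooth(kalman_filter(series, system, **kw))


def reliability(p_k: np.ndarray) -> float:
    """Time-mean of the per-date posterior signal variances.

    A per-pixel scalar summarising how certain the filter is of its own
    reconstruction; small values mean tight posterior bands throughout.
    """
    p_k = np.asarray(p_k, dtype=float)
    if p_k.size == 0:
        raise ValueError("reliability of an empty variance series is undefined")
    return float(p_k.mean())


@dataclass
class KFImputation:
    """Per-pixel smoothed reconstruction with uncertainty.

    ``estimate`` is the posterior mean of the signal L_t + S_t given the
    whole series, ``p_k`` its posterior variance, the confidence band a
    nominal 95% Gaussian interval around the estimate that also accounts for
    observation noise, and ``combined_series`` the observation wherever one
    exists and the estimate elsewhere (observed values are never replaced).
    """

    estimate: np.ndarray
    p_k: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reliability: float
    combined_series: np.ndarray
    params: StateSpaceParams
    degenerate: bool = False

    @property
    def band_halfwidth(self) -> np.ndarray:
        return 0.5 * (self.ci_high - self.ci_low)


def impute_series(
    series: np.ndarray,
    params: StateSpaceParams,
    level: float = 0.95,
) -> KFImputation:
    """Filter + smooth one gap series and package the imputation."""
    if level != 0.95:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2.0))
    else:
        z = _Z_95
    series = np.asarray(series, dtype=float)
    observed = np.isfinite(series)
    system = build_state_space(params)
    if observed.sum() < 2:
        # Unusable pixel: prior mean with maximal (diffuse) variance.
        fill = float(series[observed][0]) if observed.any() else 0.0
        T = series.shape[0]
        est = np.full(T, fill)
        p_k = np.full(T, _INIT_VAR)
        half = z * np.sqrt(p_k + system.obs_var)
        combined = np.where(observed, series, est)
        return KFImputation(
            estimate=est,
            p_k=p_k,
            ci_low=est - half,
            ci_high=est + half,
            reliability=reliability(p_k),
            combined_series=combined,
            params=params,
            degenerate=True,
        )
    sm = smooth_series(series, system)
    est = sm.signal_mean()
    p_k = np.maximum(sm.signal_var(), 0.0)
    half = z * np.sqrt(p_k + system.obs_var)
    combined = np.where(observed, series, est)
    return KFImputation(
        estimate=est,
        p_k=p_k,
        ci_low=est - half,
        ci_high=est + half,
        reliability=reliability(p_k),
        combined_series=combined,
        params=params,
        degenerate=False,
    )


@dataclass
class KFCubeImputation:
    """Grid-wide KF imputation: per-pixel estimates, variances, reliability."""

    estimate: np.ndarray  # (T, ny, nx)
    p_k: np.ndarray  # (T, ny, nx)
    ci_low: np.ndarray
    ci_high: np.ndarray
    reliability: np.ndarray  # (ny, nx)
    combined: np.ndarray  # (T, ny, nx), gap-free
    degenerate: np.ndarray  # (ny, nx) bool
    params: list = field(default_factory=list)  # row-major per-pixel params


def impute_kf(
    cube: GapCube,
    params: StateSpaceParams | None = None,
    s: int = SEASON_DEFAULT,
    level: float = 0.95,
    progress: bool = False,
) -> KFCubeImputation:
    """Impute every pixel of a cube with the KF/RTS smoother.

    With ``params=None`` the noise scales are derived per pixel from that
    pixel's own valid observations; a shared ``params`` skips the
    derivation. Observed dates pass through unchanged in the combined
    output.
    """
    T, ny, nx = cube.shape
    est = np.empty((T, ny, nx))
    p_k = np.empty((T, ny, nx))
    lo = np.empty((T, ny, nx))
    hi = np.empty((T, ny, nx))
    rel = np.empty((ny, nx))
    comb = np.empty((T, ny, nx))
    degen = np.zeros((ny, nx), dtype=bool)
    plist: list[StateSpaceParams] = []
    it = range(cube.n_pixels)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        it = tqdm(it, desc="KF imputation")  # pragma: no cover
    for pid in it:
        iy, ix = cube.pixel_index(pid)
        series = cube.values[:, iy, ix]
        if params is None:
            try:
                p = derive_noise_params(series, s=s)
            except ValueError:
                p = StateSpaceParams(theta1=0.0, theta2=0.0, s=s)
        else:
            p = params
        plist.append(p)
        imp = impute_series(series, p, level=level)
        est[:, iy, ix] = imp.estimate
        p_k[:, iy, ix] = imp.p_k
        lo[:, iy, ix] = imp.ci_low
        hi[:, iy, ix] = imp.ci_high
        rel[iy, ix] = imp.reliability
        comb[:, iy, ix] = imp.combined_series
        degen[iy, ix] = imp.degenerate
    return KFCubeImputation(
        estimate=est,
        p_k=p_k,
        ci_low=lo,
        ci_high=hi,
        reliability=rel,
        combined=comb,
        degenerate=degen,
        params=plist,
    )
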