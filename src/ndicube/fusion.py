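"""Inverse-variance fusion of the KF and LSTM reconstructions.

Per pixel and date the two estimates are combined with precision weights

    w_LSTM = (1/sigma_LSTM^2) / (1/sigma_LSTM^2 + 1/P_k),   w_KF analogous,

so the more certain model dominates; the fused value is the convex
combination w_KF * x_KF + w_LSTM * x_LSTM. When the model errors are
independent this is the minimum-variance (BLUE) combination. The combined
variance accounts for possible error correlation:

    sigma^2 = w_KF^2 sigma_KF^2 + w_LSTM^2 sigma_LSTM^2
              + 2 w_KF w_LSTM Cov(e_KF, e_LSTM).

P_k (the KF posterior signal variance, time-varying) plays the role of
sigma_KF^2 in both the weights and the combined variance; sigma_LSTM is a
per-pixel scalar. The error covariance is estimated per pixel from paired
in-sample residuals, shrunk to zero when fewer than ``min_pairs`` pairs
exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import GapCube
from .statespace import KFCubeImputation, _Z_95
from .lstm import LSTMCubeImputation

__all__ = [
    "FusedCube",
    "fusion_weights",
    "fuse_estimates",
    "combined_variance",
    "estimate_error_covariance",
    "assemble_final",
]

MIN_COV_PAIRS = 10


def fusion_weights(p_k, sigma_lstm_sq):
    """Inverse-variance weights (w_kf, w_lstm), summing to one.

    Vectorised over broadcastable inputs. Degenerate cases: both variances
    zero -> equal weights; one zero -> full weight to that (certain) model;
    an infinite variance gives that model zero weight.
    """
    p_k = np.asarray(p_k, dtype=float)
    s2 = np.asarray(sigma_lstm_sq, dtype=float)
    if np.any(p_k < 0) or np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    p_k, s2 = np.broadcast_arrays(p_k, s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec_kf = np.where(p_k > 0, 1.0 / p_k, np.inf)
        prec_ls = np.where(s2 > 0, 1.0 / s2, np.inf)
        w_kf = prec_kf / (prec_kf + prec_ls)
    # Both zero (infinite precision tie) or both infinite (no information):
    tie = ~np.isfinite(w_kf)
    w_kf = np.where(tie, 0.5, w_kf)
    # One-sided certainties where the division above was ill-posed:
    w_kf = np.where((p_k == 0) & (s2 > 0), 1.0, w_kf)
    w_kf = np.where((s2 == 0) & (p_k > 0), 0.0, w_kf)
    w_kf = np.clip(w_kf, 0.0, 1.0)
    return w_kf, 1.0 - w_kf


def fuse_estimates(kf_value, lstm_value, weights):
    """Weighted sum of the two estimates; lies between them (convexity)."""
    w_kf, w_lstm = weights
    return np.asarray(w_kf) * np.asarray(kf_value, dtype=float) + np.asarray(
        w_lstm
    ) * np.asarray(lstm_value, dtype=float)


def combined_variance(weights, sigma_kf_sq, sigma_lstm_sq, cov=0.0):
    """Variance of the weighted combination including error covariance.

    Raises when the covariance violates the Cauchy-Schwarz bound implied by
    the supplied variances. Non-negative under that precondition.
    """
    w_kf, w_lstm = [np.asarray(w, dtype=float) for w in weights]
    v_kf = np.asarray(sigma_kf_sq, dtype=float)
    v_ls = np.asarray(sigma_lstm_sq, dtype=float)
    cov = np.asarray(cov, dtype=float)
    bound = np.sqrt(v_kf * v_ls)
    finite = np.isfinite(bound)
    if np.any(np.abs(np.where(finite, cov, 0.0)) > np.where(finite, bound, np.inf) + 1e-15):
        raise ValueError("error covariance violates the Cauchy-Schwarz bound")
    # Zero-weight terms contribute nothing even when the matching variance is
    # infinite (the w->0, v->inf limit of precision weighting).
    w_kf_b, w_lstm_b, v_kf, v_ls, cov = np.broadcast_arrays(w_kf, w_lstm, v_kf, v_ls, cov)
    with np.errstate(invalid="ignore"):
        t_kf = np.where(w_kf_b > 0, w_kf_b**2 * v_kf, 0.0)
        t_ls = np.where(w_lstm_b > 0, w_lstm_b**2 * v_ls, 0.0)
        cross = np.where((w_kf_b > 0) & (w_lstm_b > 0), 2.0 * w_kf_b * w_lstm_b * cov, 0.0)
    out = t_kf + t_ls + cross
    return float(out) if out.ndim == 0 else out


def estimate_error_covariance(
    kf_residuals: np.ndarray,
    lstm_residuals: np.ndarray,
    min_pairs: int = MIN_COV_PAIRS,
) -> float:
    """Sample covariance of paired model errors, shrunk to 0 on few pairs."""
    a = np.asarray(kf_residuals, dtype=float)
    b = np.asarray(lstm_residuals, dtype=float)
    paired = np.isfinite(a) & np.isfinite(b)
    if paired.sum() < min_pairs:
        return 0.0
    a = a[paired]
    b = b[paired]
    return float(np.mean((a - a.mean()) * (b - b.mean())))


@dataclass
class FusedCube:
    """Final fused reconstruction with weights and combined uncertainty.

    ``final`` preserves the observation wherever one exists and carries the
    fused estimate elsewhere; ``fused`` stores the model combination at
    every date (kept at observed dates too, for evaluation). Weights sum to
    one everywhere and the fused value is a convex combination of the two
    model estimates.
    """

    fused: np.ndarray  # (T, ny, nx)
    final: np.ndarray  # (T, ny, nx) observation-preserving, gap-free
    w_kf: np.ndarray  # (T, ny, nx)
    w_lstm: np.ndarray  # (T, ny, nx)
    variance: np.ndarray  # (T, ny, nx)
    ci_low: np.ndarray
    ci_high: np.ndarray
    error_cov: np.ndarray  # (ny, nx) per-pixel Cov(e_KF, e_LSTM)


def assemble_final(
    cube: GapCube,
    kf: KFCubeImputation,
    lstm: LSTMCubeImputation,
    min_pairs: int = MIN_COV_PAIRS,
    level_z: float = _Z_95,
) -> FusedCube:
    """Fuse the two cube-wide imputations into the final gap-free cube.

    Weights use the time-varying KF posterior variance P_k against the
    per-pixel sigma_LSTM^2; the per-pixel error covariance (clipped to the
    Cauchy-Schwarz bound of the variances actually used) enters the
    combined variance. Observed values are never replaced in ``final``.
    """
    T, ny, nx = cube.shape
    if kf.estimate.shape != cube.shape or lstm.estimate.shape != cube.shape:
        raise ValueError("model outputs are not aligned with the cube grid/time axis")
    if not np.all(np.isfinite(kf.estimate)):
        raise ValueError("KF imputation is missing estimates at needed dates")
    if not np.all(np.isfinite(lstm.estimate)):
        raise ValueError("LSTM imputation is missing estimates at needed dates")

    s2 = np.where(np.isfinite(lstm.sigma_lstm), lstm.sigma_lstm**2, np.inf)[None, :, :]
    w_kf, w_lstm = fusion_weights(kf.p_k, np.broadcast_to(s2, cube.shape))
    fused = fuse_estimates(kf.estimate, lstm.estimate, (w_kf, w_lstm))

    # Per-pixel error covariance from in-sample residuals at valid dates.
    obs = cube.values
    ecov = np.zeros((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            if not np.isfinite(lstm.sigma_lstm[iy, ix]):
                continue
            valid = np.isfinite(obs[:, iy, ix])
            ecov[iy, ix] = estimate_error_covariance(
                np.where(valid, kf.estimate[:, iy, ix] - obs[:, iy, ix], np.nan),
                np.where(valid, lstm.estimate[:, iy, ix] - obs[:, iy, ix], np.nan),
                min_pairs=min_pairs,
            )
    # Clip to the Cauchy-Schwarz bound of the model variances used in the
    # combination (P_k is a model variance, not the residual-sample variance,
    # so the raw estimate can overshoot the bound).
    bound = np.sqrt(kf.p_k * s2)
    cov3 = np.clip(ecov[None, :, :], -bound, bound)
    cov3 = np.where(np.isfinite(cov3), cov3, 0.0)
    variance = combined_variance((w_kf, w_lstm), kf.p_k, np.broadcast_to(s2, cube.shape), cov3)

    final = np.where(np.isfinite(obs), obs, fused)
    sd = np.sqrt(np.where(np.isfinite(variance), variance, np.nan))
    return FusedCube(
        fused=fused,
        final=final,
        w_kf=w_kf,
        w_lstm=w_lstm,
        variance=variance,
        ci_low=fused - level_z * sd,
        ci_high=fused + level_z * sd,
        error_cov=ecov,
    )
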