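"""Model/results interface over the gap-filling pipeline.

Mirrors the fit/results idiom of statistical modelling packages: a model
object is built from data (a :class:`~ndicube.cube.GapCube`), ``fit()``
runs the estimation and returns a results object carrying estimates,
uncertainties and diagnostics with a ``summary()`` table; simulation and
plotting hang off those objects.

Three models are provided: :class:`KalmanGapFiller` (per-pixel structural
state-space smoothing), :class:`ClusterLSTMImputer` (weighted-correlation
clustering + per-cluster sequence model), and :class:`HybridGapFill`
(both, fused by inverse-variance weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .clustering import ClusterAssignment, cluster_sites, THRESHOLD_DEFAULT
from .cube import GapCube, write_cube
from .fusion import FusedCube, assemble_final
from .lstm import LSTMConfig, LSTMCubeImputation, impute_lstm
from .statespace import (
    KFCubeImputation,
    StateSpaceParams,
    SEASON_DEFAULT,
    impute_kf,
)

__all__ = [
    "KalmanGapFiller",
    "KalmanGapFillResults",
    "ClusterLSTMImputer",
    "ClusterLSTMResults",
    "HybridGapFill",
    "HybridGapFillResults",
]


class KalmanGapFiller:
    """Structural state-space gap filler for a cube.

    Parameters
    ----------
    cube
        The gap cube to reconstruct.
    params
        Shared disturbance scales; with ``None`` they are derived per pixel
        from that pixel's valid observations.
    season
        Seasonal period in time steps (annual cycle at the cube's cadence).
    """

    def __init__(
        self,
        cube: GapCube,
        params: StateSpaceParams | None = None,
        season: int = SEASON_DEFAULT,
    ) -> None:
        self.cube = cube
        self.params = params
        self.season = season

    def fit(self, level: float = 0.95) -> "KalmanGapFillResults":
        imp = impute_kf(self.cube, params=self.params, s=self.season, level=level)
        return KalmanGapFillResults(model=self, imputation=imp)


@dataclass
class KalmanGapFillResults:
    model: KalmanGapFiller
    imputation: KFCubeImputation

    @property
    def estimate(self) -> np.ndarray:
        return self.imputation.estimate

    @property
    def reliability(self) -> np.ndarray:
        return self.imputation.reliability

    def metric_frame(self) -> pd.DataFrame:
        maps = _metrics.metric_maps(self.imputation.estimate, self.model.cube.values)
        maps["reliability"] = self.imputation.reliability
        return _metrics.spatial_summary(maps)

    def summary(self) -> str:
        df = self.metric_frame()
        lines = [
            "Kalman structural gap filler",
            f"  grid {self.model.cube.grid_shape}, T = {self.model.cube.n_time}, "
            f"season = {self.model.season}",
            f"  degenerate pixels: {int(self.imputation.degenerate.sum())}",
            "",
            df.to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)

    def plot_pixel(self, pid: int, ax=None):
        """Observed points, smoothed estimate and 95% band for one pixel."""
        import matplotlib.pyplot as plt

        cube = self.model.cube
        iy, ix = cube.pixel_index(pid)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = cube.time_days
        ax.fill_between(
            t,
            self.imputation.ci_low[:, iy, ix],
            self.imputation.ci_high[:, iy, ix],
            alpha=0.25,
            label="95% band",
        )
        ax.plot(t, self.imputation.estimate[:, iy, ix], lw=1, label="KF estimate")
        ax.plot(t, cube.values[:, iy, ix], ".", ms=3, label="observed")
        ax.set_xlabel(f"days since {cube.epoch}")
        ax.set_ylabel("index")
        ax.legend(loc="best", fontsize=8)
        return ax


class ClusterLSTMImputer:
    """Clustering-based recurrent gap filler for a cube."""

    def __init__(
        self,
        cube: GapCube,
        config: LSTMConfig | None = None,
        threshold: float = THRESHOLD_DEFAULT,
        assignment: ClusterAssignment | None = None,
    ) -> None:
        self.cube = cube
        self.config = config or LSTMConfig()
        self.threshold = threshold
        self.assignment = assignment

    def fit(self) -> "ClusterLSTMResults":
        assignment = self.assignment
        if assignment is None:
            assignment = cluster_sites(self.cube, threshold=self.threshold)
        imp = impute_lstm(self.cube, assignment, self.config)
        return ClusterLSTMResults(model=self, assignment=assignment, imputation=imp)


@dataclass
class ClusterLSTMResults:
    model: ClusterLSTMImputer
    assignment: ClusterAssignment
    imputation: LSTMCubeImputation

    @property
    def estimate(self) -> np.ndarray:
        return self.imputation.estimate

    def metric_frame(self) -> pd.DataFrame:
        maps = _metrics.metric_maps(self.imputation.estimate, self.model.cube.values)
        sig2 = self.imputation.sigma_lstm**2
        maps["reliability"] = np.where(np.isfinite(sig2), sig2, np.nan)
        return _metrics.spatial_summary(maps)

    def summary(self) -> str:
        n_trained = sum(self.imputation.trained.values())
        lines = [
            "Clustered LSTM gap filler",
            f"  clusters: {self.assignment.n_clusters} "
            f"(trained {n_trained}, small/skipped {int(self.assignment.small.sum())})",
            f"  threshold: {self.assignment.threshold}",
            "",
            self.metric_frame().to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)


class HybridGapFill:
    """Variance-weighted hybrid of the KF and clustered-LSTM gap fillers.

    ``holdout_fraction`` hides that share of the valid dates from both
    models before fitting so the results can be scored honestly on unseen
    observations (see :meth:`HybridGapFillResults.metric_frame`).
    """

    def __init__(
        self,
        cube: GapCube,
        kf_params: StateSpaceParams | None = None,
        season: int = SEASON_DEFAULT,
        lstm_config: LSTMConfig | None = None,
        threshold: float = THRESHOLD_DEFAULT,
        holdout_fraction: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.cube = cube
        self.kf_params = kf_params
        self.season = season
        self.lstm_config = lstm_config or LSTMConfig(seed=seed)
        self.threshold = threshold
        self.holdout_fraction = holdout_fraction
        self.seed = seed

    def fit(self) -> "HybridGapFillResults":
        cube = self.cube
        held = None
        if self.holdout_fraction > 0.0:
            keep, held = _metrics.holdout_mask(cube.mask, self.holdout_fraction, self.seed)
            cube = GapCube(
                values=np.where(keep, cube.values, np.nan),
                time_days=cube.time_days,
                epoch=cube.epoch,
            )
        kf_res = KalmanGapFiller(cube, params=self.kf_params, season=self.season).fit()
        lstm_res = ClusterLSTMImputer(
            cube, config=self.lstm_config, threshold=self.threshold
        ).fit()
        fused = assemble_final(cube, kf_res.imputation, lstm_res.imputation)
        return HybridGapFillResults(
            model=self,
            fit_cube=cube,
            kf=kf_res,
            lstm=lstm_res,
            fused=fused,
            holdout=held,
        )


@dataclass
class HybridGapFillResults:
    """Fused reconstruction plus both member models and their diagnostics."""

    model: HybridGapFill
    fit_cube: GapCube  # the cube the models actually saw
    kf: KalmanGapFillResults
    lstm: ClusterLSTMResults
    fused: FusedCube
    holdout: np.ndarray | None = None  # (T, ny, nx) bool, held-out valid dates

    def reconstruction(self, which: str = "ensemble") -> np.ndarray:
        if which == "ensemble":
            return self.fused.fused
        if which == "kf":
            return self.kf.imputation.estimate
        if which == "lstm":
            return self.lstm.imputation.estimate
        raise ValueError(f"unknown model {which!r}")

    def final_cube(self) -> GapCube:
        """Gap-free cube: observations preserved, fused estimates elsewhere."""
        vals = np.clip(self.fused.final, -1.0, 1.0)
        return GapCube(
            values=vals,
            time_days=self.fit_cube.time_days,
            epoch=self.fit_cube.epoch,
        )

    def _eval_observations(self, holdout_only: bool) -> np.ndarray:
        if holdout_only:
            if self.holdout is None:
                raise ValueError("no hold-out mask; fit with holdout_fraction > 0")
            return np.where(self.holdout, self.model.cube.values, np.nan)
        return self.fit_cube.values

    def metric_frame(self, holdout_only: bool = False) -> pd.DataFrame:
        """Spatially averaged MAE/MAPE/RMSE (+ SD) per model.

        In-sample by default (valid dates of the fitted cube); with
        ``holdout_only`` the metrics use only the valid dates hidden from
        the models at fit time.
        """
        obs = self._eval_observations(holdout_only)
        rows = []
        rel = {
            "kf": self.kf.imputation.reliability,
            "lstm": np.where(
                np.isfinite(self.lstm.imputation.sigma_lstm),
                self.lstm.imputation.sigma_lstm**2,
                np.nan,
            ),
            "ensemble": np.nanmean(self.fused.variance, axis=0),
        }
        for which in ("kf", "lstm", "ensemble"):
            maps = _metrics.metric_maps(self.reconstruction(which), obs)
            maps["reliability"] = rel[which]
            df = _metrics.spatial_summary(maps)
            df.insert(0, "model", which)
            rows.append(df.reset_index(names="metric"))
        return pd.concat(rows, ignore_index=True)[["model", "metric", "avg", "sd"]]

    def class_map(
        self,
        which: str = "ensemble",
        mae_threshold: float = _metrics.MAE_THRESHOLD_DEFAULT,
        reliability_threshold: float = _metrics.RELIABILITY_THRESHOLD_DEFAULT,
    ) -> np.ndarray:
        maps = _metrics.metric_maps(self.reconstruction(which), self.fit_cube.values)
        rel = (
            self.kf.imputation.reliability
            if which == "kf"
            else np.nanmean(self.fused.variance, axis=0)
        )
        return _metrics.classify_cells(maps["mae"], rel, mae_threshold, reliability_threshold)

    def summary(self) -> str:
        df = self.metric_frame()
        lines = [
            "Hybrid KF + clustered-LSTM gap filler (inverse-variance fusion)",
            f"  grid {self.fit_cube.grid_shape}, T = {self.fit_cube.n_time}",
            f"  clusters: {self.lstm.assignment.n_clusters} "
            f"(small/skipped {int(self.lstm.assignment.small.sum())})",
            f"  mean w_KF = {float(np.nanmean(self.fused.w_kf)):.3f}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
        ]
        if self.holdout is not None:
            lines += ["", "hold-out metrics:", self.metric_frame(holdout_only=True).to_string(
                index=False, float_format=lambda v: f"{v:.6g}"
            )]
        return "\n".join(lines)

    def to_netcdf(self, path) -> None:
        """Write the final cube plus estimates, variances and weights."""
        write_cube(
            self.fit_cube,
            path,
            extra={
                "final": self.fused.final,
                "estimate_fused": self.fused.fused,
                "variance_fused": self.fused.variance,
                "weight_kf": self.fused.w_kf,
                "estimate": self.kf.imputation.estimate,
                "variance": self.kf.imputation.p_k,
                "reliability": self.kf.imputation.reliability,
                "estimate_lstm": self.lstm.imputation.estimate,
                "sigma_lstm": self.lstm.imputation.sigma_lstm,
                "cluster": self.lstm.assignment.label_grid().astype(float),
            },
        )

    def plot_pixel(self, pid: int, ax=None):
        """Observed points plus all three reconstructions for one pixel."""
        import matplotlib.pyplot as plt

        cube = self.fit_cube
        iy, ix = cube.pixel_index(pid)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = cube.time_days
        ax.fill_between(
            t, self.fused.ci_low[:, iy, ix], self.fused.ci_high[:, iy, ix], alpha=0.2
        )
        ax.plot(t, self.kf.imputation.estimate[:, iy, ix], lw=0.8, label="KF")
        ax.plot(t, self.lstm.imputation.estimate[:, iy, ix], lw=0.8, label="LSTM")
        ax.plot(t, self.fused.fused[:, iy, ix], lw=1.2, label="ensemble")
        ax.plot(t, cube.values[:, iy, ix], ".", ms=3, color="k", label="observed")
        ax.set_xlabel(f"days since {cube.epoch}")
        ax.set_ylabel("index")
        ax.legend(loc="best", fontsize=8)
        return ax
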