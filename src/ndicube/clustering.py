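"""Weighted-correlation clustering of pixel time series.

Pixels with similar temporal dynamics are grouped so a single sequence model
can be trained per group on its most complete member. Similarity between a
candidate series and the cluster reference is the Pearson correlation over
their jointly valid dates, down-weighted by the candidate's completeness
relative to the reference:

    r_wi = cor(x_r, x_i) * L_i / L_r

where L_i and L_r count valid dates. The greedy pass repeatedly picks the
most complete unassigned pixel as a new reference and absorbs every
unassigned pixel whose weighted correlation strictly exceeds the threshold
(default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import GapCube

__all__ = ["ClusterAssignment", "weighted_correlation", "cluster_sites"]

THRESHOLD_DEFAULT = 0.75
MIN_OVERLAP_DEFAULT = 10
MIN_VALID_DEFAULT = 10
MIN_CLUSTER_DEFAULT = 5


@dataclass
class ClusterAssignment:
    """Result of the greedy weighted-correlation clustering.

    ``labels`` holds one integer per pixel in row-major order (-1 marks
    pixels with too few valid dates to cluster), ``references`` the
    row-major pixel id of each cluster's reference (its most complete member
    at selection time), and ``small`` flags clusters below the minimum size
    whose pixels should fall back to KF-only fusion downstream.
    """

    labels: np.ndarray  # (n_pixels,) int
    references: list[int]
    threshold: float
    grid_shape: tuple[int, int]
    min_cluster: int = MIN_CLUSTER_DEFAULT

    @property
    def n_clusters(self) -> int:
        return len(self.references)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.labels >= 0], minlength=self.n_clusters)

    @property
    def small(self) -> np.ndarray:
        """Boolean per cluster: flagged small (< min_cluster members)."""
        return self.sizes < self.min_cluster

    def label_grid(self) -> np.ndarray:
        return self.labels.reshape(self.grid_shape)

    def members(self, k: int) -> np.ndarray:
        """Row-major pixel ids of cluster k."""
        return np.nonzero(self.labels == k)[0]

    def to_frame(self) -> pd.DataFrame:
        """Summary table of (cluster, reference pixel, size, small flag)."""
        return pd.DataFrame(
            {
                "cluster": np.arange(self.n_clusters),
                "reference_pixel": self.references,
                "size": self.sizes,
                "small": self.small,
            }
        )


def weighted_correlation(
    x_r: np.ndarray,
    x_i: np.ndarray,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    multiplier: str = "count_ratio",
) -> float:
    """Completeness-weighted Pearson correlation of two gap series.

    Pearson correlation over jointly valid dates times ``L_i / L_r``
    (``multiplier="count_ratio"``); with ``multiplier="overlap"`` the joint
    overlap count replaces the ratio, the alternative reading of the
    weighting. Returns NaN (treated as below any threshold) when the
    overlap is too small or either series is constant on it.
    """
    x_r = np.asarray(x_r, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    if x_r.shape != x_i.shape:
        raise ValueError("series must share one time axis")
    vr = np.isfinite(x_r)
    vi = np.isfinite(x_i)
    joint = vr & vi
    if joint.sum() < max(min_overlap, 2):
        return float("nan")
    a = x_r[joint]
    b = x_i[joint]
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    if multiplier == "count_ratio":
        w = vi.sum() / vr.sum()
    elif multiplier == "overlap":
        w = float(joint.sum())
    else:
        raise ValueError(f"unknown multiplier {multiplier!r}")
    return r * w


def cluster_sites(
    cube: GapCube,
    threshold: float = THRESHOLD_DEFAULT,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    min_valid: int = MIN_VALID_DEFAULT,
    min_cluster: int = MIN_CLUSTER_DEFAULT,
    multiplier: str = "count_ratio",
) -> ClusterAssignment:
    """Greedy two-step clustering of all eligible pixels.

    Repeat until every eligible pixel is assigned: pick the unassigned pixel
    with the most valid dates (ties broken by smallest row-major id) as a
    new reference, then assign to the new cluster the reference plus every
    unassigned pixel whose weighted correlation with it strictly exceeds
    ``threshold``. Pixels with fewer than ``min_valid`` valid dates get
    label -1. Deterministic; terminates in at most one iteration per pixel.
    """
    X = cube.series_matrix()  # (n_pixels, T)
    n_pixels = X.shape[0]
    valid = np.isfinite(X)
    counts = valid.sum(axis=1)
    labels = np.full(n_pixels, -1, dtype=int)
    eligible = counts >= min_valid
    unassigned = eligible.copy()
    references: list[int] = []

    while unassigned.any():
        cand = np.nonzero(unassigned)[0]
        ref = int(cand[np.argmax(counts[cand])])  # argmax takes the first maximum
        k = len(references)
        references.append(ref)
        labels[ref] = k
        unassigned[ref] = False
        rest = np.nonzero(unassigned)[0]
        if rest.size == 0:
            continue
        r_w = _weighted_corr_to_ref(X, valid, counts, ref, rest, min_overlap, multiplier)
        take = rest[np.nan_to_num(r_w, nan=-np.inf) > threshold]
        labels[take] = k
        unassigned[take] = False

    return ClusterAssignment(
        labels=labels,
        references=references,
        threshold=threshold,
        grid_shape=cube.grid_shape,
        min_cluster=min_cluster,
    )


def _weighted_corr_to_ref(
    X: np.ndarray,
    valid: np.ndarray,
    counts: np.ndarray,
    ref: int,
    rest: np.ndarray,
    min_overlap: int,
    multiplier: str,
) -> np.ndarray:
    """Vectorised weighted correlations of many candidates against one reference."""
    xr = X[ref]
    vr = valid[ref]
    Xc = X[rest]
    Vc = valid[rest]
    joint = Vc & vr
    n = joint.sum(axis=1).astype(float)
    A = np.where(joint, xr, 0.0)
    B = np.where(joint, Xc, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = A.sum(axis=1) / n
        mb = B.sum(axis=1) / n
        cov = (A * B).sum(axis=1) / n - ma * mb
        va = (A * A).sum(axis=1) / n - ma * ma
        vb = (B * B).sum(axis=1) / n - mb * mb
        r = cov / np.sqrt(np.maximum(va, 0.0) * np.maximum(vb, 0.0))
    r[n < max(min_overlap, 2)] = np.nan
    if multiplier == "count_ratio":
        w = counts[rest] / counts[ref]
    else:
        w = n
    return r * w
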