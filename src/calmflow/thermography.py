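"""Thermogram segmentation and skin-temperature comparison.

Each thermogram is a matrix of temperatures (degC).  Skin is separated from
background by two-cluster k-means on the pixel temperatures (1-D: the
clustering is on temperature values, not pixel coordinates), with
deterministic initialisation at the 10th and 90th percentiles; the warmer
cluster is labelled skin.  Per-participant mean skin temperatures are then
compared between the first and last measurement of a condition with a
two-tailed t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .inference import StatResult, paired_ttest


@dataclass
class ThermogramFrame:
    """A temperature matrix with its acquisition metadata."""

    temperatures: np.ndarray        # (rows, cols) degC
    participant: int | str | None = None
    condition: str | None = None    # AC / RS
    when: str | None = None         # first / last

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 2:
            raise ValueError("temperatures must be a 2-D matrix")
        if not np.all(np.isfinite(self.temperatures)):
            raise ValueError("non-finite temperatures")
        t = self.temperatures
        if t.min() < 0.0 or t.max() > 50.0:
            warnings.warn("temperatures outside the plausible 0-50 degC "
                          "range", stacklevel=2)


@dataclass
class SkinSegmentation:
    mask: np.ndarray                # True = skin (warmer cluster)
    t_skin: float                   # degC
    t_bg: float                     # degC
    inertia: float                  # within-cluster sum of squares

    @property
    def mean_skin_temperature(self) -> float:
        return self.t_skin


def kmeans_segment(frame: ThermogramFrame) -> SkinSegmentation:
    """Two-cluster k-means on pixel temperatures; warmer cluster = skin.

    Initialises deterministically at the 10th and 90th percentiles and runs
    Lloyd iterations to convergence, so repeated calls give identical
    segmentations; the segmentation is equivariant to adding a constant to
    the frame.
    """
    vals = frame.temperatures.reshape(-1, 1)
    if np.ptp(vals) == 0:
        raise ValueError("all pixels identical; cannot split two clusters")
    init = np.percentile(vals, [10.0, 90.0]).reshape(2, 1)
    if init[0, 0] == init[1, 0]:  # degenerate percentiles; fall back to range
        init = np.array([[vals.min()], [vals.max()]])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300, tol=1e-12,
                algorithm="lloyd").fit(vals)
    centres = km.cluster_centers_.ravel()
    warm = int(np.argmax(centres))
    mask = (km.labels_ == warm).reshape(frame.temperatures.shape)
    if mask.all() or not mask.any():
        raise ValueError("degenerate segmentation: one cluster is empty")
    return SkinSegmentation(mask=mask, t_skin=float(centres[warm]),
                            t_bg=float(centres[1 - warm]),
                            inertia=float(km.inertia_))


def mean_skin_temperature(frame: ThermogramFrame,
                          segmentation: SkinSegmentation | None = None
                          ) -> float:
    """Mean temperature over the skin pixels of one frame."""
    seg = segmentation or kmeans_segment(frame)
    return float(frame.temperatures[seg.mask].mean())


def skin_temperature_change(first_frames, last_frames,
                            mode: str = "paired",
                            sided: str = "two-sided") -> StatResult:
    """t comparison of per-participant mean skin temperatures, first vs last.

    ``first_frames`` and ``last_frames`` are matched sequences of
    ThermogramFrame (same participants, same order).  Each frame is
    segmented, its skin pixels averaged, and the per-participant means
    compared with a two-tailed t test (positive t: warmer at the end).
    ``mode`` selects paired (df = n - 1) or pooled two-sample (df = 2n - 2).
    """
    first_frames, last_frames = list(first_frames), list(last_frames)
    if len(first_frames) != len(last_frames):
        raise ValueError("first/last frame lists differ in length")
    if not first_frames:
        raise ValueError("no frames given")
    first = [mean_skin_temperature(f) for f in first_frames]
    last = [mean_skin_temperature(f) for f in last_frames]
    result = paired_ttest(first, last, sided=sided, mode=mode)
    direction = ("warmer" if np.mean(last) > np.mean(first) else
                 "cooler" if np.mean(last) < np.mean(first) else "unchanged")
    result.extra["direction_last_vs_first"] = direction
    result.extra["mean_first"] = float(np.mean(first))
    result.extra["mean_last"] = float(np.mean(last))
    return result
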