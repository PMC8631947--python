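"""Reverse-correlation receptive-field maps, z = 3 contour extraction, and
the probe-orthogonality metric D.

The z-map compares, per grid position, spike counts in the [30, 100] ms
window after each stimulus presentation at that position with counts in the
equal-length window immediately preceding those presentations.  The cRF
outline is the z = 3 contour of the Gaussian-smoothed map; D measures how
far RF centers drift in the visual field per mm of cortical depth along a
line fitted through the stacked centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from shapely.geometry import Polygon

COUNT_WINDOW_MS = (30.0, 100.0)


@dataclass
class RFMap:
    az_axis_dva: np.ndarray
    el_axis_dva: np.ndarray
    z: np.ndarray                  # (n_az, n_el); NaN where undefined
    smoothed: bool = False
    contours: list[np.ndarray] = field(default_factory=list)  # (n, 2) dva polygons
    centers: list[tuple[float, float]] = field(default_factory=list)
    level: float = 3.0

    @property
    def empty(self) -> bool:
        return not np.any(np.isfinite(self.z))

    @property
    def center(self) -> Optional[tuple[float, float]]:
        """Centroid of the largest contoured region, if any."""
        return self.centers[0] if self.centers else None


def rf_zmap(events: pd.DataFrame, spike_times_ms: np.ndarray,
            count_window_ms: tuple[float, float] = COUNT_WINDOW_MS) -> RFMap:
    """Reverse-correlation z-map (pre-smoothing).

    Per grid position: z = (mean count in the post-event window - mean count
    in the equal-length window preceding that position's events) / SD of
    those preceding-window counts.  Positions with zero baseline SD are
    recorded as undefined (NaN).
    """
    w_lo, w_hi = count_window_ms
    w = w_hi - w_lo
    st = np.sort(np.asarray(spike_times_ms, dtype=float))
    t = events["t_ms"].to_numpy()
    evoked = np.searchsorted(st, t + w_hi) - np.searchsorted(st, t + w_lo)
    baseline = np.searchsorted(st, t) - np.searchsorted(st, t - w)
    az = np.round(events["azimuth_dva"].to_numpy(), 9)
    el = np.round(events["elevation_dva"].to_numpy(), 9)
    az_axis = np.unique(az)
    el_axis = np.unique(el)
    z = np.full((az_axis.size, el_axis.size), np.nan)
    ai = np.searchsorted(az_axis, az)
    ei = np.searchsorted(el_axis, el)
    flat = ai * el_axis.size + ei
    order = np.argsort(flat, kind="stable")
    bounds = np.searchsorted(flat[order], np.arange(az_axis.size * el_axis.size + 1))
    for k in range(az_axis.size * el_axis.size):
        sel = order[bounds[k]:bounds[k + 1]]
        if sel.size == 0:
            continue
        base = baseline[sel].astype(float)
        sd = base.std(ddof=1) if sel.size > 1 else 0.0
        if sd == 0:
            continue
        z[k // el_axis.size, k % el_axis.size] = (evoked[sel].mean() - base.mean()) / sd
    return RFMap(az_axis_dva=az_axis, el_axis_dva=el_axis, z=z)


def rf_smooth_contour(rf: RFMap, sigma_grid: float = 1.0,
                      level: float = 3.0) -> RFMap:
    """Gaussian-smooth the z-map and extract closed contours at ``level``.

    Undefined positions are treated by normalized convolution (smoothing the
    defined values and the definition mask separately).  Contours are closed
    polygons in dva; the largest-area region is listed first and its area
    centroid is "the" cRF center.
    """
    if rf.empty:
        raise ValueError("map has no defined z values")
    mask = np.isfinite(rf.z).astype(float)
    filled = np.where(mask > 0, rf.z, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_grid)
    den = ndimage.gaussian_filter(mask, sigma_grid)
    with np.errstate(invalid="ignore"):
        smooth = np.where(den > 1e-12, num / den, np.nan)
    smooth_finite = np.nan_to_num(smooth, nan=-np.inf)
    raw_contours = measure.find_contours(smooth_finite, level)
    daz = rf.az_axis_dva[1] - rf.az_axis_dva[0] if rf.az_axis_dva.size > 1 else 1.0
    del_ = rf.el_axis_dva[1] - rf.el_axis_dva[0] if rf.el_axis_dva.size > 1 else 1.0
    polys = []
    for c in raw_contours:
        if c.shape[0] < 4 or not np.allclose(c[0], c[-1]):
            continue  # open contour touching the map edge: not a closed cRF
        dva = np.column_stack([rf.az_axis_dva[0] + c[:, 0] * daz,
                               rf.el_axis_dva[0] + c[:, 1] * del_])
        poly = Polygon(dva)
        if poly.is_valid and poly.area > 0:
            polys.append((poly, dva))
    polys.sort(key=lambda p: -p[0].area)
    return RFMap(az_axis_dva=rf.az_axis_dva, el_axis_dva=rf.el_axis_dva,
                 z=smooth, smoothed=True,
                 contours=[dva for _, dva in polys],
                 centers=[(p.centroid.x, p.centroid.y) for p, _ in polys],
                 level=level)


@dataclass
class ProbeOrthogonality:
    slope_az_dva_per_mm: float
    slope_el_dva_per_mm: float
    d_dva_per_mm: float
    depth_span_mm: float
    n_centers: int


def probe_orthogonality(centers: Sequence[tuple[float, float, float]],
                        span_mm: float = 2.0) -> ProbeOrthogonality:
    """Orthogonality metric D from stacked RF centers.

    ``centers`` are (depth mm, azimuth dva, elevation dva) triplets; the fit
    uses centers within ``span_mm`` of the most superficial one.  D is the
    distance in the azimuth x elevation plane between the fitted line's
    endpoints, per mm depth — i.e. the planar drift rate along the probe.
    """
    arr = np.asarray(centers, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("centers must be (depth, azimuth, elevation) triplets")
    d0 = arr[:, 0].min()
    sel = arr[arr[:, 0] <= d0 + span_mm]
    if sel.shape[0] < 3:
        raise ValueError("need at least 3 RF centers within the depth span")
    depth = sel[:, 0]
    A = np.column_stack([np.ones_like(depth), depth])
    coef, *_ = np.linalg.lstsq(A, sel[:, 1:3], rcond=None)
    slope_az, slope_el = coef[1]
    d = float(np.hypot(slope_az, slope_el))
    return ProbeOrthogonality(float(slope_az), float(slope_el), d,
                              float(span_mm), sel.shape[0])
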