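"""Orientation tuning and its relation to border-ownership selectivity.

Orientation has period 180 deg, so circular statistics are computed in the
doubled-angle domain: the response to orientation j contributes a vector
with direction 2j and magnitude equal to the rate; the preferred
orientation is the resultant direction divided by 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, kruskal

from ._stats import RandomizationP, randomization_pvalue

EVOKED_WINDOW_MS = (30.0, 200.0)


@dataclass
class OrientationTuning:
    unit_id: str
    orientations_deg: np.ndarray
    mean_rates: np.ndarray          # sp/s, polarities pooled
    kw_p: float
    z_peak: float
    selective: bool
    resultant_magnitude: float
    preferred_orientation_deg: float  # NaN when the resultant vanishes


@dataclass
class AggregateOrientation:
    angle_deg: float
    magnitude: float
    p: float
    p_corrected: float
    n_units: int


def doubled_angle_resultant(angles_deg: np.ndarray,
                            magnitudes: np.ndarray) -> tuple[float, float]:
    """Resultant of vectors with direction 2*angle and the given magnitudes.

    Returns (magnitude, direction/2 in [0, 180)); the direction is NaN when
    the resultant vanishes.
    """
    a = np.deg2rad(2.0 * np.asarray(angles_deg, dtype=float))
    m = np.asarray(magnitudes, dtype=float)
    x, y = np.sum(m * np.cos(a)), np.sum(m * np.sin(a))
    mag = float(np.hypot(x, y))
    if mag < 1e-12 * max(np.sum(np.abs(m)), 1e-300):
        return mag, float("nan")
    ang = (np.rad2deg(np.arctan2(y, x)) / 2.0) % 180.0
    return mag, float(ang)


def preferred_orientation(orientations_deg: np.ndarray,
                          mean_rates: np.ndarray) -> tuple[float, float]:
    """(preferred orientation deg, resultant magnitude) from mean rates."""
    rates = np.asarray(mean_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if not np.any(rates > 0):
        raise ValueError("preferred orientation undefined: all rates zero")
    mag, ang = doubled_angle_resultant(orientations_deg, rates)
    return ang, mag


def orientation_selectivity(
    trials: pd.DataFrame,
    spikes: pd.DataFrame,
    unit_id: str = "u000",
    evoked_window_ms: tuple[float, float] = EVOKED_WINDOW_MS,
    alpha: float = 0.05,
    z_threshold: float = 3.0,
) -> OrientationTuning:
    """Kruskal-Wallis orientation selectivity plus peak-orientation z-score.

    Evoked counts in [30, 200] ms are grouped by orientation (contrast
    polarities pooled).  The z-score of the best orientation's rate uses the
    mean/SD of the rate in an equal-duration window preceding stimulus
    onset.  Selective iff kw_p < alpha and z_peak >= z_threshold.
    """
    w_lo, w_hi = evoked_window_ms
    w = w_hi - w_lo
    sp = spikes[spikes["unit_id"] == unit_id]
    by_trial = {tid: g["t_ms"].to_numpy() for tid, g in sp.groupby("trial_id")}
    counts, base_counts, orients = [], [], []
    for _, tr in trials.iterrows():
        t = by_trial.get(tr["trial_id"], np.array([]))
        counts.append(np.sum((t >= w_lo) & (t < w_hi)))
        base_counts.append(np.sum((t >= -w) & (t < 0.0)))
        orients.append(tr["orientation_deg"])
    counts = np.asarray(counts, dtype=float)
    base_counts = np.asarray(base_counts, dtype=float)
    orients = np.asarray(orients, dtype=float)
    uniq = np.unique(orients)
    if uniq.size < 2:
        raise ValueError("need at least two orientations")
    groups = [counts[orients == o] for o in uniq]
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
        kw_p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kw_p = float(kruskal(*groups).pvalue)
    mean_rates = np.array([g.mean() for g in groups]) / (w / 1000.0)
    base_sd = base_counts.std(ddof=1)
    if base_sd == 0:
        raise ValueError("zero baseline SD: z-score undefined, unit excluded")
    z_peak = float((counts[orients == uniq[mean_rates.argmax()]].mean()
                    - base_counts.mean()) / base_sd)
    mag, ang = doubled_angle_resultant(uniq, mean_rates)
    return OrientationTuning(
        unit_id=unit_id, orientations_deg=uniq, mean_rates=mean_rates,
        kw_p=kw_p, z_peak=z_peak,
        selective=bool(kw_p < alpha and z_peak >= z_threshold),
        resultant_magnitude=mag, preferred_orientation_deg=ang)


def aggregate_orientation(
    unit_magnitudes: np.ndarray,
    unit_preferred_deg: np.ndarray,
    n_randomizations: int = 2000,
    min_units: int = 4,
    seed: int = 0,
) -> Optional[AggregateOrientation]:
    """Aggregate preferred orientation of a penetration with a randomization
    test: unit resultants keep their magnitudes but get uniform random
    doubled-angle directions under the null."""
    mags = np.asarray(unit_magnitudes, dtype=float)
    prefs = np.asarray(unit_preferred_deg, dtype=float)
    ok = np.isfinite(mags) & np.isfinite(prefs)
    mags, prefs = mags[ok], prefs[ok]
    if mags.size < min_units:
        return None
    mag, ang = doubled_angle_resultant(prefs, mags)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_randomizations, mags.size))
    x = (mags * np.cos(theta)).sum(axis=1)
    y = (mags * np.sin(theta)).sum(axis=1)
    null = np.hypot(x, y)
    pr = randomization_pvalue(null, mag, alternative="greater")
    return AggregateOrientation(angle_deg=ang, magnitude=mag, p=pr.p,
                                p_corrected=pr.p_corrected, n_units=mags.size)


def bo_selective_circular_mean(
    orientations_deg: np.ndarray,
    abs_boi: np.ndarray,
    significant: np.ndarray,
    min_tested: int = 4,
) -> float:
    """Circular mean of border-ownership-selective orientations: direction/2
    of the |BOI|-weighted doubled-angle resultant over significant
    orientations.  NaN when none is significant or the resultant vanishes."""
    orientations_deg = np.asarray(orientations_deg, dtype=float)
    if orientations_deg.size < min_tested:
        raise ValueError(f"need at least {min_tested} tested orientations")
    sig = np.asarray(significant, dtype=bool)
    if not sig.any():
        return float("nan")
    _, ang = doubled_angle_resultant(orientations_deg[sig],
                                     np.asarray(abs_boi, dtype=float)[sig])
    return ang


def identity_line_distance(x_deg: float, y_deg: float) -> float:
    """Perpendicular distance (deg) of an orientation pair to the nearest
    periodic identity line: |wrap180(x - y)| / sqrt(2), wrap into (-90, 90]."""
    d = (x_deg - y_deg) % 180.0
    if d > 90.0:
        d -= 180.0
    return abs(d) / np.sqrt(2.0)


def identity_distance_test(
    preferred_deg: np.ndarray,
    bo_circular_mean_deg: np.ndarray,
    n_shuffles: int = 2000,
    min_pairs: int = 5,
    seed: int = 0,
) -> tuple[float, RandomizationP]:
    """Mean identity-line distance with a pairing-shuffle randomization test
    (null: preferred orientation and BO-selective orientation unrelated)."""
    x = np.asarray(preferred_deg, dtype=float)
    y = np.asarray(bo_circular_mean_deg, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} complete pairs")
    dist = np.vectorize(identity_line_distance)
    observed = float(np.mean(dist(x, y)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = np.mean(dist(x, rng.permutation(y)))
    return observed, randomization_pvalue(null, observed, alternative="less")


def preferred_side_span(sides_deg: Sequence[float]) -> tuple[float, bool]:
    """Smallest circular arc (deg) containing all preferred ownership sides.

    Sides are true directions (period 360).  Contiguous iff the span is
    < 180 deg.
    """
    s = np.sort(np.asarray(sides_deg, dtype=float) % 360.0)
    if s.size < 2:
        raise ValueError("need at least two preferred sides")
    gaps = np.diff(np.append(s, s[0] + 360.0))
    span = float(360.0 - gaps.max())
    return span, span < 180.0


@dataclass
class ContingencyResult:
    table: np.ndarray              # rows: orientation -/+; cols: BO -/+
    chi2: float
    p: float
    fisher_p: Optional[float]      # reported when an expected cell < 5
    n: int


def bo_orientation_contingency(orientation_selective: np.ndarray,
                               bo_selective: np.ndarray,
                               min_units: int = 20) -> ContingencyResult:
    """Chi-square test of independence between orientation selectivity and
    border-ownership selectivity (no continuity correction)."""
    o = np.asarray(orientation_selective, dtype=bool)
    b = np.asarray(bo_selective, dtype=bool)
    if o.size != b.size:
        raise ValueError("flag arrays must be the same length")
    if o.size < min_units:
        raise ValueError(f"need at least {min_units} units")
    table = np.array([[np.sum(~o & ~b), np.sum(~o & b)],
                      [np.sum(o & ~b), np.sum(o & b)]], dtype=float)
    return contingency_chi2(table)


def contingency_chi2(table: np.ndarray) -> ContingencyResult:
    table = np.asarray(table, dtype=float)
    res = chi2_contingency(table, correction=False)
    expected = res.expected_freq
    fisher_p = None
    if (expected < 5).any():
        warnings.warn("expected cell count < 5; reporting Fisher exact test alongside")
        fisher_p = float(fisher_exact(table).pvalue)
    return ContingencyResult(table=table, chi2=float(res.statistic),
                             p=float(res.pvalue), fisher_p=fisher_p,
                             n=int(table.sum()))
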