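"""Shared statistical machinery: persistence-gated threshold crossings,
BCa bootstrap over units, and randomization p-values.

Randomization p-values are reported as the plain fraction of null samples at
least as extreme as the observed statistic (which can be 0), together with
the add-one-corrected value (k+1)/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from scipy.stats import norm


@dataclass
class RandomizationP:
    p: float                 # plain fraction, can be 0
    p_corrected: float       # (k+1)/(n+1)
    n_randomizations: int


def randomization_pvalue(null_stats: np.ndarray, observed: float,
                         alternative: str = "greater") -> RandomizationP:
    """Fraction of the null at least as extreme as ``observed``.

    ``alternative='greater'`` counts null >= observed, ``'less'`` counts
    null <= observed.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    n = null_stats.size
    if alternative == "greater":
        k = int(np.sum(null_stats >= observed))
    elif alternative == "less":
        k = int(np.sum(null_stats <= observed))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return RandomizationP(p=k / n, p_corrected=(k + 1) / (n + 1), n_randomizations=n)


def sliding_min(f: np.ndarray, width: int) -> np.ndarray:
    """Minimum of ``f`` over the forward-looking window [i, i+width).

    Positions whose window would extend past the end get -inf (the
    persistence requirement cannot be verified there, so they never
    qualify).  Works on the last axis of an N-d array.
    """
    f = np.asarray(f, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    out = ndimage.minimum_filter1d(f, size=width, axis=-1,
                                   mode="nearest",
                                   origin=-(width // 2))
    # forward window starting at i covers [i, i+width); invalidate tails
    out = out.copy()
    if width > 1:
        out[..., -(width - 1):] = -np.inf
    return out


def threshold_latency(t_ms: np.ndarray, f: np.ndarray, threshold: float,
                      persistence_ms: float = 20.0) -> float:
    """Earliest t with f >= threshold throughout [t, t + persistence).

    Returns NaN when no such crossing exists.  ``t_ms`` must be uniformly
    sampled.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    f = np.asarray(f, dtype=float)
    if t_ms.size < 2:
        return float("nan")
    dt = t_ms[1] - t_ms[0]
    width = max(int(round(persistence_ms / dt)), 1)
    qualifying = sliding_min(f, width) >= threshold
    idx = np.flatnonzero(qualifying)
    if idx.size == 0:
        return float("nan")
    return float(t_ms[idx[0]])


def critical_threshold(f: np.ndarray, t_ms: np.ndarray,
                       persistence_ms: float = 20.0) -> np.ndarray:
    """Largest threshold at which each function still has a defined latency.

    For each row of ``f`` this is max_t min_{s in [t, t+persistence)} f(s):
    a latency exists at threshold theta iff this value >= theta.  Used to
    turn the shuffle-null threshold search into a quantile computation.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    dt = t_ms[1] - t_ms[0]
    width = max(int(round(persistence_ms / dt)), 1)
    mins = sliding_min(np.atleast_2d(f), width)
    return mins.max(axis=-1)


@dataclass
class BootstrapCI:
    estimate: float
    lo: float
    hi: float
    n_boot: int
    n_dropped: int           # replicates with undefined statistic
    frac_dropped: float
    valid: bool
    replicates: Optional[np.ndarray] = None


def bca_interval(replicates: np.ndarray, observed: float,
                 jackknife: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval.

    ``replicates`` must already be cleaned of undefined values.
    """
    reps = np.asarray(replicates, dtype=float)
    jk = np.asarray(jackknife, dtype=float)
    jk = jk[np.isfinite(jk)]
    # bias correction
    prop = np.mean(reps < observed) + 0.5 * np.mean(reps == observed)
    prop = min(max(prop, 1.0 / (len(reps) + 1)), 1.0 - 1.0 / (len(reps) + 1))
    z0 = norm.ppf(prop)
    # acceleration from jackknife skewness
    if jk.size >= 3:
        d = jk.mean() - jk
        denom = 6.0 * (np.sum(d ** 2) ** 1.5)
        a = float(np.sum(d ** 3) / denom) if denom > 0 else 0.0
    else:
        a = 0.0
    z_lo, z_hi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)

    def adj(z: float) -> float:
        zz = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        return float(norm.cdf(zz))

    lo = float(np.quantile(reps, adj(z_lo)))
    hi = float(np.quantile(reps, adj(z_hi)))
    return lo, hi


def bootstrap_statistic_ci(
    statistic: Callable[[np.ndarray], float],
    n_units: int,
    n_boot: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
    max_undefined_frac: float = 0.5,
    keep_replicates: bool = False,
) -> BootstrapCI:
    """BCa CI for a unit-level resampling statistic that may be undefined (NaN).

    ``statistic`` maps an index array (resampled unit indices) to a scalar.
    Undefined replicates are dropped and their fraction reported; the CI is
    invalidated when more than ``max_undefined_frac`` are undefined.
    """
    observed = statistic(np.arange(n_units))
    if not np.isfinite(observed):
        return BootstrapCI(observed, float("nan"), float("nan"),
                           n_boot, n_boot, 1.0, False)
    if n_units == 1:
        # resampling is degenerate: every replicate equals the observed value
        return BootstrapCI(observed, observed, observed, n_boot, 0, 0.0, True,
                           replicates=np.full(n_boot, observed) if keep_replicates else None)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_units, size=n_units)
        reps[b] = statistic(idx)
    defined = reps[np.isfinite(reps)]
    n_dropped = n_boot - defined.size
    frac = n_dropped / n_boot
    if frac > max_undefined_frac or defined.size < 2:
        return BootstrapCI(observed, float("nan"), float("nan"),
                           n_boot, n_dropped, frac, False,
                           replicates=reps if keep_replicates else None)
    jack = np.empty(n_units)
    all_idx = np.arange(n_units)
    for i in range(n_units):
        jack[i] = statistic(np.delete(all_idx, i))
    lo, hi = bca_interval(defined, observed, jack, alpha=alpha)
    return BootstrapCI(observed, lo, hi, n_boot, n_dropped, frac, True,
                       replicates=reps if keep_replicates else None)


def one_sided_bootstrap_comparison(reps_a: np.ndarray, reps_b: np.ndarray) -> float:
    """P(latency_B - latency_A <= 0) over bootstrap pairs (tests A earlier than B).

    Undefined replicates are dropped pairwise.  Exact ties — an artifact of
    the 1 ms reporting grid — are split evenly between the two directions,
    which preserves p ~ 0.5 for exchangeable populations and coincides with
    the plain fraction whenever ties are negligible.
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() == 0:
        return float("nan")
    d = b[ok] - a[ok]
    return float(np.mean(d < 0.0) + 0.5 * np.mean(d == 0.0))
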