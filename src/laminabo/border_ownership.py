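"""Border-ownership selectivity: inclusion criteria, the border-ownership
index (BOI), its permutation test, preferred side, and the per-penetration
columnar-clustering test.

The BOI contrasts the two ownership configurations of an identical local
edge, averaged over both contrast polarities:

    BOI = ((R1 + R3) - (R2 + R4)) / (R1 + R3 + R2 + R4)

where R_i is the mean rate in [50, 500] ms for condition i; conditions
{1, 3} place the owning square on side A, {2, 4} on side B, and {1, 2} vs
{3, 4} swap contrast polarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from shapely.geometry import LineString, Polygon

from .datamodel import BO_WINDOW_MS, Session, StimulusGeometry
from ._stats import RandomizationP, randomization_pvalue

PRETRIAL_WINDOW_MS = (-400.0, 0.0)


@dataclass
class BODataset:
    """Per-trial spike counts of one unit for one stimulus geometry."""

    unit_id: str
    dataset_id: int
    edge_orientation_deg: float
    geometry: Optional[StimulusGeometry]
    counts: dict[int, np.ndarray]           # condition -> per-trial counts, [50,500] ms
    pretrial_counts: dict[int, np.ndarray]  # condition -> per-trial counts, [-400,0) ms
    window_ms: tuple[float, float] = BO_WINDOW_MS

    @property
    def rates(self) -> dict[int, float]:
        """Mean rate (sp/s) per condition over the analysis window."""
        w = (self.window_ms[1] - self.window_ms[0]) / 1000.0
        return {c: float(np.mean(v)) / w if len(v) else float("nan")
                for c, v in self.counts.items()}

    @property
    def n_trials(self) -> dict[int, int]:
        return {c: len(v) for c, v in self.counts.items()}


@dataclass
class InclusionFlags:
    min_rate: bool            # (1) >=1 sp/s in at least one condition
    evoked_vs_baseline: bool  # (2) rank-sum evoked vs pre-trial, Bonferroni over 4
    min_trials: bool          # (3) at least six trials per condition
    edge_in_crf: bool         # (4) central edge intersects the cRF contour
    crf_clear_of_edges: bool  # (5) contour >= 1 dva from non-central square edges
    determinable: bool = True

    @property
    def included(self) -> bool:
        return all((self.min_rate, self.evoked_vs_baseline, self.min_trials,
                    self.edge_in_crf, self.crf_clear_of_edges, self.determinable))


@dataclass
class BOResult:
    unit_id: str
    dataset_id: int
    edge_orientation_deg: float
    boi: float
    p: float
    p_corrected: float
    significant: bool
    preferred_side_deg: float     # NaN when tied
    included: bool
    flags: Optional[InclusionFlags] = None


@dataclass
class PenetrationClustering:
    penetration_id: str
    n_units: int
    proportion: float             # most-common preferred side


@dataclass
class ClusteringResult:
    per_penetration: list[PenetrationClustering]
    p_pref: float                 # mean proportion across penetrations
    p: float
    p_corrected: float
    n_randomizations: int


def build_bo_datasets(session: Session,
                      window_ms: tuple[float, float] = BO_WINDOW_MS) -> list[BODataset]:
    """Per-trial spike counts for every (unit, stimulus geometry) pair."""
    out = []
    trials = session.trials
    spikes = session.spikes
    grouped = spikes.groupby(["unit_id", "trial_id"])["t_ms"]
    # per (unit, trial) counts in the evoked and pre-trial windows
    evoked = grouped.apply(
        lambda t: int(np.sum((t >= window_ms[0]) & (t < window_ms[1]))))
    pre = grouped.apply(
        lambda t: int(np.sum((t >= PRETRIAL_WINDOW_MS[0]) & (t < PRETRIAL_WINDOW_MS[1]))))
    for unit_id in (u.unit_id for u in session.units):
        for geom in session.manifest.datasets:
            sub = trials[trials["dataset_id"] == geom.dataset_id]
            counts, pre_counts = {}, {}
            for cond in (1, 2, 3, 4):
                tids = sub.loc[sub["condition_id"] == cond, "trial_id"]
                counts[cond] = np.array(
                    [evoked.get((unit_id, t), 0) for t in tids], dtype=float)
                pre_counts[cond] = np.array(
                    [pre.get((unit_id, t), 0) for t in tids], dtype=float)
            out.append(BODataset(
                unit_id=unit_id, dataset_id=geom.dataset_id,
                edge_orientation_deg=geom.edge_orientation_deg,
                geometry=geom, counts=counts, pretrial_counts=pre_counts,
                window_ms=window_ms))
    return out


def compute_boi(r1: float, r2: float, r3: float, r4: float) -> float:
    """((R1+R3) - (R2+R4)) / (R1+R3+R2+R4); positive toward side A (conditions 1 & 3)."""
    total = r1 + r2 + r3 + r4
    if total <= 0:
        raise ValueError("BOI undefined: all condition rates are zero")
    return ((r1 + r3) - (r2 + r4)) / total


def dataset_boi(dataset: BODataset) -> float:
    r = dataset.rates
    return compute_boi(r[1], r[2], r[3], r[4])


def apply_inclusion_criteria(
    dataset: BODataset,
    crf_contour: Optional[np.ndarray],
    min_rate_hz: float = 1.0,
    min_trials: int = 6,
    clearance_dva: float = 1.0,
    alpha: float = 0.05,
) -> InclusionFlags:
    """Evaluate the five inclusion criteria for one dataset.

    ``crf_contour`` is an (n, 2) closed polygon in dva (the z=3 cRF outline);
    when it is None criteria 4-5 are undeterminable and the dataset is
    excluded with ``determinable=False``.
    """
    rates = dataset.rates
    f1 = any(r >= min_rate_hz for r in rates.values() if np.isfinite(r))

    # (2) evoked vs pre-trial spike counts, two-sided rank-sum, Bonferroni
    # over the 4 conditions; pre-trial counts are scaled to the evoked-window
    # length so the two samples estimate the same quantity under H0
    w_ev = dataset.window_ms[1] - dataset.window_ms[0]
    w_pre = PRETRIAL_WINDOW_MS[1] - PRETRIAL_WINDOW_MS[0]
    scale = w_ev / w_pre
    f2 = False
    for cond in (1, 2, 3, 4):
        ev, pre = dataset.counts[cond], dataset.pretrial_counts[cond] * scale
        if len(ev) == 0 or len(pre) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = ranksums(ev, pre).pvalue
        if np.isfinite(p) and p < alpha / 4.0:
            f2 = True
            break

    f3 = all(n >= min_trials for n in dataset.n_trials.values())

    if crf_contour is None or dataset.geometry is None:
        return InclusionFlags(f1, f2, f3, False, False, determinable=False)
    poly = Polygon(crf_contour)
    geom = dataset.geometry
    edge = LineString(geom.central_edge_segment())
    f4 = poly.intersects(edge)
    # non-central edges: the remaining 3 sides of each square
    clearance_ok = True
    for side in ("a", "b"):
        sq = geom.square_polygon(side)
        for i in (1, 2, 3):  # side 0 (index 0->1) is the central edge
            seg = LineString([sq[i], sq[(i + 1) % 4]])
            if poly.distance(seg) < clearance_dva:
                clearance_ok = False
    return InclusionFlags(f1, f2, f3, bool(f4), clearance_ok)


def permutation_test_boi(dataset: BODataset, n_shuffles: int = 10_000,
                         seed: int = 0) -> RandomizationP:
    """Permutation test of |BOI| by shuffling ownership labels within each
    contrast-polarity pair, independently for {1,2} and {3,4}."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    total_spikes = sum(v.sum() for v in dataset.counts.values())
    if total_spikes <= 0:
        raise ValueError("permutation test undefined with no spikes")
    rng = np.random.default_rng(seed)
    observed = abs(dataset_boi(dataset))

    def pair_means(c_a: np.ndarray, c_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # sorting the pool makes the null stream independent of trial order,
        # so p is exactly invariant to relabeling trials within a condition
        pooled = np.sort(np.concatenate([c_a, c_b]))
        n_a = len(c_a)
        tiled = np.broadcast_to(pooled, (n_shuffles, pooled.size))
        perm = rng.permuted(tiled, axis=1)
        return perm[:, :n_a].mean(axis=1), perm[:, n_a:].mean(axis=1)

    m1, m2 = pair_means(dataset.counts[1], dataset.counts[2])
    m3, m4 = pair_means(dataset.counts[3], dataset.counts[4])
    denom = m1 + m2 + m3 + m4
    with np.errstate(invalid="ignore", divide="ignore"):
        boi_null = np.abs(((m1 + m3) - (m2 + m4)) / denom)
    boi_null = np.where(denom > 0, boi_null, 0.0)
    return randomization_pvalue(boi_null, observed, alternative="greater")


def preferred_side(boi: float, geometry: StimulusGeometry) -> float:
    """Direction (deg) from the central edge toward the preferred owning square."""
    if boi > 0:
        return geometry.side_a_direction_deg
    if boi < 0:
        return geometry.side_b_direction_deg
    return float("nan")


def analyze_unit(
    datasets: Sequence[BODataset],
    crf_contour: Optional[np.ndarray],
    n_shuffles: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[BOResult]:
    """Full BO analysis for one unit's datasets with Bonferroni correction
    across the unit's included datasets."""
    rng = np.random.default_rng(seed)
    flags = [apply_inclusion_criteria(ds, crf_contour) for ds in datasets]
    included = [ds for ds, fl in zip(datasets, flags) if fl.included]
    n_tests = max(len(included), 1)
    results = []
    for ds, fl in zip(datasets, flags):
        if not fl.included:
            results.append(BOResult(ds.unit_id, ds.dataset_id,
                                    ds.edge_orientation_deg,
                                    boi=float("nan"), p=float("nan"),
                                    p_corrected=float("nan"), significant=False,
                                    preferred_side_deg=float("nan"),
                                    included=False, flags=fl))
            continue
        boi = dataset_boi(ds)
        pr = permutation_test_boi(ds, n_shuffles=n_shuffles,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        p_bonf = min(pr.p * n_tests, 1.0)
        sig = p_bonf < alpha
        results.append(BOResult(ds.unit_id, ds.dataset_id,
                                ds.edge_orientation_deg,
                                boi=boi, p=pr.p, p_corrected=p_bonf,
                                significant=sig,
                                preferred_side_deg=preferred_side(boi, ds.geometry),
                                included=True, flags=fl))
    return results


def results_table(results: Sequence[BOResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(dict(unit_id=r.unit_id, dataset_id=r.dataset_id,
                         edge_orientation_deg=r.edge_orientation_deg,
                         boi=r.boi, p=r.p, p_corrected=r.p_corrected,
                         significant=r.significant,
                         preferred_side_deg=r.preferred_side_deg,
                         included=r.included))
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# columnar clustering of the preferred side


def select_clustering_sides(results: Sequence[BOResult]) -> np.ndarray:
    """Per-unit preferred sides for the clustering test of one penetration.

    For each orientation, each unit contributes its significant dataset with
    the highest |BOI| (ties broken toward the lower orientation value); the
    largest subgroup sharing the same geometry is retained, so each unit
    contributes at most one dataset.  Returns the preferred side (deg) per
    retained unit.
    """
    sig = [r for r in results if r.significant and np.isfinite(r.boi)]
    if not sig:
        return np.array([])
    best: dict[tuple[str, float], BOResult] = {}
    for r in sig:
        key = (r.unit_id, r.edge_orientation_deg)
        cur = best.get(key)
        if cur is None or abs(r.boi) > abs(cur.boi):
            best[key] = r
    # group by geometry (orientation + dataset), keep the largest subgroup;
    # tie-break toward the lower orientation value
    groups: dict[tuple[float, int], list[BOResult]] = {}
    for r in best.values():
        groups.setdefault((r.edge_orientation_deg, r.dataset_id), []).append(r)
    key = min(groups, key=lambda k: (-len(groups[k]), k[0]))
    chosen: dict[str, BOResult] = {}
    for r in groups[key]:
        cur = chosen.get(r.unit_id)
        if cur is None or abs(r.boi) > abs(cur.boi):
            chosen[r.unit_id] = r
    return np.array([r.preferred_side_deg for r in chosen.values()])


def _proportion_most_common(sides: np.ndarray) -> float:
    """Proportion of units sharing the most common preferred side."""
    _, counts = np.unique(np.round(sides, 6), return_counts=True)
    return counts.max() / counts.sum()


def penetration_clustering(
    sides_by_penetration: dict[str, np.ndarray],
    n_randomizations: int = 2000,
    min_units: int = 4,
    seed: int = 0,
) -> ClusteringResult:
    """Randomization test of columnar clustering of the preferred side.

    ``sides_by_penetration`` maps penetration id to the per-unit preferred
    sides (deg) selected by :func:`select_clustering_sides`.  Penetrations
    with fewer than ``min_units`` units are dropped.  The null assigns each
    unit's side by a fair coin (the two sides of its edge).
    """
    qualifying = {pid: np.asarray(s, dtype=float)
                  for pid, s in sides_by_penetration.items()
                  if len(s) >= min_units}
    if not qualifying:
        warnings.warn("no penetration with enough border-ownership-selective units")
        return ClusteringResult([], float("nan"), float("nan"), float("nan"), 0)
    per_pen = [PenetrationClustering(pid, len(s), _proportion_most_common(s))
               for pid, s in qualifying.items()]
    observed = float(np.mean([p.proportion for p in per_pen]))
    rng = np.random.default_rng(seed)
    ns = np.array([p.n_units for p in per_pen])
    null = np.empty(n_randomizations)
    for i in range(n_randomizations):
        props = []
        for n in ns:
            k = rng.binomial(n, 0.5)
            props.append(max(k, n - k) / n)
        null[i] = np.mean(props)
    pr = randomization_pvalue(null, observed, alternative="greater")
    return ClusteringResult(per_pen, observed, pr.p, pr.p_corrected,
                            n_randomizations)
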