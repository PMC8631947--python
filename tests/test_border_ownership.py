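"""BOI arithmetic, permutation-test behavior, inclusion criteria, preferred
side, and the columnar-clustering randomization test."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminabo import border_ownership as bo
from laminabo.datamodel import StimulusGeometry

from conftest import make_counts_dataset


class TestBOIArithmetic:
    @pytest.mark.parametrize("rates,expected", [
        ((10, 5, 10, 5), 1 / 3),
        ((7, 7, 7, 7), 0.0),
        ((8, 0, 8, 0), 1.0),
        ((0, 8, 0, 8), -1.0),
    ])
    def test_worked_examples(self, rates, expected):
        assert bo.compute_boi(*rates) == pytest.approx(expected)

    def test_all_zero_rates_error(self):
        with pytest.raises(ValueError, match="zero"):
            bo.compute_boi(0, 0, 0, 0)

    @given(st.lists(st.floats(0.0, 200.0), min_size=4, max_size=4),
           st.floats(0.01, 50.0))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_and_scale_invariance(self, rates, c):
        r1, r2, r3, r4 = rates
        if r1 + r2 + r3 + r4 <= 0:
            return
        b = bo.compute_boi(r1, r2, r3, r4)
        assert abs(b) <= 1.0 + 1e-12
        # swapping ownership labels negates BOI exactly
        assert bo.compute_boi(r2, r1, r4, r3) == pytest.approx(-b)
        # rate rescaling leaves BOI unchanged
        assert bo.compute_boi(c * r1, c * r2, c * r3, c * r4) == pytest.approx(b)


class TestPermutationTest:
    def test_identical_counts_give_p_one(self):
        ds = make_counts_dataset({c: [5.0] * 8 for c in (1, 2, 3, 4)})
        assert bo.permutation_test_boi(ds, 1000, seed=0).p == 1.0

    def test_too_few_shuffles_rejected(self):
        ds = make_counts_dataset({c: [5.0] * 8 for c in (1, 2, 3, 4)})
        with pytest.raises(ValueError, match="n_shuffles"):
            bo.permutation_test_boi(ds, 50, seed=0)

    def test_no_spikes_rejected(self):
        ds = make_counts_dataset({c: [0.0] * 8 for c in (1, 2, 3, 4)})
        with pytest.raises(ValueError, match="no spikes"):
            bo.permutation_test_boi(ds, 1000, seed=0)

    def test_power_on_strong_modulation(self):
        """Pref 40 sp/s vs non-pref 10 sp/s at 10 trials: p < 0.01 nearly always."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ds = make_counts_dataset({
                1: rng.poisson(18, 10).astype(float),
                3: rng.poisson(18, 10).astype(float),
                2: rng.poisson(4.5, 10).astype(float),
                4: rng.poisson(4.5, 10).astype(float),
            })
            hits += bo.permutation_test_boi(ds, 2000, seed=seed).p < 0.01
        assert hits >= 19

    def test_invariant_to_within_condition_relabeling(self):
        rng = np.random.default_rng(4)
        counts = {c: rng.poisson(10, 8).astype(float) for c in (1, 2, 3, 4)}
        ds1 = make_counts_dataset(counts)
        shuffled = {c: v[::-1].copy() for c, v in counts.items()}
        ds2 = make_counts_dataset(shuffled)
        p1 = bo.permutation_test_boi(ds1, 5000, seed=9).p
        p2 = bo.permutation_test_boi(ds2, 5000, seed=9).p
        assert p1 == p2


class TestPreferredSide:
    def test_geometry_convention(self):
        geom = StimulusGeometry(0, 16.0, 90.0, (0.0, 0.0), 180.0)
        assert bo.preferred_side(0.4, geom) == 180.0
        assert bo.preferred_side(-0.4, geom) == 0.0

    def test_antisymmetry(self, geometry):
        a = bo.preferred_side(0.3, geometry)
        b = bo.preferred_side(-0.3, geometry)
        assert (a - b) % 360.0 == 180.0

    def test_tie_is_nan(self, geometry):
        assert np.isnan(bo.preferred_side(0.0, geometry))


class TestInclusionCriteria:
    def _contour(self, cx=5.0, cy=5.0, r=1.5):
        th = np.linspace(0, 2 * np.pi, 41)
        return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])

    def test_low_rate_fails_criterion_1(self, geometry):
        # 0.2 spikes / 450 ms window = 0.44 sp/s in every condition
        ds = make_counts_dataset({c: [0.2] * 8 for c in (1, 2, 3, 4)})
        ds.geometry = geometry
        flags = bo.apply_inclusion_criteria(ds, self._contour())
        assert not flags.min_rate and not flags.included

    def test_five_trials_fails_criterion_3(self, geometry):
        counts = {c: [20.0] * 8 for c in (1, 2, 3, 4)}
        counts[2] = [20.0] * 5
        ds = make_counts_dataset(counts)
        ds.geometry = geometry
        flags = bo.apply_inclusion_criteria(ds, self._contour())
        assert not flags.min_trials

    def test_edge_outside_crf_fails_criterion_4(self, geometry):
        ds = make_counts_dataset({c: [20.0] * 8 for c in (1, 2, 3, 4)})
        ds.geometry = geometry
        flags = bo.apply_inclusion_criteria(ds, self._contour(cx=30.0, cy=30.0))
        assert not flags.edge_in_crf

    def test_contour_near_noncentral_edge_fails_criterion_5(self, geometry):
        ds = make_counts_dataset({c: [20.0] * 8 for c in (1, 2, 3, 4)})
        ds.geometry = geometry
        # square side 16 centered on edge (5,5): lateral edges at az -3 and 13
        flags = bo.apply_inclusion_criteria(ds, self._contour(cx=12.0, cy=5.0))
        assert flags.edge_in_crf and not flags.crf_clear_of_edges

    def test_passing_dataset_included(self, geometry):
        rng = np.random.default_rng(0)
        ds = make_counts_dataset(
            {c: rng.poisson(20, 8).astype(float) for c in (1, 2, 3, 4)},
            pretrial={c: rng.poisson(1, 8).astype(float) for c in (1, 2, 3, 4)})
        ds.geometry = geometry
        flags = bo.apply_inclusion_criteria(ds, self._contour())
        assert flags.included

    def test_missing_contour_undeterminable(self, geometry):
        ds = make_counts_dataset({c: [20.0] * 8 for c in (1, 2, 3, 4)})
        ds.geometry = geometry
        flags = bo.apply_inclusion_criteria(ds, None)
        assert not flags.determinable and not flags.included


class TestClustering:
    def test_four_units_same_side_matches_exact_enumeration(self):
        """P(proportion = 1 | fair coin, n=4) = 2 * 0.5^4 = 0.125."""
        sides = {"p1": np.array([90.0] * 4)}
        res = bo.penetration_clustering(sides, n_randomizations=4000, seed=0)
        assert res.p_pref == 1.0
        assert res.p == pytest.approx(0.125, abs=0.02)

    def test_coherent_penetrations_give_p_pref_one(self):
        sides = {f"p{k}": np.array([270.0] * 5) for k in range(4)}
        res = bo.penetration_clustering(sides, n_randomizations=500, seed=1)
        assert res.p_pref == 1.0

    def test_no_qualifying_penetration_warns(self):
        with pytest.warns(UserWarning, match="no penetration"):
            res = bo.penetration_clustering({"p1": np.array([0.0, 180.0])},
                                            n_randomizations=100, seed=0)
        assert np.isnan(res.p_pref)

    def test_proportion_is_majority(self):
        sides = {"p1": np.array([0.0, 0.0, 180.0, 180.0])}
        res = bo.penetration_clustering(sides, n_randomizations=100, seed=0)
        assert res.per_penetration[0].proportion == 0.5

    def test_random_sides_p_roughly_uniform(self):
        """Under i.i.d. fair-coin sides the randomization p is ~ Uniform(0,1)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(150):
            sides = {f"p{k}": rng.choice([0.0, 180.0], size=6) for k in range(5)}
            res = bo.penetration_clustering(sides, n_randomizations=400,
                                            seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.p)
        stat = kstest(pvals, "uniform")
        assert stat.pvalue > 1e-4


class TestSelection:
    def _result(self, unit, orient, boi, side, sig=True, ds_id=0):
        return bo.BOResult(unit, ds_id, orient, boi, 0.001, 0.004, sig, side, True)

    def test_highest_abs_boi_per_orientation(self):
        results = [
            self._result("u0", 0.0, 0.2, 90.0),
            self._result("u0", 0.0, -0.6, 270.0),
            self._result("u1", 0.0, 0.5, 90.0),
        ]
        sides = bo.select_clustering_sides(results)
        assert sorted(sides) == [90.0, 270.0]

    def test_largest_geometry_subgroup_retained(self):
        results = [
            self._result("u0", 0.0, 0.5, 90.0, ds_id=0),
            self._result("u1", 0.0, 0.4, 90.0, ds_id=0),
            self._result("u2", 90.0, 0.9, 0.0, ds_id=1),
        ]
        sides = bo.select_clustering_sides(results)
        assert len(sides) == 2 and set(sides) == {90.0}

    def test_nonsignificant_excluded(self):
        results = [self._result("u0", 0.0, 0.5, 90.0, sig=False)]
        assert bo.select_clustering_sides(results).size == 0
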