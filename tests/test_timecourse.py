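"""Kernel, response functions, index functions, latency machinery, and BOR."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from laminabo import synth
from laminabo import timecourse as tc
from laminabo._stats import threshold_latency


class TestKernel:
    def test_zero_at_origin_and_decay(self):
        t = np.array([0.0, 1e4])
        k = tc.psp_kernel(t)
        assert k[0] == 0.0
        assert k[1] < 1e-12

    def test_negative_times_zero(self):
        assert tc.psp_kernel(np.array([-5.0]))[0] == 0.0

    def test_argmax_matches_numerical_maximization(self):
        """Closed form tau_g ln((tau_g+tau_d)/tau_g) vs numerical optimum."""
        closed = tc.psp_kernel_argmax(1.0, 20.0)
        assert closed == pytest.approx(np.log(21.0), abs=1e-12)
        res = minimize_scalar(lambda t: -tc.psp_kernel(np.array([t]))[0],
                              bounds=(0.1, 20.0), method="bounded",
                              options={"xatol": 1e-6})
        assert closed == pytest.approx(res.x, abs=0.01)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="time constants"):
            tc.psp_kernel(np.array([1.0]), tau_g_ms=0.0)


class TestThresholdLatency:
    t = np.arange(0.0, 501.0, 1.0)

    def _f(self, segments):
        f = np.zeros_like(self.t)
        for lo, hi, v in segments:
            f[(self.t >= lo) & (self.t < hi)] = v
        return f

    def test_sustained_step(self):
        f = self._f([(80, 501, 1.0)])
        assert threshold_latency(self.t, f, 0.5) == 80.0

    def test_always_below(self):
        assert np.isnan(threshold_latency(self.t, self._f([]), 0.5))

    def test_persistence_rule_skips_blip(self):
        f = self._f([(60, 70, 1.0), (120, 501, 1.0)])
        assert threshold_latency(self.t, f, 0.5) == 120.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        f = np.cumsum(rng.normal(0.02, 0.1, self.t.size)).clip(min=0)
        lats = [threshold_latency(self.t, f, thr) for thr in (0.2, 0.5, 1.0)]
        defined = [x for x in lats if np.isfinite(x)]
        assert all(a <= b for a, b in zip(defined, defined[1:]))

    def test_tail_window_cannot_qualify(self):
        f = self._f([(495, 501, 1.0)])
        assert np.isnan(threshold_latency(self.t, f, 0.5))


def _poisson_trains(rate_hz, n_trials, rng, t_range=(-400.0, 500.0)):
    dur = t_range[1] - t_range[0]
    out = []
    for _ in range(n_trials):
        n = rng.poisson(rate_hz * dur / 1000.0)
        out.append(np.sort(rng.uniform(*t_range, n)))
    return out


class TestResponseFunctions:
    def test_identical_trains_give_equal_functions(self):
        rng = np.random.default_rng(0)
        trains = _poisson_trains(20.0, 8, rng)
        spike_trains = {c: [t.copy() for t in trains] for c in (1, 2, 3, 4)}
        rf = tc.response_functions(spike_trains)
        np.testing.assert_allclose(rf.pref, rf.nonpref)

    def test_scale_invariance_of_normalized_functions(self):
        """Duplicating every spike leaves the normalized functions unchanged."""
        rng = np.random.default_rng(1)
        spike_trains = {c: _poisson_trains(15.0, 6, rng) for c in (1, 2, 3, 4)}
        rf1 = tc.response_functions(spike_trains)
        doubled = {c: [np.sort(np.concatenate([t, t])) for t in v]
                   for c, v in spike_trains.items()}
        rf2 = tc.response_functions(doubled)
        np.testing.assert_allclose(rf1.pref, rf2.pref, atol=1e-12)
        assert rf2.norm_const == pytest.approx(2.0 * rf1.norm_const)

    def test_no_spikes_cannot_normalize(self):
        spike_trains = {c: [np.array([])] * 4 for c in (1, 2, 3, 4)}
        with pytest.raises(ValueError, match="normaliz"):
            tc.response_functions(spike_trains)

    def test_normalization_constant_definition(self):
        """Mean of (pref+nonpref)/2 over [50, 500] ms equals 1."""
        rng = np.random.default_rng(2)
        spike_trains = {c: _poisson_trains(10.0 * c, 8, rng) for c in (1, 2, 3, 4)}
        rf = tc.response_functions(spike_trains)
        sel = (rf.t_ms >= 50.0) & (rf.t_ms < 500.0)
        mean = ((rf.pref + rf.nonpref) / 2.0)[sel].mean()
        assert mean == pytest.approx(1.0, abs=0.01)


class TestIndexFunction:
    t = np.arange(0.0, 501.0, 1.0)

    def test_ratio_arithmetic(self):
        P = np.full((3, self.t.size), 3.0)
        N = np.full((3, self.t.size), 1.0)
        b = tc.boi_function(P, N, self.t)
        np.testing.assert_allclose(b.value, 0.5)

    def test_equal_functions_give_zero(self):
        P = np.random.default_rng(0).uniform(1, 2, (4, self.t.size))
        b = tc.boi_function(P, P.copy(), self.t)
        np.testing.assert_allclose(b.value, 0.0)

    def test_bounded_and_floor_flagged(self):
        P = np.zeros((2, self.t.size))
        N = np.zeros((2, self.t.size))
        b = tc.boi_function(P, N, self.t)
        assert b.floored.all()
        assert np.all(np.abs(b.value) <= 1.0)


class TestDivergenceLatency:
    def test_identical_populations_undefined(self):
        t = np.arange(0.0, 201.0, 1.0)
        P = np.random.default_rng(0).uniform(1, 2, (12, t.size))
        assert np.isnan(tc.divergence_latency(P, P.copy(), t))

    def test_step_divergence_recovered(self):
        t = np.arange(0.0, 201.0, 1.0)
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 2, (30, t.size))
        P = base + 0.001 * rng.standard_normal((30, t.size))
        N = base - 0.5 * (t >= 80.0)[None, :]
        assert tc.divergence_latency(P, N, t) == pytest.approx(80.0, abs=1.0)

    def test_transient_divergence_rejected(self):
        t = np.arange(0.0, 201.0, 1.0)
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 2, (30, t.size))
        P = base + 0.001 * rng.standard_normal((30, t.size))
        N = base - 0.5 * ((t >= 80.0) & (t < 90.0))[None, :]
        assert np.isnan(tc.divergence_latency(P, N, t))


class TestShuffleThreshold:
    def test_identical_compartments_get_equal_thresholds(self):
        t = np.arange(0.0, 501.0, 1.0)
        rng = np.random.default_rng(3)
        P = rng.uniform(1, 2, (40, t.size))
        N = rng.uniform(1, 2, (40, t.size))
        thr, per = tc.shuffle_threshold({"a": (P, N), "b": (P.copy(), N.copy())},
                                        t, n_shuffles=400, seed=5)
        assert per["a"] == pytest.approx(per["b"], abs=0.001)

    def test_self_consistency_under_null(self):
        """At the returned threshold, <1% of fresh shuffles have a latency."""
        t = np.arange(0.0, 501.0, 1.0)
        rng = np.random.default_rng(4)
        P = rng.uniform(1, 2, (40, t.size))
        N = rng.uniform(1, 2, (40, t.size))
        thr, _ = tc.shuffle_threshold({"a": (P, N)}, t, n_shuffles=1000, seed=6)
        shuf = tc._shuffled_population_index(P, N, 1000,
                                             np.random.default_rng(7))
        rate = np.mean([np.isfinite(tc.index_latency(f, t, thr)) for f in shuf])
        assert rate < 0.02

    def test_stability_in_n_shuffles(self):
        t = np.arange(0.0, 501.0, 1.0)
        rng = np.random.default_rng(8)
        P = rng.uniform(1, 2, (60, t.size))
        N = rng.uniform(1, 2, (60, t.size))
        t1, _ = tc.shuffle_threshold({"a": (P, N)}, t, n_shuffles=1000, seed=1)
        t2, _ = tc.shuffle_threshold({"a": (P, N)}, t, n_shuffles=2000, seed=2)
        assert abs(t1 - t2) < 0.01

    def test_degenerate_population_rejected(self):
        t = np.arange(0.0, 501.0, 1.0)
        Z = np.zeros((5, t.size))
        with pytest.raises(ValueError, match="degenerate"):
            tc.shuffle_threshold({"a": (Z, Z.copy())}, t, n_shuffles=100, seed=0)


class TestBootstrap:
    t = np.arange(0.0, 501.0, 1.0)

    def _pop(self, n, latency, rng):
        ramp = 1.0 / (1.0 + np.exp(-(self.t - latency) / 3.0))
        P = 1.0 + 0.6 * ramp + 0.05 * rng.standard_normal((n, self.t.size))
        N = 1.0 - 0.0 * ramp + 0.05 * rng.standard_normal((n, self.t.size))
        return P, N

    def test_ci_brackets_constructed_latency(self):
        rng = np.random.default_rng(0)
        P, N = self._pop(40, 120.0, rng)
        est, _ = tc.bootstrap_latency_ci(P, N, self.t, threshold=0.1,
                                         n_boot=200, seed=1)
        assert est.ci_valid
        assert est.ci95_ms[0] <= est.latency_ms <= est.ci95_ms[1]
        assert abs(est.latency_ms - 120.0) < 10.0

    def test_single_unit_degenerate_ci(self):
        rng = np.random.default_rng(1)
        P, N = self._pop(1, 100.0, rng)
        est, _ = tc.bootstrap_latency_ci(P, N, self.t, threshold=0.1,
                                         n_boot=50, seed=2)
        assert est.ci95_ms[0] == est.ci95_ms[1] == est.latency_ms

    def test_identical_populations_compare_at_half(self):
        rng = np.random.default_rng(2)
        P, N = self._pop(40, 100.0, rng)
        p, _, _ = tc.compare_latencies((P, N), (P.copy(), N.copy()), self.t,
                                       threshold=0.1, n_boot=300, seed=3)
        assert 0.2 < p < 0.8

    def test_undefined_observed_latency_rejected(self):
        rng = np.random.default_rng(3)
        P, N = self._pop(10, 100.0, rng)
        flat = np.ones_like(P)
        with pytest.raises(ValueError, match="defined"):
            tc.compare_latencies((flat, flat.copy()), (P, N), self.t,
                                 threshold=0.5, n_boot=100, seed=4)


class TestBOR:
    def _regular(self, period_ms, t_range=(0.0, 500.0)):
        return np.arange(t_range[0] + period_ms / 2.0, t_range[1], period_ms)

    def test_deterministic_order_gives_one(self):
        """Strictly ordered window counts -> BOR = 1 at every defined window."""
        trains = {1: [self._regular(5.0)] * 6, 3: [self._regular(5.0)] * 6,
                  2: [self._regular(25.0)] * 6, 4: [self._regular(25.0)] * 6}
        f = tc.bor_function(trains, n_sets=500, seed=0)
        defined = f.bor[np.isfinite(f.bor)]
        assert defined.size > 0
        np.testing.assert_allclose(defined, 1.0)

    def test_min_spikes_rule(self):
        """Windows holding fewer than 10 spikes across conditions are undefined."""
        one = [np.array([250.0])]
        trains = {1: one * 2, 2: [np.array([])] * 2,
                  3: [np.array([400.0, 401.0])] * 2, 4: [np.array([])] * 2}
        f = tc.bor_function(trains, n_sets=200, seed=1)
        assert np.isnan(f.bor).all()  # at most 6 spikes anywhere

    def test_symmetric_rates_near_half(self):
        # large-trial regime: the in-sample preferred-side bias
        # (~arcsin(sqrt(w/nT))/pi) is negligible at 100 trials
        rng = np.random.default_rng(5)
        trains = {c: _poisson_trains(30.0, 100, rng, t_range=(0.0, 500.0))
                  for c in (1, 2, 3, 4)}
        f = tc.bor_function(trains, n_sets=10_000, seed=2)
        assert np.nanmean(f.bor) == pytest.approx(0.5, abs=0.03)

    def test_tied_preferred_side_skipped(self):
        trains = {c: [self._regular(10.0)] * 4 for c in (1, 2, 3, 4)}
        with pytest.warns(UserWarning, match="tied"):
            assert tc.bor_function(trains, n_sets=200, seed=3) is None

    def test_population_latency_recovers_planted_onset(self):
        """Planted BO latency 90 ms recovered within +-10 ms by the
        shuffle-thresholded mean BOR function (right-edge convention)."""
        import warnings
        params = synth.BOSessionParams(
            n_units={"deep": 50},
            bo_latency_ms={"superficial": 100.0, "granular": 95.0, "deep": 90.0})
        session, _ = synth.gen_bo_session(params, seed=7)
        fns = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, u in enumerate(session.units):
                trains = tc.unit_condition_spike_trains(session, u.unit_id, 0)
                f = tc.bor_function(trains, n_sets=2000, seed=k)
                if f is not None:
                    fns.append(f)
        mat = np.stack([f.bor for f in fns])
        t = fns[0].t_ms
        thr, _ = tc.bor_shuffle_threshold({"deep": mat}, t, n_shuffles=300, seed=1)
        assert thr > 0.5  # BOR shuffles hover around 1/2
        est, _ = tc.bor_population_latency(fns, thr, n_boot=100, seed=2)
        assert est.latency_ms == pytest.approx(90.0, abs=10.0)

    def test_population_latency_on_constructed_functions(self):
        """Mean BOR stepping to 1 at t=100 -> latency 100 (right-edge grid)."""
        t = np.arange(0.0, 501.0, 1.0)
        bor = np.where(t >= 100.0, 1.0, 0.5)[None, :].repeat(12, axis=0)
        fns = [tc.BORFunction("u", t, bor[i], 100.0, 100, 1) for i in range(12)]
        est, _ = tc.bor_population_latency(fns, threshold=0.75, n_boot=100, seed=0)
        assert est.latency_ms == 100.0


class TestRingLatency:
    def test_instant_step_latency(self):
        t = np.arange(-100.0, 301.0, 1.0)
        f = (t >= 50.0).astype(float)[None, :].repeat(8, axis=0)
        ests, comps, thr = tc.ring_latencies({"a": f, "b": f.copy()}, t,
                                             n_boot=50, seed=0)
        assert thr == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert ests["a"].latency_ms == 50.0
        assert 0.2 < comps[("a", "b")] < 0.8

    def test_compartment_ordering_recovered(self):
        rng = np.random.default_rng(0)
        t = np.arange(-100.0, 301.0, 1.0)

        def pop(n, lat):
            ramp = 1.0 / (1.0 + np.exp(-(t - lat) / 2.0))
            return np.clip(0.05 + 0.95 * ramp
                           + 0.05 * rng.standard_normal((n, t.size)), 0, None)

        pops = {"granular": pop(60, 48.0), "deep": pop(60, 52.0)}
        ests, comps, _ = tc.ring_latencies(pops, t, n_boot=200, seed=1)
        assert ests["granular"].latency_ms < ests["deep"].latency_ms
        assert comps[("granular", "deep")] < 0.05


class TestSubsample:
    t = np.arange(0.0, 501.0, 1.0)

    def test_full_sample_single_repeat_reproduces_estimate(self):
        rng = np.random.default_rng(0)
        ramp = 1.0 / (1.0 + np.exp(-(self.t - 90.0) / 3.0))
        P = 1.0 + 0.5 * ramp + 0.02 * rng.standard_normal((20, self.t.size))
        N = 1.0 + 0.02 * rng.standard_normal((20, self.t.size))
        b = tc.boi_function(P, N, self.t)
        full = tc.index_latency(b.value, self.t, 0.1)
        lats = tc.subsample_latencies(P, N, self.t, 0.1, target_n=20,
                                      n_repeats=1, seed=1)
        assert lats[0] == full

    def test_oversized_target_rejected(self):
        P = np.ones((5, self.t.size))
        with pytest.raises(ValueError, match="target_n"):
            tc.subsample_latencies(P, P.copy(), self.t, 0.1, target_n=6)


def test_cp_function_polarity_grouping():
    """Contrast-polarity index: planted cp modulation appears as a plateau."""
    params = synth.BOSessionParams(n_units={"deep": 30}, cp_modulation=0.3,
                                   bo_modulation=0.0)
    session, _ = synth.gen_bo_session(params, seed=31)
    fns = []
    for u in session.units:
        trains = tc.unit_condition_spike_trains(session, u.unit_id, 0)
        fns.append(tc.response_functions(trains, unit_id=u.unit_id,
                                         grouping="polarity"))
    t, P, N = tc.stack_population(fns)
    cp = tc.boi_function(P, N, t)
    sel = (t >= 200) & (t <= 500)
    assert cp.value[sel].mean() == pytest.approx(0.3, abs=0.05)
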