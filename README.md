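# laminabo

Laminar analysis of **border ownership** in extracellular recordings from
primate visual cortex (area V4).

A border-ownership stimulus shows an identical luminance edge inside a
neuron's classical receptive field (cRF) while the *object that owns the
edge* sits on one side or the other. Many V4 neurons fire more when the
edge belongs to an object on their preferred side, even though nothing
inside the cRF changes. This package implements the full analysis chain for
asking *where in the cortical microcircuit* that signal arises: which
laminar compartment (superficial, granular, deep) expresses
border-ownership selectivity first, whether neurons with the same preferred
side cluster into columns, and how border ownership relates to orientation
tuning.

It is written for electrophysiologists working with linear multi-contact
("laminar") probes: spike times per unit per trial, a trial-aligned LFP
across 32 contacts at 100 µm pitch, reverse-correlation receptive-field
mapping streams, and orientation-tuning trials.

## The statistics at the core

**Border-ownership index.** With `R_i` the mean rate in [50, 500] ms for
the four conditions (1/2: the two ownership sides at one contrast polarity,
3/4: the same sides with luminances reversed),

    BOI = ((R1 + R3) − (R2 + R4)) / (R1 + R3 + R2 + R4)

Significance comes from a permutation test that shuffles the ownership
labels within each contrast-polarity pair (10,000 shuffles).

**Time course.** Spike trains are convolved with a postsynaptic kernel
`K(t) = (1 − e^(−t/τ_g)) e^(−t/τ_d)` (τ_g = 1 ms, τ_d = 20 ms), averaged
into preferred / non-preferred response functions, and combined into the
index function `B(t) = (R_pref(t) − R_nonpref(t)) / (R_pref(t) + R_nonpref(t))`.
Latency is the earliest crossing of a threshold held for 20 consecutive ms;
the threshold is calibrated so that fewer than 1% of label-shuffled
populations produce any latency at all, and the highest threshold across
laminar compartments is applied to every compartment. Confidence intervals
use a BCa bootstrap over units; compartments are compared with a one-sided
bootstrap on latency differences.

**Border-ownership reliability (BOR).** In 100 ms sliding windows, sets of
four single-trial spike counts are drawn (one per condition) and BOR is the
fraction of sets whose count-difference sign matches the unit's across-trial
preferred side — a trial-resampled reliability measure with the same latency
machinery applied to its population mean.

**Laminar assignment.** The current source density, the negative second
spatial difference of the 3.3–88 Hz band-passed trial-averaged LFP,
exposes the earliest prominent current sink, which marks the granular
(input) layer; units are placed at the waveform-amplitude-weighted depth of
their five-contact footprint and classified relative to that band.

**Orientation.** Orientation statistics live in the doubled-angle domain
(orientation has period 180°): preferred orientation is the direction / 2 of
the rate-weighted resultant, columnar aggregates and their randomization
tests operate on unit resultants, and the relation between preferred
orientation and the circular mean of border-ownership-selective orientations
is measured as the perpendicular distance to the periodic identity line.

Because public data for this kind of experiment exist only as
figure-embedded values, the package ships a first-class synthetic-session
generator (`laminabo.synth`) with planted ground truth — inhomogeneous
Poisson units with compartment-specific response and modulation latencies,
columnar sharing of the preferred side, a forward-modeled laminar LFP, and
von-Mises orientation tuning — so every stage is tested by parameter
recovery and null calibration.

## Worked example

```python
import numpy as np
from laminabo import synth, border_ownership as bo, timecourse as tc

params = synth.BOSessionParams(
    n_units={"superficial": 40, "granular": 60, "deep": 80})
session, truth = synth.gen_bo_session(params, seed=1)

# one unit's dataset: rates, BOI, permutation test
d = bo.build_bo_datasets(session)[12]
print({c: round(r, 1) for c, r in d.rates.items()})
print(f"BOI = {bo.dataset_boi(d):+.3f}")
print(f"p = {bo.permutation_test_boi(d, 10_000, seed=2).p:.4f}")

# population BOI-function latencies per laminar compartment
comp_of = {u.unit_id: u.compartment for u in truth.units}
fns = {}
for u in session.units:
    trains = tc.unit_condition_spike_trains(session, u.unit_id, 0)
    fns.setdefault(comp_of[u.unit_id], []).append(
        tc.response_functions(trains, unit_id=u.unit_id))
pops = {}
for comp, lst in fns.items():
    t, P, N = tc.stack_population(lst)
    pops[comp] = (P, N)
threshold, _ = tc.shuffle_threshold(pops, t, n_shuffles=1000, seed=3)
for comp in ("deep", "granular", "superficial"):
    P, N = pops[comp]
    lat = tc.index_latency(tc.boi_function(P, N, t).value, t, threshold)
    print(f"{comp:12s} latency = {lat:.0f} ms")
p, est_deep, _ = tc.compare_latencies(pops["deep"], pops["granular"],
                                      t, threshold, n_boot=500, seed=4)
print(f"deep earlier than granular: p = {p:.3f}")
```

prints

```
{1: 85.6, 2: 38.6, 3: 38.9, 4: 19.2}
BOI = +0.366
p = 0.0000
deep         latency = 75 ms
granular     latency = 99 ms
superficial  latency = 103 ms
deep earlier than granular: p = 0.014
```

The example unit fires ~twice as hard when the edge is owned from its
preferred side at both contrast polarities (BOI 0.37, permutation p <
0.0001). At the population level the border-ownership signal emerges in the
deep compartment ~24 ms before the granular compartment — recovering the
generator's planted onsets (75 / 95 / 100 ms) — and the one-sided bootstrap
comparison calls the deep lead significant.

There is also a CLI mirroring the stages (`laminabo simulate / rf / csd /
bo / timecourse / orient / cluster / report`); run `laminabo --help`.

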