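# Methods

This note documents the models, estimators, parameter defaults, and
numerical conventions in `laminabo`, and what the synthetic tests do and do
not demonstrate about real recordings.

## Data model and conventions

A session is one penetration of a 32-contact laminar probe (100 µm pitch).
Times are ms relative to stimulus onset, with the recorded epoch
[−400, 1500] ms; angles are degrees; depth is mm increasing downward from
the most superficial contact (higher contact index = more superficial).
Border-ownership conditions are numbered 1–4: {1, 2} share one luminance
pairing and {3, 4} the reversed luminances; {1, 3} put the owning square on
"side A" of the central edge and {2, 4} on side B, so the stimulus inside
the cRF is identical within each polarity pair. A "preferred side" is a
true direction (period 360°): the outward normal from the edge toward the
owning square of the preferred configuration. Sessions are stored as a JSON
manifest plus CSV tables (spikes, trials, units) and HDF5 for the LFP;
undefined statistics serialize as explicit JSON nulls.

## Border-ownership selectivity

Rates are spike counts in [50, 500] ms divided by the window length.
`BOI = ((R1+R3) − (R2+R4)) / ΣR_i`; it is exactly antisymmetric under
ownership-label exchange and invariant to rate rescaling. The permutation
test pools the trial counts within each polarity pair, permutes them
independently for the two pairs (default 10,000 shuffles), and reports the
plain fraction of |BOI_shuffled| ≥ |BOI| alongside the add-one-corrected
value (k+1)/(n+1); the pooled counts are sorted before permuting so the
null stream — and hence p — is exactly invariant to relabeling trials
within a condition. Significance uses p < 0.05 with Bonferroni correction
across a unit's included datasets.

Inclusion requires: (1) ≥ 1 sp/s in at least one condition; (2) evoked
counts differing from pre-trial counts for at least one condition
(two-sided rank-sum, Bonferroni over the four conditions; the 400 ms
pre-trial counts are scaled to the 450 ms evoked-window length so both
samples estimate the same rate under H0); (3) at least six trials per
condition; (4) the central edge intersecting the z = 3 cRF contour
(segment–polygon intersection); (5) the contour keeping ≥ 1 dva clearance
from all non-central square edges. Without a cRF contour, criteria 4–5 are
undeterminable and the dataset is excluded with that reason.

## Response functions and latency estimation

Spike trains are rounded to a 0.1 ms grid and convolved with
`K(t) = (1 − e^(−t/τ_g)) e^(−t/τ_d)` (τ_g = 1 ms, τ_d = 20 ms, no
normalization; the closed-form peak is τ_g·ln((τ_g+τ_d)/τ_g) ≈ 3.045 ms).
Condition means are averaged across contrast polarity into preferred /
non-preferred functions, normalized by the cross-condition mean over
[50, 500] ms, and downsampled to 1 ms for population statistics. Population
index functions use compartment means:
`B(t) = (mean pref − mean nonpref) / (mean pref + mean nonpref)` with the
denominator floored at 10⁻⁶ (flagged wherever active).

Latency is the earliest crossing of a fixed threshold held for 20
consecutive milliseconds, searched in [0, 500] ms; windows that would
extend past the search range can never qualify. The threshold is calibrated
from the null: per compartment, pref/non-pref labels are flipped per unit
(1000 shuffles — label exchange flips the sign of each unit's difference
function while leaving the sum invariant, so shuffled functions are matrix
products, not recomputations), and the lowest threshold on a 0.001 grid at
which < 1% of shuffled functions have a defined latency is retained; the
maximum across compartments times every compartment. The grid search is
implemented as a quantile of each shuffled function's *critical threshold*
(its maximum over t of the 20 ms forward-window minimum), which is exactly
equivalent and O(n log n).

Confidence intervals are 95% BCa bootstrap over unit resampling of the full
pipeline (mean functions → B(t) → threshold latency). The BCa z₀ and
acceleration terms are computed directly (bias from the replicate CDF at
the observed value with ties split, acceleration from jackknife skewness)
because bootstrap replicates with undefined latency must be dropped — their
fraction is reported and the CI is invalidated above 50% undefined. A
single-unit population yields the degenerate CI equal to the point
estimate. Compartments are compared one-sided as the fraction of bootstrap
pairs with latency_B − latency_A ≤ 0; exact ties, an artifact of the 1 ms
latency grid, are split evenly between directions so identical populations
give p ≈ 0.5, while the plain fraction is recovered whenever ties are
negligible.

The sign-rank divergence latency (first t at which a paired Wilcoxon test
across units is p < 0.05 for 20 adjacent ms) is provided for population
pref/non-pref functions, as is a subsampling control that re-times each
compartment after drawing equal-sized unit subsets without replacement.

## Border-ownership reliability (BOR)

For each 100 ms window (1 ms steps, time reported at the window's right
edge), 10,000 sets of four spike trains are drawn, one random trial per
condition; `A(j)` / `B(j)` flag whether `sgn[(C1+C3)−(C2+C4)]` matches or
opposes `S = sgn[(R1+R3)−(R2+R4)]` from the [50, 500] ms rates, and
`BOR = ΣA/(ΣA+ΣB)`. A window is undefined when it holds fewer than 10
spikes across all trials and conditions or when every set ties; units with
S = 0 are skipped with a diagnostic. Population BOR functions are NaN-aware
unit means; their latency uses the same persistence/threshold machinery,
with the shuffle null implemented as per-unit flips BOR → 1 − BOR.

A property worth knowing: because S is estimated from the same trials used
in the window comparisons, a side-symmetric unit has E[BOR] slightly above
1/2 at small trial counts — approximately arcsin(√(w/nT))/π ≈ 0.03 at 8
trials (window w = 100 ms, rate window T = 450 ms) — vanishing as trials
grow. The null-calibration tests therefore run at 100 trials/condition,
where the bias is below 0.015; at the study's 8–10 trials BOR should be
read as a reliability measure with this small optimism, not as an unbiased
probability.

## Current source density and layer assignment

The trial-averaged LFP is band-passed 3.3–88 Hz with a zero-phase
2nd-order Butterworth (forward–backward, preserving latencies), and
`CSD(z,t) = −[φ(z+h) − 2φ(z) + φ(z−h)]/h²` with h = 100 µm — sink-positive,
edge contacts dropped rather than extrapolated (assumption-free). The depth
axis is interpolated to 10 µm with a cubic spline. The granular band is the
earliest contiguous sink region exceeding 50% of the in-window (0–100 ms)
sink maximum; the band spans the depths where the sink at its peak time
stays above 50% of that sink's peak. A map is uninterpretable when the peak
sink is below 5× the robust (MAD-based) pre-stimulus noise level, and a
manual band override is accepted. The 50% rule and SNR gate are this
package's automation of what is otherwise a visual judgement, and they are
deliberately overridable.

Units are placed at the amplitude-weighted mean depth of their five-contact
waveform footprint and classified superficial / granular / deep relative to
the band; units more than 2 mm below the most superficial active contact
are excluded (white-matter guard), as are units with an all-zero footprint.

## Receptive fields and probe orthogonality

Reverse-correlation z-maps count spikes in [30, 100] ms after each event
and compare them, per grid position, with counts in the equal-length window
immediately preceding that position's events (mean difference over baseline
SD; zero-SD positions are recorded as undefined). Maps are smoothed with a
σ = 1 grid-step Gaussian (undefined positions handled by normalized
convolution) and the cRF is the z = 3 contour (marching squares); with
several closed contours the largest-area region is "the" cRF and its area
centroid the center. Note that with rapid event streams the preceding
window of one event overlaps the response window of earlier events; the
z-map tolerates this contamination when the RF covers a small fraction of
the mapping grid (as with the default 25 × 25 dva grid), which is why the
mapping tests run at that full grid size.

The orthogonality metric D fits a least-squares line through (depth,
azimuth, elevation) RF centers within a 2 mm span from the most superficial
center and reports the planar drift rate (dva/mm) — invariant to rigid
translation and to depth reversal.

## Orientation statistics

Selectivity: Kruskal–Wallis on evoked counts [30, 200] ms grouped by
orientation (polarities pooled) at p < 0.05, plus a z ≥ 3 requirement on
the best orientation's rate against the pre-stimulus baseline. Preferred
orientation is direction/2 of the doubled-angle, rate-weighted resultant.
Penetration aggregates take the resultant of unit resultants; the
randomization null redraws unit directions uniformly on the doubled circle
keeping magnitudes (2000 draws). The circular mean of border-ownership-
selective orientations weights doubled-angle vectors by |BOI| over
Bonferroni-significant orientations (≥ 4 tested orientations required). The
identity-line distance for a pair (x, y) of orientations is
|wrap₁₈₀(x−y)|/√2 with the wrap into (−90, 90] — the perpendicular distance
to the nearest periodic identity line — tested against a pairing-shuffle
null. Preferred-side spans are computed on true directions (period 360°),
span = 360° − largest gap, contiguous iff < 180°. The orientation ×
border-ownership contingency table uses a chi-square test without
continuity correction (Fisher's exact test is reported alongside when an
expected cell is < 5).

## The synthetic-session generator

Each unit's rate is

    r(t) = b + A·g(t−L_crf)·[1 + s_bo·m·h(t−L_bo′)]·[1 + s_cp·c·h(t−L_crf)]

with logistic onset envelopes g, h (10 ms rise, so an envelope is ~0 at its
onset and ~1 10 ms later), b the baseline (default 2 sp/s), A the evoked
amplitude (50 sp/s), m the border-ownership modulation (default 0.45,
matching the sustained selectivity such neurons show), c the
contrast-polarity modulation (0.3); b and A get lognormal unit-to-unit
heterogeneity (σ = 0.3). `s_bo` is +1 when the trial's owning side matches
the unit's preferred side; `s_cp` is +1 for the preferred polarity pair.
Spikes are inhomogeneous Poisson (1 ms bins, uniform jitter within bins);
all generators are pure functions of (parameters, seed).

**Latency semantics.** The threshold latency of a kernel-smoothed index
function trails the underlying rate-modulation onset by the kernel's
integration delay — the step response of K(t) reaches half its plateau at
≈ 14.8 ms for (τ_g, τ_d) = (1, 20) ms. Reported latencies in this kind of
experiment are measured on that smoothed scale, so the generator's
`bo_latency` parameter is likewise defined on the measured scale: the
modulation envelope onsets `kernel_step_delay()` earlier, i.e.
L_bo′ = L_bo − 14.8 ms. Planted and estimated latencies are then directly
comparable; the residual recovery error is the population-noise crossing
delay, a few ms. The cRF onset `crf_latency` stays a plain rate-onset
(the ring-latency analyses only compare compartments). Compartment defaults:
cRF onsets granular 48 / deep 50 / superficial 51 ms (feed-forward input
arrives granular-first), BO-modulation latencies deep 75 / granular 95 /
superficial 100 ms (deep-first), unit-to-unit jitter 3 ms.

Columnar structure: each unit shares the penetration's preferred side with
probability `columnar_coherence` (default 0.75, matching the degree of
side-sharing such penetrations exhibit) and takes the opposite side
otherwise.

The LFP forward model plants a sink-positive CSD — an early granular sink
(Gaussian in depth, σ = 0.25 mm; Gaussian in time, peak 45 ms), a source
0.45 mm below it, a later sink 0.85 mm below, and a weak superficial
source — solves φ″ = −CSD with zero-potential boundaries on a fine depth
grid, samples the contacts, and adds spatially smoothed 1/f noise scaled by
1/√n_trials. Double depth-integration of the planted CSD therefore
reproduces the potential exactly up to discretization, making `compute_csd`
an invertibility oracle; oracle comparisons view the planted CSD through
the same temporal band-pass, which commutes with the spatial second
difference. Units are planted at least one contact pitch (0.1 mm) clear of
the band boundaries, since compartment labels inside the
boundary-ambiguous zone are not meaningful in real data either.

RF mapping streams place events every 50 ms at uniform grid positions with
a Poisson background (5 sp/s) plus Poisson(gain·exp(−‖pos−center‖²/2σ²))
evoked spikes uniform in the [30, 100] ms window (defaults: gain 10 spikes
at the optimum, σ = 1.5 dva — a strong transient drive appropriate for
mapping with high-contrast probes). Orientation sessions draw rates from a
doubled-angle von Mises profile (κ default 2) over 12 orientations × 2
polarities with a pre-stimulus epoch for baselines.

**What the generator does not emulate:** spike sorting and waveform noise,
eye movements and fixational jitter, latency–amplitude correlations,
non-Poisson spiking (bursting, refractoriness), attention effects,
cross-penetration CSD variability, and non-multiplicative or transient
border-ownership modulation. Passing recovery tests therefore shows the
estimators are correct and calibrated under the assumed statistical
structure, not that real V4 data satisfy that structure.

## Problem sizes in the test suite

The suite runs at desk scale by choice: permutation calibration uses 2000
null datasets × 10,000 shuffles; BOI/latency recovery uses 200-unit and
(120, 100, 60)-unit populations with 20 replicate simulations and 500
bootstrap draws per comparison; RF mapping uses the full 25 × 25 dva grid
with 8000 events; clustering and orientation calibrations use 150–200
simulated penetrations with 400–2000 randomizations. `scripts/acceptance.py`
re-runs the same chain in well under a minute.

## Known limitations

* The granular-band boundary rule (50% of sink peak) is one reasonable
  automation of a visual criterion; band width estimates inherit bias from
  overlapping sources, which is why the override exists.
* Randomization p-values are reported as plain fractions (they can be 0);
  use the add-one-corrected companion value when a strictly positive
  estimate is needed.
* BOR carries the small in-sample optimism described above at few-trial
  counts.
* The divergence-latency and threshold-latency definitions are
  sample-size-dependent by construction; the subsampling control exists to
  check orderings against that dependence, not to remove it.
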