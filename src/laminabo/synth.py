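"""Synthetic laminar V4 sessions with planted ground truth.

The generators emulate the statistical structure the analysis chain assumes:

* inhomogeneous-Poisson units whose rate is a baseline plus an evoked
  component with a compartment-specific onset latency, multiplicatively
  modulated by border ownership (planted signed BOI ``m``) with a later,
  compartment-specific modulation latency (deep earliest), and by contrast
  polarity;
* columnar sharing of the preferred side of border ownership within a
  penetration;
* a laminar LFP obtained as the exact depth-integral forward model of a
  planted current-source-density pattern — an early granular sink with a
  deeper source and a later deep sink — plus 1/f noise;
* reverse-correlation mapping event streams with Gaussian spatial receptive
  fields;
* von-Mises orientation tuning in the doubled-angle domain.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    LFPBlock,
    RFGridSpec,
    SessionManifest,
    StimulusGeometry,
    UnitMeta,
    make_spike_table,
    make_trial_table,
    Session,
)

COMPARTMENTS = ("superficial", "granular", "deep")

#: evoked-response onset per compartment, ms (granular earliest, as for
#: feed-forward input); values round the study's cRF latency estimates
DEFAULT_CRF_LATENCY_MS = {"superficial": 51.0, "granular": 48.0, "deep": 50.0}

#: border-ownership modulation onset per compartment, ms (deep earliest)
DEFAULT_BO_LATENCY_MS = {"superficial": 100.0, "granular": 95.0, "deep": 75.0}


def onset_ramp(t_ms: np.ndarray, rise_ms: float = 10.0) -> np.ndarray:
    """Smooth unit-amplitude onset envelope (logistic, ~10 ms 2%-98% rise).

    The envelope is ~0 at t=0 (the planted latency) and ~1 at t=rise_ms.
    """
    t = np.asarray(t_ms, dtype=float)
    return expit((t - rise_ms / 2.0) / (rise_ms / 8.0))


@dataclass
class UnitGroundTruth:
    unit_id: str
    compartment: str
    depth_mm: float
    baseline_rate: float          # sp/s
    evoked_amplitude: float       # sp/s
    crf_latency_ms: float
    bo_latency_ms: float
    bo_modulation: float          # planted sustained |BOI| contribution, in [0, 1)
    preferred_side_deg: float     # direction toward the owning square
    cp_modulation: float
    preferred_orientation_deg: float
    kappa: float


@dataclass
class GroundTruth:
    units: list[UnitGroundTruth]
    granular_band_mm: tuple[float, float]
    columnar_side_deg: float
    rf_center_dva: tuple[float, float]
    rf_sigma_dva: float
    columnar_coherence: float
    seed: int

    def __post_init__(self) -> None:
        top, bottom = self.granular_band_mm
        if not top < bottom:
            raise ValueError("granular_band_mm top must be < bottom")
        for u in self.units:
            if not 0.0 <= u.bo_modulation < 1.0:
                raise ValueError(f"bo_modulation must be in [0,1), got {u.bo_modulation}")
            if u.bo_latency_ms < u.crf_latency_ms:
                raise ValueError("bo_latency must be >= crf_latency")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BOSessionParams:
    """Study conditions for a synthetic border-ownership session.

    Defaults emulate the recordings the analysis was designed for: 32-contact
    probe at 100 um pitch, 8 repetitions per condition, a 16-dva square,
    sustained multiplicative BO modulation, and a granular band centered
    mid-penetration.
    """

    n_units: dict[str, int] = field(
        default_factory=lambda: {"superficial": 6, "granular": 8, "deep": 10})
    n_trials_per_condition: int = 8
    baseline_rate: float = 2.0            # sp/s
    evoked_amplitude: float = 50.0        # sp/s
    bo_modulation: float = 0.45
    cp_modulation: float = 0.3
    crf_latency_ms: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CRF_LATENCY_MS))
    bo_latency_ms: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BO_LATENCY_MS))
    latency_jitter_ms: float = 3.0        # unit-to-unit SD around compartment onset
    columnar_coherence: float = 0.75      # P(unit shares the penetration's side)
    columnar_side_deg: float = 270.0
    edge_orientation_deg: float = 0.0     # horizontal central edge
    square_side_dva: float = 16.0
    edge_position_dva: tuple[float, float] = (5.0, 5.0)
    granular_band_mm: tuple[float, float] = (0.95, 1.45)
    n_contacts: int = 32
    contact_pitch_um: float = 100.0
    stim_duration_ms: float = 500.0
    rate_heterogeneity: float = 0.3       # lognormal sigma on rates across units

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.baseline_rate < 0 or self.evoked_amplitude < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.bo_modulation < 1.0:
            raise ValueError("bo_modulation must be in [0, 1)")
        if not 0.0 <= self.cp_modulation < 1.0:
            raise ValueError("cp_modulation must be in [0, 1) "
                             "(instantaneous rate must stay non-negative)")


def _poisson_spike_times(rate_hz: np.ndarray, t_grid_ms: np.ndarray,
                         n_trials: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Spike times for n_trials realizations of an inhomogeneous Poisson process.

    ``rate_hz`` is the rate at the left edge of each 1-ms bin of
    ``t_grid_ms``; counts are Poisson per bin, times uniform within bins.
    """
    dt = t_grid_ms[1] - t_grid_ms[0]
    lam = np.clip(rate_hz, 0.0, None) * dt / 1000.0
    counts = rng.poisson(lam, size=(n_trials, lam.size))
    out = []
    for tr in range(n_trials):
        c = counts[tr]
        idx = np.repeat(np.arange(lam.size), c)
        times = t_grid_ms[idx] + rng.uniform(0.0, dt, size=idx.size)
        out.append(np.sort(times))
    return out


def _depth_to_contact(depth_mm: float, n_contacts: int, pitch_mm: float) -> int:
    contact = n_contacts - 1 - int(round(depth_mm / pitch_mm))
    return int(np.clip(contact, 0, n_contacts - 1))


def _waveform_footprint(depth_mm: float, peak_contact: int,
                        contact_depths: np.ndarray,
                        rng: np.random.Generator) -> tuple:
    """Peak-to-trough amplitudes on the 5 contacts around the peak contact."""
    sigma = 0.12  # mm; spatial decay of the extracellular waveform
    amps = []
    n = contact_depths.size
    for k in range(peak_contact - 2, peak_contact + 3):
        if 0 <= k < n:
            a = 100.0 * np.exp(-((contact_depths[k] - depth_mm) ** 2) / (2 * sigma ** 2))
            a *= rng.lognormal(0.0, 0.05)
        else:
            a = 0.0
        amps.append(float(a))
    return tuple(amps)


def gen_bo_session(
    params: Optional[BOSessionParams] = None,
    seed: int = 0,
) -> tuple[Session, GroundTruth]:
    """Generate a border-ownership session with planted ground truth.

    Each unit's instantaneous rate is

        r(t) = b + A * g(t - L_crf) * (1 + s_bo*m*h(t - L_bo)) * (1 + s_cp*c*h(t - L_crf))

    with logistic onset envelopes g, h; ``s_bo`` is +1 when the trial's
    owning side matches the unit's preferred side, and ``s_cp`` +1 for the
    unit's preferred contrast-polarity pair.
    """
    params = params or BOSessionParams()
    rng = np.random.default_rng(seed)
    # bo_latency is specified on the scale of the *measured* BOI-function
    # latency; the underlying rate modulation onsets earlier by the
    # measurement chain's deterministic smoothing delay (kernel step-response
    # half-rise), so planted and estimated latencies are directly comparable
    from .timecourse import kernel_step_delay
    mod_delay = kernel_step_delay()
    pitch_mm = params.contact_pitch_um / 1000.0
    span_mm = (params.n_contacts - 1) * pitch_mm
    top, bottom = params.granular_band_mm
    if not (0 <= top < bottom <= span_mm):
        raise ValueError("granular band must lie within the probe span")

    geometry = StimulusGeometry(
        dataset_id=0,
        square_side_dva=params.square_side_dva,
        edge_orientation_deg=params.edge_orientation_deg,
        edge_position_dva=params.edge_position_dva,
        side_a_direction_deg=(params.edge_orientation_deg + 90.0) % 360.0,
    )
    manifest = SessionManifest(
        penetration_id=f"synth-{seed}",
        n_contacts=params.n_contacts,
        contact_pitch_um=params.contact_pitch_um,
        datasets=[geometry],
        seed=seed,
    )
    contact_depths = manifest.contact_depths_mm

    # trials: 4 conditions x n repetitions, block-interleaved
    n_rep = params.n_trials_per_condition
    records = []
    tid = 0
    for rep in range(n_rep):
        for cond in (1, 2, 3, 4):
            records.append(dict(
                trial_id=tid, condition_id=cond, dataset_id=0,
                edge_orientation_deg=params.edge_orientation_deg,
                edge_az_dva=params.edge_position_dva[0],
                edge_el_dva=params.edge_position_dva[1],
                onset_time_ms=1000.0 * tid,
            ))
            tid += 1
    trials = make_trial_table(records)

    # ground-truth units
    gt_units: list[UnitGroundTruth] = []
    units_meta: list[UnitMeta] = []
    # units are planted at least one contact pitch clear of the band
    # boundaries: compartment labels are not meaningful inside the
    # boundary-ambiguous zone (one electrode spacing) in real data either
    margin = pitch_mm
    depth_ranges = {
        "superficial": (max(top - 0.75, 0.05), top - margin),
        "granular": (top + margin, bottom - margin),
        "deep": (bottom + margin, min(bottom + 0.75, span_mm - 0.05)),
    }
    uidx = 0
    for comp in COMPARTMENTS:
        lo, hi = depth_ranges[comp]
        for _ in range(params.n_units.get(comp, 0)):
            depth = float(rng.uniform(lo, hi))
            shares = rng.random() < params.columnar_coherence
            side = params.columnar_side_deg if shares else (params.columnar_side_deg + 180.0) % 360.0
            het = rng.lognormal(0.0, params.rate_heterogeneity)
            crf_lat = params.crf_latency_ms[comp] + rng.normal(0.0, params.latency_jitter_ms)
            bo_lat = params.bo_latency_ms[comp] + rng.normal(0.0, params.latency_jitter_ms)
            bo_lat = max(bo_lat, crf_lat)  # modulation cannot precede the response
            unit_id = f"u{uidx:03d}"
            gt_units.append(UnitGroundTruth(
                unit_id=unit_id, compartment=comp, depth_mm=depth,
                baseline_rate=params.baseline_rate * het,
                evoked_amplitude=params.evoked_amplitude * het,
                crf_latency_ms=float(crf_lat), bo_latency_ms=float(bo_lat),
                bo_modulation=params.bo_modulation,
                preferred_side_deg=float(side),
                cp_modulation=params.cp_modulation,
                preferred_orientation_deg=float(rng.uniform(0, 180)),
                kappa=1.5,
            ))
            peak_contact = _depth_to_contact(depth, params.n_contacts, pitch_mm)
            units_meta.append(UnitMeta(
                unit_id=unit_id,
                isolation="single",
                peak_contact=peak_contact,
                contact_amplitudes=_waveform_footprint(
                    depth, peak_contact, contact_depths, rng),
            ))
            uidx += 1

    # spike generation on a 1-ms grid over [-400, stim_duration]
    t_grid = np.arange(-400.0, params.stim_duration_ms, 1.0)
    all_units, all_trials, all_times = [], [], []
    trial_by_cond = {c: trials.loc[trials.condition_id == c, "trial_id"].to_numpy()
                     for c in (1, 2, 3, 4)}
    for gt in gt_units:
        g = onset_ramp(t_grid - gt.crf_latency_ms)
        h_bo = onset_ramp(t_grid - (gt.bo_latency_ms - mod_delay))
        h_cp = onset_ramp(t_grid - gt.crf_latency_ms)
        pref_matches_side_a = np.cos(np.deg2rad(
            gt.preferred_side_deg - geometry.side_a_direction_deg)) > 0
        for cond in (1, 2, 3, 4):
            s_bo = 1.0 if ((cond in (1, 3)) == pref_matches_side_a) else -1.0
            s_cp = 1.0 if cond in (1, 2) else -1.0
            rate = gt.baseline_rate + gt.evoked_amplitude * g \
                * (1.0 + s_bo * gt.bo_modulation * h_bo) \
                * (1.0 + s_cp * gt.cp_modulation * h_cp)
            if np.any(rate < 0):
                raise ValueError("negative instantaneous rate; reduce modulation depths")
            spikes_per_trial = _poisson_spike_times(
                rate, t_grid, len(trial_by_cond[cond]), rng)
            for trial_id, st in zip(trial_by_cond[cond], spikes_per_trial):
                all_units.append(np.full(st.size, gt.unit_id, dtype=object))
                all_trials.append(np.full(st.size, trial_id))
                all_times.append(st)
    spikes = make_spike_table(
        np.concatenate(all_units) if all_units else [],
        np.concatenate(all_trials) if all_trials else [],
        np.concatenate(all_times) if all_times else [],
    )

    gt = GroundTruth(
        units=gt_units,
        granular_band_mm=params.granular_band_mm,
        columnar_side_deg=params.columnar_side_deg,
        rf_center_dva=params.edge_position_dva,
        rf_sigma_dva=1.5,
        columnar_coherence=params.columnar_coherence,
        seed=seed,
    )
    session = Session(manifest=manifest, spikes=spikes, trials=trials,
                      units=units_meta)
    return session, gt


# ---------------------------------------------------------------------------
# laminar LFP forward model


@dataclass
class LFPGroundTruth:
    csd: np.ndarray            # planted CSD at contact depths, (n_time, n_contacts)
    t_ms: np.ndarray
    contact_depths_mm: np.ndarray
    granular_center_mm: float
    granular_sink_peak_ms: float


def _csd_profile(depths_mm: np.ndarray, t_ms: np.ndarray,
                 granular_center_mm: float) -> np.ndarray:
    """Planted sink-positive CSD: early granular sink, deeper source, late deep sink."""
    z = depths_mm[None, :]
    t = t_ms[:, None]

    def dipole(z0, sigma_z, t0, sigma_t, amp):
        return amp * np.exp(-(z - z0) ** 2 / (2 * sigma_z ** 2)) \
                   * np.exp(-(t - t0) ** 2 / (2 * sigma_t ** 2))

    csd = dipole(granular_center_mm, 0.25, 45.0, 12.0, 1.0)          # leading sink
    csd += dipole(granular_center_mm + 0.45, 0.25, 50.0, 12.0, -0.7)  # deep source
    csd += dipole(granular_center_mm + 0.85, 0.25, 75.0, 15.0, 0.5)   # late deep sink
    csd += dipole(granular_center_mm - 0.5, 0.3, 60.0, 15.0, -0.3)    # superficial source
    return csd


def _one_over_f_noise(shape: tuple[int, int], fs_hz: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Temporally 1/f, spatially smooth Gaussian noise, unit peak scale."""
    n_t, n_c = shape
    white = rng.standard_normal((n_t, n_c))
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs_hz)
    gain = np.zeros_like(freqs)
    gain[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = np.fft.rfft(white, axis=0) * gain[:, None]
    noise = np.fft.irfft(spec, n=n_t, axis=0)
    # mild spatial correlation across neighboring contacts
    kernel = np.array([0.25, 0.5, 0.25])
    noise = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), 1, noise)
    peak = np.abs(noise).max()
    return noise / peak if peak > 0 else noise


def gen_lfp_session(
    granular_band_mm: tuple[float, float] = (0.95, 1.45),
    n_contacts: int = 32,
    contact_pitch_um: float = 100.0,
    fs_hz: float = 1000.0,
    epoch_ms: tuple[float, float] = (-100.0, 250.0),
    noise_amplitude: float = 0.05,
    n_trials: int = 50,
    seed: int = 0,
) -> tuple[LFPBlock, LFPGroundTruth]:
    """Forward-model a trial-averaged laminar LFP from a planted CSD.

    The potential solves phi'' = -CSD (sink-positive convention) with
    zero-potential boundaries at both ends of the probe, so that a discrete
    second spatial difference recovers the planted CSD up to discretization.
    Additive 1/f noise is scaled by ``noise_amplitude`` relative to the
    signal peak and by 1/sqrt(n_trials) (trial averaging).
    """
    pitch_mm = contact_pitch_um / 1000.0
    span_mm = (n_contacts - 1) * pitch_mm
    top, bottom = granular_band_mm
    if not (0.0 <= top < bottom <= span_mm):
        raise ValueError("granular band must lie within the probe span")
    rng = np.random.default_rng(seed)
    t_ms = np.arange(epoch_ms[0], epoch_ms[1], 1000.0 / fs_hz)
    depths = (n_contacts - 1 - np.arange(n_contacts)) * pitch_mm
    center = 0.5 * (top + bottom)

    # fine depth grid for an accurate double integration
    fine = np.arange(0.0, span_mm + 1e-9, pitch_mm / 10.0)
    csd_fine = _csd_profile(fine, t_ms, center)
    # phi'' = -csd; integrate twice, then enforce phi=0 at both boundaries
    dz = fine[1] - fine[0]
    first = np.cumsum(-csd_fine, axis=1) * dz
    phi = np.cumsum(first, axis=1) * dz
    phi -= phi[:, :1]
    phi -= (fine / fine[-1])[None, :] * phi[:, -1:]
    # sample at contact depths (contacts ordered by index: deep first contact 0)
    idx = np.round(depths / dz).astype(int)
    data = phi[:, idx]

    if noise_amplitude > 0:
        noise = _one_over_f_noise((t_ms.size, n_contacts), fs_hz, rng)
        data = data + noise * noise_amplitude * np.abs(data).max() / np.sqrt(n_trials)

    lfp = LFPBlock(sampling_rate_hz=fs_hz, t_ms=t_ms, data=data, n_trials=n_trials)
    csd_contacts = _csd_profile(depths, t_ms, center)
    gt = LFPGroundTruth(csd=csd_contacts, t_ms=t_ms, contact_depths_mm=depths,
                        granular_center_mm=center, granular_sink_peak_ms=45.0)
    return lfp, gt


def gen_noise_lfp(n_contacts: int = 32, contact_pitch_um: float = 100.0,
                  fs_hz: float = 1000.0, epoch_ms: tuple[float, float] = (-100.0, 250.0),
                  seed: int = 0) -> LFPBlock:
    """Pure-noise LFP with no planted dipoles (null input for CSD tests)."""
    rng = np.random.default_rng(seed)
    t_ms = np.arange(epoch_ms[0], epoch_ms[1], 1000.0 / fs_hz)
    data = _one_over_f_noise((t_ms.size, n_contacts), fs_hz, rng) * 0.05
    return LFPBlock(sampling_rate_hz=fs_hz, t_ms=t_ms, data=data, n_trials=1)


# ---------------------------------------------------------------------------
# receptive-field mapping streams


def gen_rf_events(
    rf_center_dva: tuple[float, float] = (5.0, 5.0),
    rf_sigma_dva: float = 1.5,
    grid: Optional[RFGridSpec] = None,
    n_events: int = 2000,
    baseline_rate: float = 5.0,     # sp/s continuous background
    gain: float = 10.0,             # expected extra spikes per optimal event
    event_spacing_ms: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Reverse-correlation event stream plus one unit's spike times.

    Events step every ``event_spacing_ms`` at positions drawn uniformly from
    the grid.  Spikes are a homogeneous Poisson background plus, for each
    event, Poisson(gain * exp(-||pos-center||^2 / 2 sigma^2)) evoked spikes
    uniform in the [30, 100] ms post-event window.  Times are absolute
    session time in ms.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    grid = grid or RFGridSpec()
    rng = np.random.default_rng(seed)
    positions = grid.positions()
    pick = rng.integers(0, positions.shape[0], size=n_events)
    onset = np.arange(n_events) * event_spacing_ms + 200.0
    events = pd.DataFrame({
        "event_id": np.arange(n_events),
        "t_ms": onset,
        "azimuth_dva": positions[pick, 0],
        "elevation_dva": positions[pick, 1],
    })
    total_ms = onset[-1] + 500.0
    n_bg = rng.poisson(baseline_rate * total_ms / 1000.0)
    spikes = [rng.uniform(0.0, total_ms, size=n_bg)]
    center = np.asarray(rf_center_dva)
    d2 = np.sum((positions[pick] - center) ** 2, axis=1)
    mean_extra = gain * np.exp(-d2 / (2.0 * rf_sigma_dva ** 2))
    n_extra = rng.poisson(mean_extra)
    for i in np.flatnonzero(n_extra):
        spikes.append(onset[i] + rng.uniform(30.0, 100.0, size=n_extra[i]))
    spike_times = np.sort(np.concatenate(spikes))
    return events, spike_times


def gen_rf_stack(
    depths_mm: np.ndarray,
    center0_dva: tuple[float, float] = (5.0, 5.0),
    drift_dva_per_mm: tuple[float, float] = (0.0, 0.0),
    jitter_dva: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float, float]]:
    """(depth, azimuth, elevation) RF centers drifting linearly with depth.

    Convenience for probe-orthogonality recovery tests.
    """
    rng = np.random.default_rng(seed)
    out = []
    for d in np.asarray(depths_mm, dtype=float):
        az = center0_dva[0] + drift_dva_per_mm[0] * d + rng.normal(0.0, jitter_dva)
        el = center0_dva[1] + drift_dva_per_mm[1] * d + rng.normal(0.0, jitter_dva)
        out.append((float(d), float(az), float(el)))
    return out


# ---------------------------------------------------------------------------
# orientation tuning


def gen_orientation_session(
    preferred_deg: float = 45.0,
    kappa: float = 2.0,
    n_orientations: int = 12,
    n_trials: int = 10,
    baseline_rate: float = 2.0,
    evoked_amplitude: float = 40.0,
    crf_latency_ms: float = 50.0,
    stim_duration_ms: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One unit's orientation-tuning dataset (12 orientations x 2 polarities).

    The evoked rate follows a von Mises profile in the doubled angle:
    amplitude * exp(kappa * (cos(2*(theta - preferred)) - 1)).
    Returns (trials, spikes); trials carry ``orientation_deg`` and
    ``polarity``.  The epoch covers [-250, 300] ms so a pre-stimulus
    baseline window is available.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    orientations = np.arange(n_orientations) * (180.0 / n_orientations)
    t_grid = np.arange(-250.0, 300.0, 1.0)
    g = onset_ramp(t_grid - crf_latency_ms)
    g = g * (t_grid < crf_latency_ms + stim_duration_ms)  # transient stimulus
    rows, su, st, stt = [], [], [], []
    tid = 0
    for theta in orientations:
        tune = np.exp(kappa * (np.cos(2.0 * np.deg2rad(theta - preferred_deg)) - 1.0))
        rate = baseline_rate + evoked_amplitude * tune * g
        for pol in (0, 1):
            spikes_per_trial = _poisson_spike_times(rate, t_grid, n_trials, rng)
            for sp in spikes_per_trial:
                rows.append(dict(trial_id=tid, orientation_deg=float(theta),
                                 polarity=pol, onset_time_ms=1000.0 * tid))
                su.append(np.full(sp.size, "u000", dtype=object))
                st.append(np.full(sp.size, tid))
                stt.append(sp)
                tid += 1
    trials = pd.DataFrame.from_records(rows)
    spikes = make_spike_table(
        np.concatenate(su) if su else [],
        np.concatenate(st) if st else [],
        np.concatenate(stt) if stt else [],
    )
    return trials, spikes
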