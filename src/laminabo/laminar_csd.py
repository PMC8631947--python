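"""Current-source-density analysis of the laminar LFP and assignment of
units to cortical compartments.

The CSD is the negative discrete second spatial difference of the
trial-averaged, 3.3-88 Hz band-passed potential (sink-positive convention,
so current sinks plot positive).  The earliest prominent sink within the
first 100 ms marks the granular (input) layer; units are placed at the
amplitude-weighted depth of their waveform footprint and classified as
superficial / granular / deep relative to the granular band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .datamodel import LFPBlock, SessionManifest, UnitMeta

CSD_BAND_HZ = (3.3, 88.0)


@dataclass
class CSDMap:
    depth_mm: np.ndarray           # increasing downward, 10 um steps
    t_ms: np.ndarray
    values: np.ndarray             # (n_depth, n_time), sink-positive
    contact_depth_mm: np.ndarray   # interior contact depths (pre-interpolation)
    contact_values: np.ndarray     # (n_interior, n_time)


@dataclass
class GranularBand:
    interpretable: bool
    top_mm: float = float("nan")
    bottom_mm: float = float("nan")
    center_mm: float = float("nan")
    peak_sink_latency_ms: float = float("nan")
    peak_sink_value: float = float("nan")


@dataclass
class LayerAssignment:
    unit_id: str
    depth_mm: float
    depth_rel_granular_center_mm: float
    compartment: str               # superficial | granular | deep | excluded


def bandpass_lfp(data: np.ndarray, fs_hz: float,
                 band_hz: tuple[float, float] = CSD_BAND_HZ) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass along the time axis."""
    nyq = fs_hz / 2.0
    hi = min(band_hz[1], 0.99 * nyq)
    b, a = butter(2, [band_hz[0] / nyq, hi / nyq], btype="bandpass")
    return filtfilt(b, a, data, axis=0)


def compute_csd(lfp: LFPBlock, contact_pitch_um: float = 100.0,
                band_hz: tuple[float, float] = CSD_BAND_HZ,
                interp_um: float = 10.0) -> CSDMap:
    """CSD(z, t) = -[phi(z+h) - 2 phi(z) + phi(z-h)] / h^2 on the filtered,
    trial-averaged LFP; edge contacts dropped; depth axis interpolated to
    ``interp_um`` with a cubic spline."""
    if lfp.n_contacts < 3:
        raise ValueError("CSD needs at least 3 contacts")
    phi = bandpass_lfp(lfp.data, lfp.sampling_rate_hz, band_hz)  # (t, c)
    h_mm = contact_pitch_um / 1000.0
    # contact index increases toward the surface; order columns by depth
    n = lfp.n_contacts
    depths = (n - 1 - np.arange(n)) * h_mm
    order = np.argsort(depths)
    phi_d = phi[:, order]
    depths_sorted = depths[order]
    csd = -(phi_d[:, 2:] - 2.0 * phi_d[:, 1:-1] + phi_d[:, :-2]) / h_mm**2
    interior = depths_sorted[1:-1]
    fine = np.arange(interior[0], interior[-1] + 1e-9, interp_um / 1000.0)
    spline = CubicSpline(interior, csd, axis=1)
    values = spline(fine).T  # (depth, time)
    return CSDMap(depth_mm=fine, t_ms=lfp.t_ms, values=values,
                  contact_depth_mm=interior, contact_values=csd.T)


def identify_granular(
    csd: CSDMap,
    search_window_ms: tuple[float, float] = (0.0, 100.0),
    rel_threshold: float = 0.5,
    snr_threshold: float = 5.0,
    override_mm: Optional[tuple[float, float]] = None,
) -> GranularBand:
    """Locate the granular layer as the earliest prominent current sink.

    Candidate sinks are contiguous regions of the search window exceeding
    ``rel_threshold`` of the global sink maximum; the one whose peak occurs
    earliest is the granular sink.  The band is the contiguous depth range,
    at the sink's peak time, where the sink exceeds ``rel_threshold`` of its
    peak.  The map is uninterpretable when the peak sink does not exceed
    ``snr_threshold`` times the robust pre-stimulus noise level.  A manual
    ``override_mm`` (top, bottom) short-circuits the automatic search.
    """
    if override_mm is not None:
        top, bottom = override_mm
        if not top < bottom:
            raise ValueError("override top must be < bottom")
        return GranularBand(True, top, bottom, 0.5 * (top + bottom))
    t_sel = (csd.t_ms >= search_window_ms[0]) & (csd.t_ms <= search_window_ms[1])
    win = csd.values[:, t_sel]
    t_win = csd.t_ms[t_sel]
    peak = win.max() if win.size else 0.0
    pre = csd.values[:, csd.t_ms < 0.0]
    if pre.size:
        noise = 1.4826 * np.median(np.abs(pre - np.median(pre)))
    else:
        noise = 1.4826 * np.median(np.abs(csd.values - np.median(csd.values)))
    if peak <= 0 or (noise > 0 and peak < snr_threshold * noise):
        return GranularBand(False)
    labels, n_lab = ndimage.label(win >= rel_threshold * peak)
    best = None
    for lab in range(1, n_lab + 1):
        region = np.where(labels == lab, win, -np.inf)
        zi, ti = np.unravel_index(np.argmax(region), region.shape)
        peak_t = t_win[ti]
        if best is None or peak_t < best[0]:
            best = (peak_t, zi, ti, region[zi, ti])
    peak_t, zi, ti, peak_v = best
    profile = win[:, ti]
    above = profile >= rel_threshold * peak_v
    lab_d, _ = ndimage.label(above)
    band_sel = lab_d == lab_d[zi]
    depths = csd.depth_mm[band_sel]
    return GranularBand(True, float(depths.min()), float(depths.max()),
                        float(csd.depth_mm[zi]), float(peak_t), float(peak_v))


def assign_layers(
    units: Sequence[UnitMeta],
    band: GranularBand,
    manifest: SessionManifest,
    topmost_active_contact: Optional[int] = None,
    max_depth_below_top_mm: float = 2.0,
) -> list[LayerAssignment]:
    """Amplitude-weighted unit depths and laminar compartment labels.

    Depth is the waveform-amplitude-weighted mean depth of the five contacts
    around the peak contact.  Units deeper than ``max_depth_below_top_mm``
    below the most superficial contact with activity are excluded (white
    matter guard), as are units with an all-zero footprint.
    """
    if not band.interpretable:
        raise ValueError("granular band is not interpretable; penetration excluded")
    contact_depths = manifest.contact_depths_mm
    if topmost_active_contact is None:
        topmost_active_contact = max(u.peak_contact for u in units)
    top_active_depth = contact_depths[topmost_active_contact]
    out = []
    for u in units:
        ks = np.arange(u.peak_contact - 2, u.peak_contact + 3)
        amps = np.asarray(u.contact_amplitudes, dtype=float)
        valid = (ks >= 0) & (ks < manifest.n_contacts)
        ks, amps = ks[valid], amps[valid]
        if amps.sum() <= 0:
            warnings.warn(f"unit {u.unit_id}: all-zero waveform footprint; excluded")
            out.append(LayerAssignment(u.unit_id, float("nan"), float("nan"),
                                       "excluded"))
            continue
        depth = float(np.sum(amps * contact_depths[ks]) / amps.sum())
        rel = depth - band.center_mm
        if depth > top_active_depth + max_depth_below_top_mm:
            comp = "excluded"
        elif depth < band.top_mm:
            comp = "superficial"
        elif depth <= band.bottom_mm:
            comp = "granular"
        else:
            comp = "deep"
        out.append(LayerAssignment(u.unit_id, depth, rel, comp))
    return out
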