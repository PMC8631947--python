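"""Domain types for laminar border-ownership sessions.

A *session* is one penetration of a 32-contact laminar probe in area V4:
spike times per unit per trial, trial metadata with the four border-ownership
conditions, per-unit waveform footprints used for depth assignment, and the
trial-aligned multi-contact LFP used for current-source-density analysis.

Conventions
-----------
* times in ms relative to stimulus onset; recorded epoch [-400, 1500] ms
* angles in degrees; edge orientation has period 180, ownership *sides* are
  true directions with period 360
* depth in mm, increasing downward from the most superficial contact
  (higher contact index = more superficial)
* border-ownership conditions numbered 1..4: {1, 2} share one luminance
  pairing and {3, 4} the reversed luminances; conditions 1 & 3 place the
  owning square on one side of the central edge, 2 & 4 on the other, so
  stimulus content inside the cRF is identical within {1, 2} and within
  {3, 4}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: recorded epoch relative to stimulus onset, ms
EPOCH_MS = (-400.0, 1500.0)

#: spike-count window for border-ownership rates, ms
BO_WINDOW_MS = (50.0, 500.0)

CONDITION_IDS = (1, 2, 3, 4)

#: conditions in which the square owns the "positive" side (toward
#: ``preferred side`` when BOI > 0)
SIDE_A_CONDITIONS = (1, 3)
SIDE_B_CONDITIONS = (2, 4)

#: contrast-polarity pairs: ownership label shuffles happen within each pair
POLARITY_PAIRS = ((1, 2), (3, 4))


class ValidationError(ValueError):
    """A domain-type invariant was violated; the message names the field."""


@dataclass
class RFGridSpec:
    """Reverse-correlation mapping grid: square lattice of probe positions."""

    extent_dva: float = 25.0
    spacing_dva: float = 1.0
    center_dva: tuple[float, float] = (7.5, 7.5)

    def __post_init__(self) -> None:
        if self.spacing_dva <= 0:
            raise ValidationError("rf_grid.spacing_dva must be > 0")
        if self.extent_dva <= 0:
            raise ValidationError("rf_grid.extent_dva must be > 0")

    def positions(self) -> np.ndarray:
        """All (azimuth, elevation) lattice positions, shape (n, 2)."""
        half = self.extent_dva / 2.0
        ax = np.arange(-half, half + 1e-9, self.spacing_dva) + self.center_dva[0]
        el = np.arange(-half, half + 1e-9, self.spacing_dva) + self.center_dva[1]
        aa, ee = np.meshgrid(ax, el, indexing="ij")
        return np.column_stack([aa.ravel(), ee.ravel()])


@dataclass
class StimulusGeometry:
    """Geometry of one border-ownership dataset (orientation x position).

    The central edge passes through ``edge_position`` with orientation
    ``edge_orientation_deg``; two abutting squares of side
    ``square_side_dva`` lie on either side.  ``side_a_direction_deg`` is the
    direction of the outward normal from the edge toward the square that owns
    the edge in conditions 1 & 3.
    """

    dataset_id: int
    square_side_dva: float
    edge_orientation_deg: float
    edge_position_dva: tuple[float, float]
    side_a_direction_deg: float
    luminances: tuple[float, float] = (0.23, 0.77)

    def __post_init__(self) -> None:
        if self.square_side_dva <= 0:
            raise ValidationError("square_side_dva must be > 0")
        self.edge_orientation_deg = float(self.edge_orientation_deg) % 180.0
        self.side_a_direction_deg = float(self.side_a_direction_deg) % 360.0

    @property
    def side_b_direction_deg(self) -> float:
        return (self.side_a_direction_deg + 180.0) % 360.0

    def owning_side_direction(self, condition_id: int) -> float:
        """Direction (deg) from the central edge toward the owning square."""
        if condition_id in SIDE_A_CONDITIONS:
            return self.side_a_direction_deg
        if condition_id in SIDE_B_CONDITIONS:
            return self.side_b_direction_deg
        raise ValidationError(f"condition_id must be in 1..4, got {condition_id}")

    def square_polygon(self, side: str) -> np.ndarray:
        """Vertices (4, 2) of the square on side ``'a'`` or ``'b'``."""
        theta = np.deg2rad(self.edge_orientation_deg)
        u = np.array([np.cos(theta), np.sin(theta)])  # along the edge
        direction = self.side_a_direction_deg if side == "a" else self.side_b_direction_deg
        phi = np.deg2rad(direction)
        n = np.array([np.cos(phi), np.sin(phi)])  # toward the square
        p = np.asarray(self.edge_position_dva, dtype=float)
        s = self.square_side_dva
        c0 = p - u * s / 2.0
        c1 = p + u * s / 2.0
        return np.array([c0, c1, c1 + n * s, c0 + n * s])

    def central_edge_segment(self) -> np.ndarray:
        """End points (2, 2) of the central edge."""
        theta = np.deg2rad(self.edge_orientation_deg)
        u = np.array([np.cos(theta), np.sin(theta)])
        p = np.asarray(self.edge_position_dva, dtype=float)
        return np.array([p - u * self.square_side_dva / 2.0,
                         p + u * self.square_side_dva / 2.0])


@dataclass
class SessionManifest:
    penetration_id: str
    animal_id: str = "synthetic"
    n_contacts: int = 32
    contact_pitch_um: float = 100.0
    datasets: list[StimulusGeometry] = field(default_factory=list)
    rf_grid: RFGridSpec = field(default_factory=RFGridSpec)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_contacts < 2:
            raise ValidationError("n_contacts must be >= 2")
        if self.contact_pitch_um <= 0:
            raise ValidationError("contact_pitch_um must be > 0")

    @property
    def contact_depths_mm(self) -> np.ndarray:
        """Depth of each contact, mm below the most superficial contact.

        Contact index increases toward the surface, so depth decreases with
        index.
        """
        pitch_mm = self.contact_pitch_um / 1000.0
        return (self.n_contacts - 1 - np.arange(self.n_contacts)) * pitch_mm


@dataclass
class UnitMeta:
    """Waveform footprint of one sorted unit.

    ``contact_amplitudes`` holds the mean peak-to-trough amplitude (uV) on
    the five contacts centered on ``peak_contact`` (edge contacts padded
    with 0).
    """

    unit_id: str
    isolation: str  # 'single' | 'multi'
    peak_contact: int
    contact_amplitudes: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.isolation not in ("single", "multi"):
            raise ValidationError(f"isolation must be 'single'|'multi', got {self.isolation!r}")
        amps = tuple(float(a) for a in self.contact_amplitudes)
        if len(amps) != 5:
            raise ValidationError("contact_amplitudes must have exactly 5 entries")
        if any(a < 0 for a in amps):
            raise ValidationError("contact_amplitudes must be >= 0")
        self.contact_amplitudes = amps


@dataclass
class LFPBlock:
    """Trial-averaged, trial-aligned multi-contact LFP (ring stimulus onset at t=0)."""

    sampling_rate_hz: float
    t_ms: np.ndarray          # (n_time,)
    data: np.ndarray          # (n_time, n_contacts), mV
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be > 0")
        if self.data.ndim != 2:
            raise ValidationError("LFP data must be 2D (time x contact)")
        if self.data.shape[0] != self.t_ms.shape[0]:
            raise ValidationError("LFP data rows must match t_ms length")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")

    @property
    def n_contacts(self) -> int:
        return self.data.shape[1]


def make_spike_table(unit_ids: Sequence[str], trial_ids: Sequence[int],
                     t_ms: Sequence[float]) -> pd.DataFrame:
    """Assemble a spike table: one row per spike."""
    df = pd.DataFrame({
        "unit_id": pd.array(unit_ids, dtype="str"),
        "trial_id": np.asarray(trial_ids, dtype=np.int64),
        "t_ms": np.asarray(t_ms, dtype=float),
    })
    validate_spike_table(df)
    return df


def validate_spike_table(spikes: pd.DataFrame) -> None:
    for col in ("unit_id", "trial_id", "t_ms"):
        if col not in spikes.columns:
            raise ValidationError(f"spike table missing column {col!r}")
    t = spikes["t_ms"].to_numpy()
    if len(t) and not np.all(np.isfinite(t)):
        raise ValidationError("spike table t_ms contains non-finite values")
    if len(t) and (t.min() < EPOCH_MS[0] or t.max() > EPOCH_MS[1]):
        raise ValidationError(
            f"spike table t_ms outside recorded epoch {EPOCH_MS}")


def make_trial_table(records: Sequence[dict]) -> pd.DataFrame:
    """Trial table from dicts with trial_id/condition_id/dataset_id/... keys."""
    df = pd.DataFrame.from_records(records)
    validate_trial_table(df)
    return df


def validate_trial_table(trials: pd.DataFrame) -> None:
    required = ("trial_id", "condition_id", "dataset_id",
                "edge_orientation_deg", "onset_time_ms")
    for col in required:
        if col not in trials.columns:
            raise ValidationError(f"trial table missing column {col!r}")
    cond = trials["condition_id"].to_numpy()
    if len(cond) and not np.isin(cond, CONDITION_IDS).all():
        bad = sorted(set(cond) - set(CONDITION_IDS))
        raise ValidationError(f"condition_id outside 1..4: {bad}")
    if trials["trial_id"].duplicated().any():
        dupes = trials.loc[trials["trial_id"].duplicated(), "trial_id"].tolist()
        raise ValidationError(f"duplicate trial_id values: {dupes[:5]}")


@dataclass
class Session:
    """One penetration's worth of data, cross-validated on construction."""

    manifest: SessionManifest
    spikes: pd.DataFrame
    trials: pd.DataFrame
    units: list[UnitMeta]
    lfp: Optional[LFPBlock] = None

    def __post_init__(self) -> None:
        validate_spike_table(self.spikes)
        validate_trial_table(self.trials)
        known_trials = set(self.trials["trial_id"])
        spike_trials = set(self.spikes["trial_id"].unique())
        dangling = sorted(spike_trials - known_trials)
        if dangling:
            raise ValidationError(
                f"spike table references unknown trial_id values: {dangling[:10]}")
        known_units = {u.unit_id for u in self.units}
        dangling_units = sorted(set(self.spikes["unit_id"].unique()) - known_units)
        if dangling_units:
            raise ValidationError(
                f"spike table references unknown unit_id values: {dangling_units[:10]}")
        if self.lfp is not None and self.lfp.n_contacts != self.manifest.n_contacts:
            raise ValidationError(
                "LFP contact count does not match manifest.n_contacts")
        known_ds = {g.dataset_id for g in self.manifest.datasets}
        bad_ds = sorted(set(self.trials["dataset_id"]) - known_ds - {-1})
        if bad_ds:
            raise ValidationError(
                f"trial table references unknown dataset_id values: {bad_ds[:10]}")

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def spikes_for_unit(self, unit_id: str) -> pd.DataFrame:
        return self.spikes[self.spikes["unit_id"] == unit_id]

    def geometry(self, dataset_id: int) -> StimulusGeometry:
        for g in self.manifest.datasets:
            if g.dataset_id == dataset_id:
                return g
        raise KeyError(f"no dataset with id {dataset_id}")


def manifest_to_dict(manifest: SessionManifest) -> dict:
    d = asdict(manifest)
    d["schema_version"] = 1
    return d


def manifest_from_dict(d: dict) -> SessionManifest:
    d = dict(d)
    d.pop("schema_version", None)
    d["rf_grid"] = RFGridSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in d.get("rf_grid", {}).items()})
    d["datasets"] = [
        StimulusGeometry(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in g.items()})
        for g in d.get("datasets", [])
    ]
    return SessionManifest(**d)
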