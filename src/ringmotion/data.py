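"""Core data containers and CSV/YAML input-output.

The experimental unit is a *trial*: a fixed group of individuals filmed on an
annular arena for a fixed duration at a constant frame rate.  Tracking output
is reduced to angular position on the arena midline; radial position carries
no information for the purely angular interaction models considered here.

Two tabular formats are used, both plain CSV with a header:

* trajectory CSV: ``trial_id, time_s, prawn_id, theta_rad`` — one row per
  individual per frame, angles in radians, wrapped into [0, 2*pi);
* orientation CSV: ``trial_id, time_s, prawn_id, state, event`` — the binary
  CW/ACW classification with direction-change indicators (``event`` is blank
  on the final frame of each trial, because events are defined between
  consecutive frames).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from ._angles import wrap_angle
from .errors import FormatError

#: Orientation encoding used throughout: increasing angle is anti-clockwise.
ACW = 1
CW = -1

_STATE_TO_STR = {ACW: "ACW", CW: "CW"}
_STR_TO_STATE = {"ACW": ACW, "CW": CW}

_TIME_TOL_S = 1e-6


@dataclass(frozen=True)
class ArenaSpec:
    """Annular arena geometry (millimetres).

    Defaults match a 200 mm outer / 70 mm inner annulus; positions are angles
    on the midline circle of radius ``(outer + inner) / 4``.
    """

    outer_diameter_mm: float = 200.0
    inner_diameter_mm: float = 70.0

    def __post_init__(self) -> None:
        if not (self.outer_diameter_mm > self.inner_diameter_mm > 0):
            raise ValueError("arena requires outer > inner > 0")

    @property
    def midline_radius_mm(self) -> float:
        return (self.outer_diameter_mm + self.inner_diameter_mm) / 4.0


@dataclass
class TrialTrajectory:
    """Angular positions of one trial: a (T, N) matrix over uniformly spaced frames."""

    trial_id: str
    frame_rate_hz: float
    times_s: np.ndarray
    theta_rad: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.theta_rad = np.asarray(self.theta_rad, dtype=float)
        if self.theta_rad.ndim != 2 or self.times_s.ndim != 1:
            raise ValueError("theta_rad must be (T, N), times_s must be (T,)")
        if self.theta_rad.shape[0] != self.times_s.shape[0]:
            raise ValueError("times and angles disagree on frame count")
        if np.any(~np.isfinite(self.theta_rad)) or np.any(~np.isfinite(self.times_s)):
            raise FormatError(f"trial {self.trial_id}: non-finite values")
        if len(self.times_s) >= 2:
            dt = np.diff(self.times_s)
            if np.any(np.abs(dt - 1.0 / self.frame_rate_hz) > _TIME_TOL_S):
                raise FormatError(
                    f"trial {self.trial_id}: non-uniform frame spacing "
                    f"(expected {1.0 / self.frame_rate_hz:.6f} s)")
        if np.any(self.theta_rad < 0) or np.any(self.theta_rad >= 2 * np.pi):
            raise ValueError(f"trial {self.trial_id}: angles outside [0, 2*pi)")

    @property
    def n_frames(self) -> int:
        return self.theta_rad.shape[0]

    @property
    def n_prawns(self) -> int:
        return self.theta_rad.shape[1]

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass
class OrientationRecord:
    """Binary CW/ACW state sequence per individual, plus change events.

    ``state`` is a (T, N) matrix with values +1 (ACW) / -1 (CW); ``events`` is
    the (T-1, N) finite difference indicator: entry (t, i) is 1 iff individual
    i's state differs between frames t and t+1.
    """

    trial_id: str
    dt_s: float
    state: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        self.events = np.asarray(self.events, dtype=np.uint8)
        if self.state.ndim != 2:
            raise ValueError("state must be (T, N)")
        if not np.all(np.isin(self.state, (ACW, CW))):
            raise FormatError(f"trial {self.trial_id}: state values must be +-1 (ACW/CW)")
        expected = (np.diff(self.state, axis=0) != 0).astype(np.uint8)
        if self.events.shape != expected.shape or np.any(self.events != expected):
            raise ValueError("events must equal the finite difference of state")

    @classmethod
    def from_states(cls, trial_id: str, dt_s: float, state: np.ndarray) -> "OrientationRecord":
        state = np.asarray(state, dtype=np.int8)
        events = (np.diff(state, axis=0) != 0).astype(np.uint8)
        return cls(trial_id, dt_s, state, events)

    @property
    def n_frames(self) -> int:
        return self.state.shape[0]

    @property
    def n_prawns(self) -> int:
        return self.state.shape[1]

    def clockwise_counts(self) -> np.ndarray:
        """Number of CW-oriented individuals at each frame, shape (T,)."""
        return np.sum(self.state == CW, axis=1)


# ---------------------------------------------------------------------------
# trajectory CSV

_TRAJ_COLUMNS = ["trial_id", "time_s", "prawn_id", "theta_rad"]


def read_trajectories(path, arena: ArenaSpec | None = None) -> list[TrialTrajectory]:
    """Read a trajectory CSV into one :class:`TrialTrajectory` per trial.

    Angles are wrapped into [0, 2*pi); individual ids are mapped to dense
    0-based columns in ascending id order.  Raises :class:`FormatError` for a
    missing column, a missing (time, individual) cell, or non-uniform frame
    spacing beyond 1e-6 s.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory file missing columns: {missing}")
    out = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        wide = g.pivot_table(index="time_s", columns="prawn_id", values="theta_rad",
                             aggfunc="first", dropna=False)
        wide = wide.sort_index()
        if wide.isna().any().any():
            t_bad = wide.index[wide.isna().any(axis=1)][0]
            raise FormatError(
                f"trial {trial_id}: missing (time, prawn) cell at time {t_bad}")
        times = wide.index.to_numpy(dtype=float)
        if len(times) < 2:
            raise FormatError(f"trial {trial_id}: needs at least two frames")
        spacing = np.diff(times)
        if np.any(np.abs(spacing - spacing[0]) > _TIME_TOL_S):
            raise FormatError(f"trial {trial_id}: non-uniform time spacing")
        rate = 1.0 / spacing.mean()
        theta = wrap_angle(wide.to_numpy(dtype=float))
        out.append(TrialTrajectory(str(trial_id), rate, times, theta))
    return out


def write_trajectories(trajs: Iterable[TrialTrajectory], path) -> None:
    frames = []
    for tr in trajs:
        t_rep = np.repeat(tr.times_s, tr.n_prawns)
        pid = np.tile(np.arange(tr.n_prawns), tr.n_frames)
        frames.append(pd.DataFrame({
            "trial_id": tr.trial_id,
            "time_s": t_rep,
            "prawn_id": pid,
            "theta_rad": tr.theta_rad.ravel(),
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_TRAJ_COLUMNS))
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def downsample(traj: TrialTrajectory, factor: int) -> TrialTrajectory:
    """Keep frames 0, factor, 2*factor, ... and divide the frame rate.

    ``factor=2`` converts a 15 Hz recording to 7.5 Hz by removing every second
    frame.  ``factor=1`` returns an identical copy.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("downsample factor must be an integer >= 1")
    if traj.n_frames <= factor:
        raise ValueError("trajectory too short for requested downsampling")
    return TrialTrajectory(
        trial_id=traj.trial_id,
        frame_rate_hz=traj.frame_rate_hz / factor,
        times_s=traj.times_s[::factor],
        theta_rad=traj.theta_rad[::factor],
    )


# ---------------------------------------------------------------------------
# orientation CSV

_ORIENT_COLUMNS = ["trial_id", "time_s", "prawn_id", "state", "event"]


def write_orientations(records: Iterable[OrientationRecord], path) -> None:
    """Write orientation records; round-trips bit-exactly through
    :func:`read_orientations`."""
    frames = []
    for rec in records:
        T, N = rec.state.shape
        times = np.arange(T) * rec.dt_s
        ev = np.vstack([rec.events.astype(object), np.full((1, N), "", dtype=object)])
        frames.append(pd.DataFrame({
            "trial_id": rec.trial_id,
            "time_s": np.repeat(times, N),
            "prawn_id": np.tile(np.arange(N), T),
            "state": [_STATE_TO_STR[s] for s in rec.state.ravel()],
            "event": ev.ravel(),
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_ORIENT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")


def read_orientations(path) -> list[OrientationRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _ORIENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"orientation file missing columns: {missing}")
    out = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        bad = set(g["state"].unique()) - set(_STR_TO_STATE)
        if bad:
            raise FormatError(f"trial {trial_id}: unknown state values {sorted(bad)}")
        coded = g.assign(code=g["state"].map(_STR_TO_STATE))
        wide = coded.pivot_table(index="time_s", columns="prawn_id", values="code",
                                 aggfunc="first", dropna=False).sort_index()
        if wide.isna().any().any():
            raise FormatError(f"trial {trial_id}: missing cells in orientation file")
        times = wide.index.to_numpy(dtype=float)
        dt = times[1] - times[0] if len(times) >= 2 else 1.0
        out.append(OrientationRecord.from_states(
            str(trial_id), dt, wide.to_numpy(dtype=np.int8)))
    return out


# ---------------------------------------------------------------------------
# run configuration

_ALL_MODELS = ("Null", "MF", "T", "S1", "S2", "S3", "S4", "D1", "D2", "D3", "D4")


@dataclass
class RunConfig:
    """Configuration for a full analysis run.

    The reproducibility contract is: identical configuration (including
    ``seed``) produces bit-identical outputs at every stage.
    """

    seed: int = 0
    frame_rate_hz: float = 7.5
    trial_length_s: float = 360.0
    group_sizes: tuple = (1, 3, 6, 12)
    n_trials_per_size: int = 25
    fit_group_size: int = 6
    models: tuple = _ALL_MODELS
    # evidence estimation
    ais_samples: int = 1000
    ais_temperatures: int = 100
    # prior bounds shared across models
    w_max: float = 5.0
    r_max: float = 0.5
    # synthetic-data generator
    obs_mu_rad_per_frame: float = 0.1
    obs_sigma_rad_per_frame: float = 0.05
    generator_model: str = "D3"
    generator_params: dict = field(default_factory=dict)
    memory_dialect: str = "trace"
    # large-scale validation protocol
    validate_sets: int = 10
    validate_set_size: int = 100

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(n) for n in self.group_sizes)
        self.models = tuple(self.models)
        for name in ("n_trials_per_size", "ais_samples", "ais_temperatures",
                     "validate_sets", "validate_set_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.frame_rate_hz <= 0 or self.trial_length_s <= 0:
            raise ValueError("frame rate and trial length must be positive")
        unknown = set(self.models) - set(_ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown model ids: {sorted(unknown)}")
        if self.memory_dialect not in ("trace", "aggregate"):
            raise ValueError("memory_dialect must be 'trace' or 'aggregate'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)
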