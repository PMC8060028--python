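"""Swim-trajectory kinematics.

Nociception in larval zebrafish is scored behaviourally: a noxious
chemical (formalin or mustard oil) triggers an escape response that shows
up as increased swimming velocity.  This module computes binned swimming
velocity (path length per second, mm/s) and angular velocity (absolute
turn angle per second, deg/s) from tracked 2-D positions, plus the
summary endpoint — the mean over a fixed window, by convention the first
three minutes after treatment.

Velocity is path-length based (not net displacement).  Headings are taken
from successive displacement vectors longer than ``displacement_epsilon``
so that tracking jitter of a stationary fish does not register as
spurious turning; bins without at least two valid headings have undefined
angular velocity and are excluded from summaries rather than zero-filled
(zero-filling would bias group medians toward 0 for sedated fish).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "KinematicsSeries",
    "ResponseSummary",
    "velocity_series",
    "angular_velocity_series",
    "response_summary",
]


@dataclass
class Trajectory:
    """Uniformly sampled 2-D positions of one larva, well-center origin (mm)."""

    times: np.ndarray  # s, strictly increasing, uniform
    xy: np.ndarray  # (n, 2) mm

    #: relative tolerance on sampling-interval uniformity
    _UNIFORM_RTOL = 1e-3

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.xy.shape != (self.times.size, 2):
            raise ValueError("xy must be (n, 2) matching times")
        if not np.all(np.isfinite(self.xy)) or not np.all(np.isfinite(self.times)):
            raise ValueError("non-finite trajectory data")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        dt = np.median(dts)
        if np.any(np.abs(dts - dt) > self._UNIFORM_RTOL * dt):
            raise ValueError("sampling is non-uniform beyond tolerance")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.times, "x_mm": self.xy[:, 0], "y_mm": self.xy[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df[["x_mm", "y_mm"]].to_numpy())


@dataclass
class KinematicsSeries:
    """Binned kinematics; undefined angular-velocity bins are NaN."""

    bin_starts: np.ndarray  # s
    bin_width: float  # s
    velocity: np.ndarray | None = None  # mm/s
    angular_velocity: np.ndarray | None = None  # deg/s, NaN where undefined

    def to_frame(self, fish_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"bin_start_s": self.bin_starts})
        df["velocity_mm_s"] = (
            self.velocity if self.velocity is not None else np.nan
        )
        df["angular_velocity_deg_s"] = (
            self.angular_velocity if self.angular_velocity is not None else np.nan
        )
        if fish_id is not None:
            df.insert(0, "fish_id", fish_id)
        return df


@dataclass
class ResponseSummary:
    """Mean of defined bins over a window, with the contributing-bin count."""

    mean: float
    n_bins: int


def _bin_layout(traj: Trajectory, bin_s: float) -> tuple[np.ndarray, int]:
    if bin_s < 2 * traj.dt:
        raise ValueError("bin must span at least 2 sampling intervals")
    n_bins = int(np.floor(traj.duration / bin_s))
    if n_bins < 1:
        raise ValueError("trajectory shorter than one bin")
    starts = traj.times[0] + bin_s * np.arange(n_bins)
    return starts, n_bins


def velocity_series(traj: Trajectory, bin_s: float = 1.0) -> KinematicsSeries:
    """Swimming velocity per bin: summed Euclidean step length / bin width.

    Each step is assigned to the bin containing its start sample; the
    trailing partial bin is dropped.  Summing ``v * bin_s`` over bins
    therefore recovers the path length of the covered samples exactly.
    """
    starts, n_bins = _bin_layout(traj, bin_s)
    steps = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1)
    step_bin = np.floor((traj.times[:-1] - traj.times[0]) / bin_s).astype(int)
    keep = step_bin < n_bins
    path = np.bincount(step_bin[keep], weights=steps[keep], minlength=n_bins)
    return KinematicsSeries(starts, bin_s, velocity=path / bin_s)


def angular_velocity_series(
    traj: Trajectory, bin_s: float = 1.0, displacement_epsilon: float = 0.05
) -> KinematicsSeries:
    """Absolute turning per bin, deg/s.

    Headings come from displacement vectors with length >=
    ``displacement_epsilon`` (mm); each turn between consecutive valid
    headings is wrapped to (-180, 180], its absolute value summed into
    the bin of the later displacement's start sample.  Bins holding fewer
    than two valid headings are NaN.
    """
    starts, n_bins = _bin_layout(traj, bin_s)
    disp = np.diff(traj.xy, axis=0)
    lengths = np.linalg.norm(disp, axis=1)
    valid = lengths >= displacement_epsilon
    idx = np.flatnonzero(valid)
    omega = np.full(n_bins, np.nan)
    head_counts = np.zeros(n_bins, dtype=int)
    step_bin = np.floor((traj.times[:-1] - traj.times[0]) / bin_s).astype(int)
    for i in idx:
        if step_bin[i] < n_bins:
            head_counts[step_bin[i]] += 1
    if idx.size >= 2:
        headings = np.degrees(np.arctan2(disp[idx, 1], disp[idx, 0]))
        turns = np.diff(headings)
        # wrap to (-180, 180]
        turns = -((-turns + 180.0) % 360.0 - 180.0)
        turn_bin = step_bin[idx[1:]]
        keep = turn_bin < n_bins
        total = np.bincount(
            turn_bin[keep], weights=np.abs(turns[keep]), minlength=n_bins
        )
        defined = head_counts >= 2
        omega[defined] = total[defined] / bin_s
    return KinematicsSeries(starts, bin_s, angular_velocity=omega)


def response_summary(
    series: KinematicsSeries, start: float, end: float, which: str = "velocity"
) -> ResponseSummary:
    """Mean of the defined bins whose start lies in [start, end).

    This is the assay endpoint: e.g. mean swimming velocity over minutes
    0-3 after treatment.
    """
    if end <= start:
        raise ValueError("end must exceed start")
    if which in ("velocity", "v"):
        values = series.velocity
    elif which in ("angular", "angular_velocity", "omega"):
        values = series.angular_velocity
    else:
        raise ValueError(f"unknown kinematic quantity {which!r}")
    if values is None:
        raise ValueError(f"series has no {which!r} values")
    in_win = (series.bin_starts >= start) & (series.bin_starts < end)
    vals = np.asarray(values)[in_win]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined bins in the requested window")
    return ResponseSummary(mean=float(vals.mean()), n_bins=int(vals.size))
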