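"""Mandible-motion signal extraction.

Larval zebrafish drive water over their gills with rhythmic mandible
movements; their per-minute count is the respiratory-rate proxy used
throughout this package.  This module turns a stack of grayscale well
frames (or a precomputed motion-intensity trace) into detected mandible
peaks, per-minute respiratory rates, and baseline-normalized rate series.

The motion statistic is the mean absolute per-pixel frame difference over
a user-supplied region of interest around the fish head.  Peaks are
prominence-thresholded local maxima of a moving-average-smoothed trace,
with a refractory period that bounds the maximum detectable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ROI",
    "FrameStack",
    "IntensityTrace",
    "PeakSet",
    "RateSeries",
    "AgreementSummary",
    "NormalizationError",
    "motion_signal",
    "detect_mandible_peaks",
    "rate_series",
    "normalize_to_baseline",
    "extraction_agreement",
]

#: Fixed respiratory-rate window length (s): rates are movements per minute.
RATE_WINDOW_S = 60.0


class NormalizationError(ValueError):
    """Raised when a rate series cannot be expressed as % of baseline."""


@dataclass(frozen=True)
class ROI:
    """Axis-aligned pixel rectangle, 0-based, half-open [x0,x1) x [y0,y1)."""

    x0: int
    x1: int
    y0: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"empty ROI: {self}")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"ROI has negative origin: {self}")

    def check_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x1 > w or self.y1 > h:
            raise ValueError(f"ROI {self} outside frame bounds {shape}")

    @property
    def slices(self) -> tuple[slice, slice]:
        # row-major: (y, x)
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass
class FrameStack:
    """Time-ordered grayscale frames of one well.

    Pixel (0, 0) is top-left; frames are row-major (y, x).
    """

    frames: np.ndarray  # (t, h, w)
    frame_rate: float  # Hz
    mm_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, h, w) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames)

    @classmethod
    def from_tiff(cls, path, frame_rate: float, mm_per_pixel: float = 1.0) -> "FrameStack":
        import tifffile

        return cls(tifffile.imread(path), frame_rate, mm_per_pixel)


@dataclass
class IntensityTrace:
    """Motion-signal time series (mean |frame difference| over the ROI)."""

    times: np.ndarray  # s
    values: np.ndarray  # intensity units, >= 0
    sample_rate: float  # Hz

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "intensity": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "IntensityTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        sr = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(t, df["intensity"].to_numpy(), sr)


@dataclass
class PeakSet:
    """Detected mandible-movement peaks."""

    times: np.ndarray  # s, strictly increasing
    heights: np.ndarray  # intensity units

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RateSeries:
    """Per-minute respiratory rates, raw and (optionally) % of baseline."""

    window_starts: np.ndarray  # s
    rate: np.ndarray  # movements/min
    normalized: np.ndarray | None = None  # % of baseline
    baseline_rate: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.window_starts.shape != self.rate.shape:
            raise ValueError("window_starts and rate must have equal length")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")

    def to_frame(self, fish_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "window_start_s": self.window_starts,
                "rate_per_min": self.rate,
                "normalized_pct": self.normalized
                if self.normalized is not None
                else np.nan,
            }
        )
        if fish_id is not None:
            df.insert(0, "fish_id", fish_id)
        return df


@dataclass
class AgreementSummary:
    """Agreement between two rate series (e.g. automatic vs manual counts)."""

    abs_diff: np.ndarray  # per-window |auto - manual|
    mean_diff: float  # mean(auto - manual), signed
    mean_abs_diff: float
    concordance: float  # Lin's concordance correlation coefficient


def motion_signal(stack: FrameStack, roi: ROI) -> IntensityTrace:
    """Mean absolute per-pixel intensity change within the ROI.

    Value at frame t (t >= 1) is ``mean_{ROI} |I_t - I_{t-1}|``; the trace
    has one fewer sample than the stack and timestamps at the later frame.
    Invariant to adding any constant to every frame.
    """
    roi.check_within(stack.shape)
    ys, xs = roi.slices
    patch = stack.frames[:, ys, xs].astype(np.float64)
    diffs = np.abs(np.diff(patch, axis=0)).mean(axis=(1, 2))
    times = stack.times[1:]
    return IntensityTrace(times, diffs, stack.frame_rate)


def detect_mandible_peaks(
    trace: IntensityTrace,
    min_prominence: float = 0.3,
    refractory: float = 0.3,
    smooth_window: float = 0.15,
) -> PeakSet:
    """Detect mandible-movement peaks in a motion-intensity trace.

    The trace is smoothed with a centered moving average of width
    ``smooth_window`` seconds, then local maxima with topographic
    prominence >= ``min_prominence`` are kept, no two closer than the
    ``refractory`` period (default 0.3 s caps the detectable rate at
    200/min, above the 160/min inclusion ceiling).  Plateau ties resolve
    to the leftmost sample.

    Parameters
    ----------
    min_prominence : intensity units; raise to reject noise ripples.
    refractory : s; minimum allowed peak spacing, must be > 0.
    smooth_window : s; moving-average width (0 disables smoothing).
    """
    if trace.values.size == 0:
        raise ValueError("empty trace")
    if not np.all(np.isfinite(trace.values)):
        raise ValueError("trace contains non-finite values")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    sr = trace.sample_rate
    w = max(1, int(round(smooth_window * sr)))
    if w % 2 == 0:
        w += 1
    if w > 1:
        # edge-padded moving average: a constant trace stays exactly constant
        padded = np.pad(trace.values, w // 2, mode="edge")
        smoothed = np.convolve(padded, np.ones(w) / w, mode="valid")
    else:
        smoothed = trace.values
    distance = max(1, int(np.ceil(refractory * sr)))
    _, props = find_peaks(
        smoothed,
        prominence=min_prominence,
        distance=distance,
        plateau_size=(1, None),
    )
    idx = props["left_edges"]
    return PeakSet(trace.times[idx], trace.values[idx])


def rate_series(peaks: PeakSet, t0: float, total_duration: float) -> RateSeries:
    """Count peaks in consecutive non-overlapping 60 s windows from ``t0``.

    The trailing partial window is dropped.  Rates are movements/min since
    the window length is fixed at one minute.
    """
    if t0 < 0:
        raise ValueError("t0 must be non-negative")
    if total_duration < RATE_WINDOW_S:
        raise ValueError("total_duration must cover at least one 60 s window")
    n_win = int(np.floor(total_duration / RATE_WINDOW_S))
    starts = t0 + RATE_WINDOW_S * np.arange(n_win)
    edges = np.append(starts, starts[-1] + RATE_WINDOW_S)
    counts, _ = np.histogram(peaks.times, bins=edges)
    return RateSeries(starts, counts.astype(float))


def normalize_to_baseline(series: RateSeries, baseline_rate: float) -> RateSeries:
    """Express rates as a percentage of the fish's own pre-drug baseline.

    Raises :class:`NormalizationError` for non-positive baselines; such
    fish should instead be excluded by the quality-control rules.
    """
    if baseline_rate <= 0:
        raise NormalizationError(
            f"cannot normalize by baseline rate {baseline_rate!r}; "
            "fish must fail inclusion instead"
        )
    return replace(
        series,
        normalized=100.0 * series.rate / baseline_rate,
        baseline_rate=float(baseline_rate),
    )


def extraction_agreement(auto: RateSeries, manual: RateSeries) -> AgreementSummary:
    """Compare automatic against manual (visual) per-window rate counts."""
    if auto.window_starts.shape != manual.window_starts.shape or not np.allclose(
        auto.window_starts, manual.window_starts
    ):
        raise ValueError("rate series cover different windows")
    d = auto.rate - manual.rate
    ccc = _lin_ccc(auto.rate, manual.rate)
    return AgreementSummary(
        abs_diff=np.abs(d),
        mean_diff=float(d.mean()),
        mean_abs_diff=float(np.abs(d).mean()),
        concordance=ccc,
    )


def _lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (1 for identical series)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        return float("nan")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))
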