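"""Inclusion criteria and outlier removal, with a full exclusion audit.

Larvae at 12-14 dpf vary widely in development; the assays therefore
apply baseline inclusion bands — respiratory rate within 60-160
movements/min and swimming velocity within 0.1-2 mm/s — before any drug
comparison.  The bands are inclusive at both edges: what is excluded is
strictly *below* or *above* the printed thresholds.  Group endpoints are
additionally fenced with Tukey's rule (outlier iff outside
quartile +/- k*IQR, k = 1.5), applied once per group on the analysis
endpoint, after normalization, with quartiles by linear interpolation of
order statistics (fence membership can flip under other quartile
conventions, so the convention is part of the contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "QCReport",
    "respiratory_inclusion",
    "swim_inclusion",
    "iqr_outlier_mask",
]

REASONS = ("pass", "rate_low", "rate_high", "speed_low", "speed_high", "outlier")


@dataclass(frozen=True)
class QCConfig:
    """Inclusion bounds and fence multiplier."""

    resp_rate_low: float = 60.0  # movements/min
    resp_rate_high: float = 160.0
    swim_speed_low: float = 0.1  # mm/s
    swim_speed_high: float = 2.0
    iqr_k: float = 1.5

    def __post_init__(self) -> None:
        if not (self.resp_rate_low < self.resp_rate_high):
            raise ValueError("respiratory bounds must satisfy low < high")
        if not (self.swim_speed_low < self.swim_speed_high):
            raise ValueError("swim bounds must satisfy low < high")
        if self.iqr_k <= 0:
            raise ValueError("iqr_k must be positive")


def respiratory_inclusion(
    baseline_rate: float, cfg: QCConfig = QCConfig()
) -> tuple[bool, str]:
    """Keep iff low <= baseline rate <= high (bounds inclusive)."""
    if baseline_rate < 0:
        raise ValueError("baseline rate must be non-negative")
    if baseline_rate < cfg.resp_rate_low:
        return False, "rate_low"
    if baseline_rate > cfg.resp_rate_high:
        return False, "rate_high"
    return True, "pass"


def swim_inclusion(
    baseline_speed: float, cfg: QCConfig = QCConfig()
) -> tuple[bool, str]:
    """Keep iff low <= baseline swimming velocity <= high (inclusive)."""
    if baseline_speed < 0:
        raise ValueError("baseline speed must be non-negative")
    if baseline_speed < cfg.swim_speed_low:
        return False, "speed_low"
    if baseline_speed > cfg.swim_speed_high:
        return False, "speed_high"
    return True, "pass"


def iqr_outlier_mask(values, k: float = 1.5) -> np.ndarray:
    """Tukey-fence outliers: value < Q1 - k*IQR or value > Q3 + k*IQR.

    Quartiles are linearly interpolated order statistics.  Requires at
    least 4 values (quartiles are unstable below that); returns a boolean
    mask aligned with the input, invariant to input order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 4:
        raise ValueError("need at least 4 values to place Tukey fences")
    if k <= 0:
        raise ValueError("k must be positive")
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


@dataclass
class QCReport:
    """Per-fish inclusion audit plus group-level accounting.

    ``table`` has one row per fish: fish_id, group, endpoint, included,
    reason.  Every exclusion carries exactly one primary reason, and
    included + excluded = total within every group.
    """

    table: pd.DataFrame
    group_counts: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        required = {"fish_id", "group", "endpoint", "included", "reason"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"QC table missing columns: {sorted(missing)}")
        bad = set(self.table["reason"]) - set(REASONS)
        if bad:
            raise ValueError(f"unknown QC reasons: {sorted(bad)}")
        if not (
            (self.table["reason"] == "pass") == self.table["included"]
        ).all():
            raise ValueError("included flag inconsistent with reason code")
        g = self.table.groupby("group", sort=False)
        self.group_counts = pd.DataFrame(
            {
                "n_total": g.size(),
                "n_included": g["included"].sum().astype(int),
            }
        ).reset_index()
        self.group_counts["n_excluded"] = (
            self.group_counts["n_total"] - self.group_counts["n_included"]
        )

    @property
    def n_included(self) -> int:
        return int(self.table["included"].sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.table["included"]).sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n_total": int(len(self.table)),
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "groups": self.group_counts.to_dict(orient="records"),
        }
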