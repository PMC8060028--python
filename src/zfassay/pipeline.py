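"""End-to-end assay orchestration: input -> extraction -> QC -> statistics.

Two assays are wired up:

* **Respiratory**: each fish contributes a 1-min pre-drug baseline
  mandible rate and a per-minute rate series after application; the
  endpoint is the baseline-normalized rate in the analysis window
  (default minutes 5-6 after application, where depression peaks).
* **Nociception**: each fish contributes a baseline swimming velocity
  and binned post-treatment kinematics; the endpoint is the mean
  swimming velocity over the first 3 minutes after treatment.

Both then apply the inclusion criteria, Tukey-fence the endpoint once
per group, and run the branch-selecting group comparison.  Groups follow
a separate-wells design — each animal receives exactly one drug
combination (sequential dosing in the same well proved inconsistent).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import angular_velocity_series, response_summary, velocity_series
from .qc import QCConfig, QCReport, iqr_outlier_mask, respiratory_inclusion, swim_inclusion
from .signals import detect_mandible_peaks, normalize_to_baseline, rate_series
from .stats import GroupComparison, StatConfig, compare_groups
from .synthetic import AssayDataset, CohortDesign, simulate_cohort

__all__ = [
    "AssayWindows",
    "AssayConfig",
    "AssayReport",
    "run_respiratory_assay",
    "run_nociception_assay",
    "final_concentration",
]

BASELINE_RATE_WINDOW_S = 60.0  # the 1-min pre-drug baseline video


@dataclass(frozen=True)
class AssayWindows:
    """Recording windows, all in seconds relative to drug application."""

    baseline_s: float = 60.0  # pre-application baseline used for QC/normalization
    post_s: float = 420.0  # analysed post-application duration
    analysis_start_s: float = 300.0  # endpoint window start (min 5)
    analysis_end_s: float = 360.0  # endpoint window end (min 6)

    def __post_init__(self) -> None:
        if self.baseline_s <= 0 or self.post_s <= 0:
            raise ValueError("window durations must be positive")
        if not 0 <= self.analysis_start_s < self.analysis_end_s <= self.post_s:
            raise ValueError("analysis window must lie within the post period")


#: The nociception assay reads the first three minutes after treatment.
NOCICEPTION_WINDOWS = AssayWindows(
    baseline_s=120.0, post_s=240.0, analysis_start_s=0.0, analysis_end_s=180.0
)


@dataclass
class AssayConfig:
    """Everything needed to reproduce one assay run."""

    kind: str  # respiratory | nociception
    design: CohortDesign | None = None
    input_dir: str | None = None
    windows: AssayWindows | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    stats: StatConfig = field(default_factory=StatConfig)
    # signal-extraction parameters (respiratory)
    peak_prominence: float = 0.3
    refractory_s: float = 0.3
    smooth_window_s: float = 0.15
    # kinematics parameters (nociception)
    bin_s: float = 1.0
    displacement_epsilon_mm: float = 0.05
    #: optional override of the default per-agonist drug models
    drug_models: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("respiratory", "nociception"):
            raise ValueError(f"unknown assay kind {self.kind!r}")
        if (self.design is None) == (self.input_dir is None):
            raise ValueError("exactly one input source (design or input_dir) required")
        if self.windows is None:
            self.windows = (
                AssayWindows() if self.kind == "respiratory" else NOCICEPTION_WINDOWS
            )

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AssayReport:
    """Per-fish endpoints, QC audit, group comparison, and provenance."""

    endpoints: pd.DataFrame
    qc: QCReport
    comparison: GroupComparison
    provenance: dict

    def content_hash(self) -> str:
        blob = (
            self.endpoints.to_csv(index=False)
            + self.comparison.to_json()
            + json.dumps(self.qc.summary(), sort_keys=True)
        )
        return hashlib.sha256(blob.encode()).hexdigest()

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.endpoints.to_csv(outdir / "endpoints.csv", index=False)
        self.qc.to_csv(outdir / "qc_report.csv")
        self.comparison.to_csv(outdir / "comparison.csv")
        summary = {
            "provenance": self.provenance,
            "qc": self.qc.summary(),
            "comparison": json.loads(self.comparison.to_json()),
            "report_hash": self.content_hash(),
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2, default=float))


def _resolve_dataset(cfg: AssayConfig) -> AssayDataset:
    if cfg.design is not None:
        return simulate_cohort(cfg.design, models=cfg.drug_models)
    from .io import load_dataset

    return load_dataset(cfg.input_dir, kind=cfg.kind)


def _provenance(cfg: AssayConfig, dataset: AssayDataset) -> dict:
    return {
        "software_version": __version__,
        "config_hash": cfg.content_hash(),
        "seed": dataset.design.seed if dataset.design is not None else None,
        "kind": cfg.kind,
        "n_fish": len(dataset),
    }


def _fence_and_compare(
    endpoint_df: pd.DataFrame, cfg: AssayConfig, group_order: list[str]
) -> tuple[pd.DataFrame, GroupComparison]:
    """Apply the per-group Tukey fence once, then run the comparison.

    Groups with fewer than 4 included fish are not fenced (quartiles are
    unstable below that).  Raises when every fish of a designed group was
    excluded, naming the group.
    """
    df = endpoint_df.copy()
    for label in group_order:
        idx = df.index[(df["group"] == label) & df["included"]]
        if len(idx) >= 4:
            mask = iqr_outlier_mask(df.loc[idx, "endpoint"].to_numpy(), cfg.qc.iqr_k)
            out_idx = idx[mask]
            df.loc[out_idx, "included"] = False
            df.loc[out_idx, "reason"] = "outlier"
    groups = {}
    for label in group_order:
        vals = df.loc[(df["group"] == label) & df["included"], "endpoint"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"all fish of group {label!r} failed quality control")
        groups[label] = vals
    return df, compare_groups(groups, cfg.stats)


def run_respiratory_assay(cfg: AssayConfig) -> AssayReport:
    """Respiratory-depression assay from config to report."""
    if cfg.kind != "respiratory":
        raise ValueError("config is not for the respiratory assay")
    dataset = _resolve_dataset(cfg)
    win = cfg.windows
    rows = []
    for rec in dataset.records:
        if rec.trace is None:
            raise ValueError(f"fish {rec.fish_id} has no intensity trace")
        app = rec.treatment.application_time
        if app < BASELINE_RATE_WINDOW_S:
            raise ValueError("recording must include a 1-min pre-drug baseline")
        peaks = detect_mandible_peaks(
            rec.trace, cfg.peak_prominence, cfg.refractory_s, cfg.smooth_window_s
        )
        baseline_rate = float(
            np.count_nonzero(
                (peaks.times >= app - BASELINE_RATE_WINDOW_S) & (peaks.times < app)
            )
        )
        keep, reason = respiratory_inclusion(baseline_rate, cfg.qc)
        endpoint = np.nan
        if keep:
            series = rate_series(peaks, t0=app, total_duration=win.post_s)
            series = normalize_to_baseline(series, baseline_rate)
            sel = np.isclose(series.window_starts - app, win.analysis_start_s)
            if not sel.any():
                raise ValueError("analysis window does not align with a rate window")
            endpoint = float(series.normalized[sel][0])
        rows.append(
            {
                "fish_id": rec.fish_id,
                "group": rec.group,
                "baseline_rate": baseline_rate,
                "true_baseline_rate": rec.true_baseline_rate,
                "endpoint": endpoint,
                "included": keep,
                "reason": reason,
            }
        )
    df = pd.DataFrame(rows)
    df, comparison = _fence_and_compare(df, cfg, dataset.groups())
    qc = QCReport(df[["fish_id", "group", "endpoint", "included", "reason"]].copy())
    return AssayReport(df, qc, comparison, _provenance(cfg, dataset))


def run_nociception_assay(cfg: AssayConfig) -> AssayReport:
    """Nociception (escape-response) assay from config to report."""
    if cfg.kind != "nociception":
        raise ValueError("config is not for the nociception assay")
    dataset = _resolve_dataset(cfg)
    win = cfg.windows
    rows = []
    for rec in dataset.records:
        if rec.trajectory is None:
            raise ValueError(f"fish {rec.fish_id} has no trajectory")
        app = rec.treatment.application_time
        if app < win.baseline_s:
            raise ValueError("recording must include the baseline window")
        vel = velocity_series(rec.trajectory, cfg.bin_s)
        ang = angular_velocity_series(
            rec.trajectory, cfg.bin_s, cfg.displacement_epsilon_mm
        )
        baseline_speed = response_summary(vel, app - win.baseline_s, app).mean
        keep, reason = swim_inclusion(baseline_speed, cfg.qc)
        endpoint = np.nan
        angular_endpoint = np.nan
        if keep:
            endpoint = response_summary(
                vel, app + win.analysis_start_s, app + win.analysis_end_s
            ).mean
            try:
                angular_endpoint = response_summary(
                    ang,
                    app + win.analysis_start_s,
                    app + win.analysis_end_s,
                    which="angular",
                ).mean
            except ValueError:
                pass  # no defined turning bins: fish essentially stationary
        rows.append(
            {
                "fish_id": rec.fish_id,
                "group": rec.group,
                "baseline_speed": baseline_speed,
                "true_baseline_speed": rec.true_baseline_speed,
                "endpoint": endpoint,
                "angular_endpoint": angular_endpoint,
                "included": keep,
                "reason": reason,
            }
        )
    df = pd.DataFrame(rows)
    df, comparison = _fence_and_compare(df, cfg, dataset.groups())
    qc = QCReport(df[["fish_id", "group", "endpoint", "included", "reason"]].copy())
    return AssayReport(df, qc, comparison, _provenance(cfg, dataset))


def final_concentration(stock: float, v_add: float, v_well: float) -> float:
    """Working concentration after pipetting ``v_add`` of stock into a well.

    ``stock * v_add / (v_add + v_well)`` — e.g. 6 uL of a 10 uM stock
    into 54 uL of medium gives 1 uM (a 10-fold dilution).
    """
    if stock < 0 or v_add < 0 or v_well < 0:
        raise ValueError("volumes and concentration must be non-negative")
    if v_add + v_well == 0:
        raise ValueError("total volume must be positive")
    return stock * v_add / (v_add + v_well)
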