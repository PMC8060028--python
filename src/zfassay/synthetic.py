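"""Synthetic cohorts under an explicit pharmacodynamic model.

Everything downstream of the camera is exercised against data generated
here with known ground truth: mandible-motion intensity traces, miniature
well videos, and swim trajectories for whole treatment groups.

The generative model, in brief:

* A drug's fractional suppression of respiratory rate follows a Hill
  dose-response with maximal effect ``emax``, half-effect concentration
  ``ec50`` (uM) and slope ``hill``, multiplied by first-order onset
  kinetics ``1 - exp(-t/onset_tau)`` after bath application.  With the
  default onset_tau of 90 s the effect passes 90% of plateau by ~4-5 min,
  matching the observed time course of fentanyl in larvae.
* A competitive antagonist (naloxone, CTAP) shifts the effective agonist
  concentration by the Gaddum/Schild factor ``d / (1 + A/kb)``.
* Mandible movements are a renewal point process with Gamma-distributed
  inter-event intervals (coefficient of variation ``rate_noise_cv``)
  whose instantaneous rate is ``baseline_rate * (1 - effect)``; the
  motion-intensity trace is a train of unimodal pulses at event times
  plus additive noise.
* Swimming is a persistent random walk confined to the well disc, with
  target speed ``baseline * (1 + gain * S(t) * (1 - analgesia))`` where
  ``S(t)`` is the onset of the nociceptive-stimulus response.  Analgesia
  suppresses the stimulus-induced *increment* only — opioids at assay
  concentrations do not slow undisturbed swimming — so a fully analgesic
  dose returns the fish to its control speed, not to zero.

Per-fish random substreams are derived by stable hashing of
(master seed, group label, fish index): adding a group to a design never
changes any other group's data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .kinematics import Trajectory
from .signals import ROI, FrameStack, IntensityTrace

__all__ = [
    "DrugModel",
    "StimulusModel",
    "FishParams",
    "FishParamsDistribution",
    "TreatmentSpec",
    "GroupSpec",
    "CohortDesign",
    "FishRecord",
    "AssayDataset",
    "BlobGeometry",
    "DRUG_MODELS",
    "STIMULUS_MODELS",
    "drug_effect",
    "antagonist_shift",
    "effective_agonist_dose",
    "respiratory_effect",
    "simulate_respiratory_trace",
    "simulate_frame_stack",
    "simulate_trajectory",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# pharmacodynamics


@dataclass(frozen=True)
class DrugModel:
    """Hill dose-response parameters for one agonist.

    ``emax``/``ec50``/``hill`` govern respiratory-rate suppression;
    ``analgesic_*`` play the same roles for suppression of the escape
    response.  ``kb`` maps antagonist names to their equilibrium
    constants (uM).  A non-zero ``excite_emax`` adds a competing
    excitatory Hill term at higher ``excite_ec50``, giving the biphasic
    (non-monotonic) profile seen with morphine; the underlying mechanism
    is deliberately not modelled.
    """

    emax: float = 0.6
    ec50: float = 0.6  # uM
    hill: float = 4.0
    onset_tau: float = 90.0  # s
    kb: dict = field(default_factory=lambda: {"naloxone": 2.0, "ctap": 40.0})
    analgesic_emax: float = 0.9
    analgesic_ec50: float = 1.5  # uM
    analgesic_hill: float = 2.0
    analgesic_onset_tau: float = 30.0  # s; escape suppression develops fast
    excite_emax: float = 0.0
    excite_ec50: float = 30.0  # uM
    excite_hill: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.emax <= 1:
            raise ValueError("emax must lie in [0, 1]")
        if self.ec50 <= 0 or self.hill <= 0 or self.onset_tau <= 0:
            raise ValueError("ec50, hill and onset_tau must be positive")
        if any(v <= 0 for v in self.kb.values()):
            raise ValueError("antagonist kb values must be positive")
        if not 0 <= self.analgesic_emax <= 1:
            raise ValueError("analgesic_emax must lie in [0, 1]")

    def analgesic_submodel(self) -> "DrugModel":
        return replace(
            self,
            emax=self.analgesic_emax,
            ec50=self.analgesic_ec50,
            hill=self.analgesic_hill,
            onset_tau=self.analgesic_onset_tau,
            excite_emax=0.0,
        )


@dataclass(frozen=True)
class StimulusModel:
    """Escape-response model for a nociceptive stimulus.

    ``gain`` is the fractional increase in target swimming speed at full
    response (dimensionless multiple of baseline); ``tau`` (s) sets the
    first-order onset after application.
    """

    gain: float = 3.0
    tau: float = 30.0

    def __post_init__(self) -> None:
        if self.gain < 0 or self.tau <= 0:
            raise ValueError("gain must be >= 0 and tau > 0")


#: Default agonist models.  Fentanyl: steep Hill placing 0.2/0.4 uM below
#: and 1/3 uM near the plateau of rate depression.  Morphine: biphasic
#: preset (inhibitory Hill minus excitatory Hill at higher EC50).
DRUG_MODELS: dict[str, DrugModel] = {
    "fentanyl": DrugModel(),
    "morphine": DrugModel(
        emax=0.5, ec50=0.5, hill=2.0, excite_emax=0.5, excite_ec50=30.0, excite_hill=2.0
    ),
}

STIMULUS_MODELS: dict[str, StimulusModel] = {
    "formalin": StimulusModel(gain=3.0, tau=30.0),
    "aitc": StimulusModel(gain=3.0, tau=30.0),
}


def _hill(dose, emax: float, ec50: float, hill: float):
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        dh = np.where(dose > 0, dose, 0.0) ** hill
    return emax * dh / (dh + ec50**hill)


def drug_effect(
    dose,
    t_since_application,
    model: DrugModel = DrugModel(),
    strain_sensitivity: float = 1.0,
) -> float | np.ndarray:
    """Fractional rate depression in [0, emax].

    ``E = s * emax * d^h / (d^h + ec50^h) * (1 - exp(-t/onset_tau))``,
    optionally minus the excitatory Hill term for biphasic presets
    (clipped to stay non-negative).  Zero dose or zero elapsed time give
    exactly zero; insensitive strains (s = 0) feel nothing.
    """
    dose = np.asarray(dose, dtype=float)
    t = np.asarray(t_since_application, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    if np.any(t < 0):
        raise ValueError("time since application must be non-negative")
    if not 0 <= strain_sensitivity <= 1:
        raise ValueError("strain_sensitivity must lie in [0, 1]")
    frac = _hill(dose, model.emax, model.ec50, model.hill)
    if model.excite_emax > 0:
        frac = frac - _hill(dose, model.excite_emax, model.excite_ec50, model.excite_hill)
    frac = np.clip(frac, 0.0, 1.0)
    onset = 1.0 - np.exp(-t / model.onset_tau)
    out = strain_sensitivity * frac * onset
    return float(out) if out.ndim == 0 else out


def antagonist_shift(agonist_dose, antagonist_dose, kb: float):
    """Gaddum/Schild shift of the effective agonist concentration.

    ``d_eff = d / (1 + A/kb)``: equal to ``d`` without antagonist, halved
    at ``A = kb``, strictly decreasing in ``A``.
    """
    d = np.asarray(agonist_dose, dtype=float)
    a = np.asarray(antagonist_dose, dtype=float)
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("doses must be non-negative")
    if kb <= 0:
        raise ValueError("kb must be positive")
    out = d / (1.0 + a / kb)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# per-fish parameters and treatments


@dataclass(frozen=True)
class FishParams:
    """Per-fish physiology and well geometry."""

    baseline_rate: float = 90.0  # mandible movements/min
    baseline_speed: float = 0.6  # mm/s
    rate_noise_cv: float = 0.1  # CV of cycle-to-cycle period
    speed_noise_cv: float = 0.2
    strain_sensitivity: float = 1.0  # 0 for insensitive strains (e.g. TU)
    well_radius: float = 5.0  # mm (10 mm diameter wells)

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.baseline_speed < 0:
            raise ValueError("baselines must be non-negative")
        if not 0 <= self.strain_sensitivity <= 1:
            raise ValueError("strain_sensitivity must lie in [0, 1]")
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        if self.rate_noise_cv < 0 or self.speed_noise_cv < 0:
            raise ValueError("noise CVs must be non-negative")


@dataclass(frozen=True)
class FishParamsDistribution:
    """Uniform sampling ranges for per-fish parameters.

    The default baseline-rate range sits inside the 60-160/min inclusion
    band (upper end of the 15-115/min control span) because published
    group sizes count included animals; pass a wider range explicitly to
    stress the inclusion rules themselves.
    """

    baseline_rate_range: tuple[float, float] = (60.0, 115.0)
    baseline_speed_range: tuple[float, float] = (0.15, 1.3)
    rate_noise_cv: float = 0.1
    speed_noise_cv: float = 0.2
    strain_sensitivity: float = 1.0
    well_radius: float = 5.0

    def sample(self, rng: np.random.Generator) -> FishParams:
        return FishParams(
            baseline_rate=float(rng.uniform(*self.baseline_rate_range)),
            baseline_speed=float(rng.uniform(*self.baseline_speed_range)),
            rate_noise_cv=self.rate_noise_cv,
            speed_noise_cv=self.speed_noise_cv,
            strain_sensitivity=self.strain_sensitivity,
            well_radius=self.well_radius,
        )


@dataclass(frozen=True)
class TreatmentSpec:
    """One well's drug combination and when it was applied."""

    agonist: str | None = None
    agonist_um: float = 0.0
    antagonist: str | None = None
    antagonist_um: float = 0.0
    stimulus: str | None = None  # nociceptive stimulus name
    stimulus_conc: float = 0.0  # formalin % or AITC uM
    application_time: float = 60.0  # s from recording start

    def __post_init__(self) -> None:
        if min(self.agonist_um, self.antagonist_um, self.stimulus_conc) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.application_time < 0:
            raise ValueError("application_time must be non-negative")


def effective_agonist_dose(treatment: TreatmentSpec, model: DrugModel) -> float:
    """Agonist concentration after the competitive-antagonist shift."""
    dose = treatment.agonist_um if treatment.agonist else 0.0
    if treatment.antagonist and treatment.antagonist_um > 0:
        key = treatment.antagonist.lower()
        if key not in model.kb:
            raise ValueError(f"no kb known for antagonist {treatment.antagonist!r}")
        dose = antagonist_shift(dose, treatment.antagonist_um, model.kb[key])
    return float(dose)


def respiratory_effect(
    t, treatment: TreatmentSpec, model: DrugModel, params: FishParams
):
    """Fractional rate depression at absolute recording time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    elapsed = np.clip(t - treatment.application_time, 0.0, None)
    dose = effective_agonist_dose(treatment, model)
    return drug_effect(dose, elapsed, model, params.strain_sensitivity)


# ---------------------------------------------------------------------------
# respiratory trace


def simulate_respiratory_trace(
    params: FishParams,
    treatment: TreatmentSpec,
    model: DrugModel,
    duration: float,
    sample_rate: float = 20.0,
    seed: int | np.random.Generator = 0,
    pulse_sigma: float = 0.05,
    pulse_amplitude: float = 1.0,
    noise_sd: float = 0.05,
) -> tuple[IntensityTrace, np.ndarray]:
    """Mandible-motion trace plus ground-truth event times.

    Events are a Gamma renewal process with instantaneous rate
    ``baseline_rate * (1 - effect)`` generated by warping unit-mean
    operational time through the integrated rate; with
    ``rate_noise_cv = 0`` the process degenerates to a deterministic
    clock.  The trace is a sum of Gaussian pulses (sd ``pulse_sigma`` s,
    height ``pulse_amplitude``) at event times plus additive noise,
    clipped at zero.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 10:
        raise ValueError("sample_rate must be at least 10 Hz to resolve events")
    base_hz = params.baseline_rate / 60.0
    if base_hz > 0 and sample_rate < 5 * base_hz:
        raise ValueError(
            f"sample_rate {sample_rate} Hz too low for baseline rate "
            f"{params.baseline_rate}/min"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    grid = np.arange(n + 1) * dt
    rate_hz = base_hz * (1.0 - respiratory_effect(grid, treatment, model, params))
    cum = cumulative_trapezoid(rate_hz, grid, initial=0.0)
    total = cum[-1]
    events = _renewal_events(rng, total, params.rate_noise_cv)
    event_times = np.interp(events, cum, grid)
    times = np.arange(n) * dt
    values = (
        rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    )
    _add_pulses(values, times, event_times, pulse_sigma, pulse_amplitude, sample_rate)
    np.clip(values, 0.0, None, out=values)
    return IntensityTrace(times, values, sample_rate), event_times


def _renewal_events(
    rng: np.random.Generator, total_operational_time: float, cv: float
) -> np.ndarray:
    """Event positions (operational time) of a unit-mean Gamma renewal process.

    The first event sits at half its drawn interval, approximating a
    stationary start; cv = 0 gives events at 0.5, 1.5, 2.5, ...
    """
    if total_operational_time <= 0:
        return np.array([])
    n_draw = int(np.ceil(total_operational_time + 5)) + int(
        10 * np.sqrt(total_operational_time + 1)
    )
    events: list[float] = []
    pos = 0.0
    first = True
    while pos <= total_operational_time:
        if cv == 0:
            draws = np.ones(n_draw)
        else:
            shape = 1.0 / cv**2
            draws = rng.gamma(shape, cv**2, n_draw)
        for x in draws:
            pos += x / 2.0 if first else x
            first = False
            if pos > total_operational_time:
                break
            events.append(pos)
        else:
            continue
        break
    return np.asarray(events)


def _add_pulses(values, times, event_times, sigma, amplitude, sample_rate) -> None:
    half = int(np.ceil(4 * sigma * sample_rate))
    n = values.size
    for te in event_times:
        c = int(round(te * sample_rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo < hi:
            values[lo:hi] += amplitude * np.exp(
                -0.5 * ((times[lo:hi] - te) / sigma) ** 2
            )


# ---------------------------------------------------------------------------
# frame stacks


@dataclass(frozen=True)
class BlobGeometry:
    """Layout of a miniature synthetic well video.

    The mandible is a Gaussian blob that displaces by ``displacement_px``
    along ``direction`` following a half-sine over ``event_duration_s``
    during each movement event, returning to rest between events.
    """

    duration: float  # s
    image_shape: tuple[int, int] = (64, 64)  # (h, w)
    blob_center: tuple[float, float] = (32.0, 32.0)  # (x, y) px
    blob_sigma: float = 2.5  # px
    blob_amplitude: float = 120.0  # intensity units above background
    background: float = 20.0
    displacement_px: float = 3.0
    direction: tuple[float, float] = (1.0, 0.0)
    event_duration_s: float = 0.2
    roi: ROI = ROI(16, 48, 16, 48)
    mm_per_pixel: float = 0.02

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        h, w = self.image_shape
        cx, cy = self.blob_center
        margin = 3 * self.blob_sigma + self.displacement_px
        if not (margin <= cx <= w - 1 - margin and margin <= cy <= h - 1 - margin):
            raise ValueError("blob (plus displacement) would leave the image bounds")


def simulate_frame_stack(
    trace_events: np.ndarray,
    geometry: BlobGeometry,
    frame_rate: float = 30.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> FrameStack:
    """Render a synthetic well video with a blob twitch at each event.

    Frame count is ``round(duration * frame_rate)``; each event displaces
    the blob over at least two frames (``event_duration_s * frame_rate``
    must be >= 2 so the motion is resolvable).  With ``noise_sd = 0`` and
    no event in progress, consecutive frames are identical.
    """
    events = np.asarray(trace_events, dtype=float)
    if frame_rate * geometry.event_duration_s < 2:
        raise ValueError("frame_rate too low to resolve events over >= 2 frames")
    if events.size > 1:
        min_gap = np.diff(np.sort(events)).min()
        if min_gap > 0 and frame_rate < 2.0 / min_gap:
            raise ValueError("frame_rate below twice the maximum event rate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(geometry.duration * frame_rate))
    h, w = geometry.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = geometry.blob_center
    ux, uy = geometry.direction
    norm = np.hypot(ux, uy) or 1.0
    ux, uy = ux / norm, uy / norm
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    frame_times = np.arange(n_frames) / frame_rate
    for i, t in enumerate(frame_times):
        offset = 0.0
        if events.size:
            phase = (t - events) / geometry.event_duration_s
            active = (phase >= 0) & (phase < 1)
            if np.any(active):
                offset = geometry.displacement_px * float(
                    np.sin(np.pi * phase[active]).max()
                )
        bx, by = cx + offset * ux, cy + offset * uy
        img = geometry.background + geometry.blob_amplitude * np.exp(
            -((xx - bx) ** 2 + (yy - by) ** 2) / (2 * geometry.blob_sigma**2)
        )
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FrameStack(frames, frame_rate, geometry.mm_per_pixel)


# ---------------------------------------------------------------------------
# trajectories


def simulate_trajectory(
    params: FishParams,
    treatment: TreatmentSpec,
    model: DrugModel,
    duration: float,
    sample_rate: float = 25.0,
    seed: int | np.random.Generator = 0,
    heading_noise: float = 90.0,
    stimulus_models: dict[str, StimulusModel] | None = None,
) -> Trajectory:
    """Persistent random walk in the well disc.

    Target speed is ``baseline * (1 + gain * S(t) * (1 - analgesia))``;
    the heading diffuses with sd ``heading_noise`` deg per sqrt(s) and
    reflects specularly at the well wall.  With all noise terms at zero
    and no stimulus, every step has length ``baseline_speed/sample_rate``
    (up to the rare wall clamp), so path length equals speed x time.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stimulus_models = stimulus_models or STIMULUS_MODELS
    dt = 1.0 / sample_rate
    n_steps = int(round(duration * sample_rate))
    times = np.arange(n_steps + 1) * dt

    # stimulus onset S(t) and analgesic suppression of the increment
    gain = 0.0
    tau = 30.0
    if treatment.stimulus and treatment.stimulus_conc > 0:
        key = treatment.stimulus.lower()
        if key not in stimulus_models:
            raise ValueError(f"unknown nociceptive stimulus {treatment.stimulus!r}")
        gain, tau = stimulus_models[key].gain, stimulus_models[key].tau
    elapsed = np.clip(times - treatment.application_time, 0.0, None)
    s_t = np.where(times >= treatment.application_time, 1.0 - np.exp(-elapsed / tau), 0.0)
    analgesia = drug_effect(
        effective_agonist_dose(treatment, model),
        elapsed,
        model.analgesic_submodel(),
        params.strain_sensitivity,
    )
    target = params.baseline_speed * (1.0 + gain * s_t * (1.0 - analgesia))

    r_well = params.well_radius
    # start away from the wall so early steps rarely clamp
    r0 = r_well * 0.5 * np.sqrt(rng.uniform())
    a0 = rng.uniform(0, 2 * np.pi)
    pos = np.empty((n_steps + 1, 2))
    pos[0] = (r0 * np.cos(a0), r0 * np.sin(a0))
    theta = rng.uniform(0, 2 * np.pi)
    turn_sd = np.radians(heading_noise) * np.sqrt(dt)
    turns = rng.normal(0.0, turn_sd, n_steps) if heading_noise > 0 else np.zeros(n_steps)
    speed_mult = (
        np.clip(rng.normal(1.0, params.speed_noise_cv, n_steps), 0.0, None)
        if params.speed_noise_cv > 0
        else np.ones(n_steps)
    )
    for k in range(n_steps):
        theta += turns[k]
        step = target[k] * speed_mult[k] * dt
        u = np.array([np.cos(theta), np.sin(theta)])
        nxt = pos[k] + step * u
        if np.hypot(*nxt) > r_well:
            nrm = nxt / np.linalg.norm(nxt)
            u = u - 2 * np.dot(u, nrm) * nrm
            theta = np.arctan2(u[1], u[0])
            nxt = pos[k] + step * u
            if np.hypot(*nxt) > r_well:
                nxt = nxt / np.linalg.norm(nxt) * (r_well * (1 - 1e-9))
        pos[k + 1] = nxt
    return Trajectory(times, pos)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    label: str
    treatment: TreatmentSpec
    n: int
    params: FishParamsDistribution = FishParamsDistribution()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("each group needs at least one fish")


@dataclass(frozen=True)
class CohortDesign:
    """A multi-well experiment: groups, recording length, sampling, seed."""

    groups: tuple[GroupSpec, ...]
    duration: float  # s, total recording including pre-drug baseline
    sample_rate: float = 20.0  # Hz (trace or position sampling)
    seed: int = 0
    assay: str = "respiratory"  # respiratory | nociception | both

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels in design")
        if self.assay not in ("respiratory", "nociception", "both"):
            raise ValueError(f"unknown assay kind {self.assay!r}")


@dataclass
class FishRecord:
    fish_id: str
    group: str
    treatment: TreatmentSpec
    params: FishParams
    trace: IntensityTrace | None = None
    event_times: np.ndarray | None = None  # ground truth
    trajectory: Trajectory | None = None
    true_baseline_rate: float = np.nan  # movements/min
    true_baseline_speed: float = np.nan  # mm/s


@dataclass
class AssayDataset:
    """Simulated cohort with per-fish ground truth."""

    design: CohortDesign
    records: list[FishRecord]
    models: dict[str, DrugModel]

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> list[str]:
        return [g.label for g in self.design.groups]

    def model_for(self, treatment: TreatmentSpec) -> DrugModel:
        if treatment.agonist:
            key = treatment.agonist.lower()
            if key not in self.models:
                raise ValueError(f"no drug model for agonist {treatment.agonist!r}")
            return self.models[key]
        return DrugModel(emax=0.0)

    def true_effect(self, record: FishRecord, t) -> np.ndarray:
        """Ground-truth fractional rate depression at recording time t."""
        return respiratory_effect(
            t, record.treatment, self.model_for(record.treatment), record.params
        )

    # -- plain-text persistence ---------------------------------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        truth_rows = []
        for rec in self.records:
            if rec.trace is not None:
                (path / "traces").mkdir(exist_ok=True)
                rec.trace.to_csv(path / "traces" / f"{rec.fish_id}.csv")
            if rec.trajectory is not None:
                (path / "trajectories").mkdir(exist_ok=True)
                rec.trajectory.to_csv(path / "trajectories" / f"{rec.fish_id}.csv")
            truth_rows.append(
                {
                    "fish_id": rec.fish_id,
                    "group": rec.group,
                    "true_baseline_rate": rec.true_baseline_rate,
                    "true_baseline_speed": rec.true_baseline_speed,
                    "n_true_events": int(rec.event_times.size)
                    if rec.event_times is not None
                    else 0,
                    "event_times": " ".join(f"{t:.6f}" for t in rec.event_times)
                    if rec.event_times is not None
                    else "",
                }
            )
        pd.DataFrame(truth_rows).to_csv(path / "ground_truth.csv", index=False)
        manifest = {
            "seed": self.design.seed,
            "assay": self.design.assay,
            "duration_s": self.design.duration,
            "sample_rate_hz": self.design.sample_rate,
            "groups": [
                {
                    "label": g.label,
                    "n": g.n,
                    "treatment": vars(g.treatment),
                }
                for g in self.design.groups
            ],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _fish_rng(master_seed: int, group_label: str, fish_index: int) -> np.random.Generator:
    """Stable per-fish substream: adding a group never perturbs another."""
    label_hash = zlib.crc32(group_label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), int(label_hash), int(fish_index)])
    return np.random.default_rng(ss)


def simulate_cohort(
    design: CohortDesign, models: dict[str, DrugModel] | None = None
) -> AssayDataset:
    """Simulate every fish of every group with ground truth attached."""
    models = dict(DRUG_MODELS if models is None else models)
    records: list[FishRecord] = []
    for group in design.groups:
        if group.treatment.agonist and group.treatment.agonist.lower() not in models:
            raise ValueError(f"no drug model for agonist {group.treatment.agonist!r}")
        model = (
            models[group.treatment.agonist.lower()]
            if group.treatment.agonist
            else DrugModel(emax=0.0)
        )
        for i in range(group.n):
            rng = _fish_rng(design.seed, group.label, i)
            params = group.params.sample(rng)
            rec = FishRecord(
                fish_id=f"{group.label}_{i:02d}",
                group=group.label,
                treatment=group.treatment,
                params=params,
                true_baseline_rate=params.baseline_rate,
                true_baseline_speed=params.baseline_speed,
            )
            if design.assay in ("respiratory", "both"):
                rec.trace, rec.event_times = simulate_respiratory_trace(
                    params,
                    group.treatment,
                    model,
                    design.duration,
                    design.sample_rate,
                    seed=rng,
                )
            if design.assay in ("nociception", "both"):
                rec.trajectory = simulate_trajectory(
                    params,
                    group.treatment,
                    model,
                    design.duration,
                    design.sample_rate,
                    seed=rng,
                )
            records.append(rec)
    return AssayDataset(design=design, records=records, models=models)
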