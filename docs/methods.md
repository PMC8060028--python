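# Methods

This note documents the models, conventions and numerical choices behind
`zfassay`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Respiratory signal path

**Motion statistic.** The mandible signal is the mean absolute per-pixel
intensity difference between consecutive frames over a user-supplied ROI
around the fish head. Mean |Δ| (rather than variance or squared
difference) is linear in contrast and robust to bit depth; it is exactly
invariant to adding a constant to every frame. The trace has one fewer
sample than the stack, timestamped at the later frame.

**Peak detection.** Peaks are local maxima of a moving-average-smoothed
trace (window 0.15 s, edge-padded so a constant trace stays constant)
with topographic prominence ≥ `min_prominence` (default 0.3 intensity
units against a default pulse amplitude of 1) and a refractory period of
0.3 s between peaks. The refractory period caps the detectable rate at
200/min, comfortably above the 160/min inclusion ceiling, so it cannot
censor a physiologically admissible fish. Plateau ties resolve to the
leftmost sample. The detector has no model of pulse shape; it is
parameter-light and auditable.

**Rates and normalization.** Rates are peak counts in consecutive,
non-overlapping 60 s windows (trailing partial window dropped), so the
unit is movements/min by construction. The baseline rate is the count in
the single 1-min pre-application window. Normalized rate is
`100 · r / r_baseline` (%); normalizing the baseline window itself gives
exactly 100%. A non-positive baseline raises an explicit error rather
than producing infinities — such fish must fail inclusion instead.

## Kinematics

Velocity per 1 s bin is summed Euclidean step length divided by bin
width (path length, not net displacement), each step assigned to the bin
of its start sample; summing `v·bin` over bins reproduces the covered
path length exactly. Angular velocity uses headings of displacement
vectors at least 0.05 mm long — shorter steps are tracking jitter and
would otherwise register as furious spinning in stationary fish — with
successive-heading changes wrapped to (−180°, 180°] and their absolute
values summed per bin. Absolute (unsigned) turning is used because the
assay direction of turn is not meaningful for the endpoint. Bins with
fewer than two valid headings are undefined (NaN) and excluded from
summaries rather than zero-filled; zero-filling would drag group medians
toward zero precisely for sedated fish. The endpoint of the nociception
assay is the mean velocity over minutes 0–3 after treatment.

## Quality control

Inclusion bands are applied to pre-treatment baselines: respiratory rate
within [60, 160] movements/min, swimming velocity within [0.1, 2] mm/s.
Both bands are inclusive at the edges: what is excluded is strictly
*below* or *above* the thresholds. Outliers are removed by Tukey's rule
(outside quartile ± 1.5·IQR) with quartiles by linear interpolation of
order statistics — the convention is part of the contract because fence
membership can flip under Tukey-hinge quartiles. The fence is applied
once, per experimental group, on the analysis endpoint after
normalization, and never re-applied iteratively; groups with fewer than
four included fish are not fenced (quartiles are unstable below that).
Every excluded fish carries exactly one primary reason code, and the
per-group accounting identity (included + excluded = total) is enforced
by the report object itself.

## Group statistics

The branch is chosen by the data unless forced: parametric iff every
group passes Shapiro–Wilk at α = 0.05 *and* the groups jointly pass
Brown–Forsythe (median-centered Levene) at α. A constant group cannot be
tested and fails the gate with a diagnostic rather than an exception.

*Parametric branch:* one-way ANOVA omnibus; pairwise two-sided pooled-
variance t tests adjusted by step-down Šidák (Holm–Šidák): with raw p
sorted ascending, `adj_i = max_{j≤i} 1 − (1 − p_j)^(m−j+1)`, clipped to
1. *Rank branch:* Wilcoxon rank-sum for two groups (exact null
enumeration when combined n ≤ 20 and tie-free, otherwise normal
approximation with tie and continuity correction); for three or more
groups, tie-corrected Kruskal–Wallis followed by Dunn's z on mean ranks
with tie-corrected variance
`z = (R̄_i − R̄_j)/√((N(N+1)/12 − T/(12(N−1)))(1/n_i + 1/n_j))`,
`T = Σ(t³ − t)`. Dunn p-values are Holm-adjusted by default; unadjusted
and Šidák variants are exposed because the classical procedure is
sometimes reported raw. Dunn's test is implemented in-package and
cross-checked in the tests against brute-force ranking on small groups.

Post-hoc tables are computed unconditionally rather than gated on a
significant omnibus, so the pairwise familywise error rate tracks α
under the null; the omnibus result is reported alongside. Note that
step-down procedures control FWER at *≤* α, so empirical null rejection
rates sit slightly below the nominal level. Both full-pairwise and
control-versus-all comparison schemes are available (several assay
designs only ever compare against control). Summaries follow the
branch: mean ± SD, or median with interpolated quartiles.

## The synthetic cohort generator

The generator defines the conditions under which the analysis chain is
validated; its defaults are fixed, not tuning knobs.

**Pharmacodynamics.** Fractional rate suppression is
`E = s·Emax·d^h/(d^h+EC50^h)·(1−e^(−t/τ))` with fentanyl defaults
Emax = 0.6, EC50 = 0.6 µM, h = 4, τ = 90 s. The Hill slope and EC50
place 0.2–0.4 µM well below and 1–3 µM near the plateau (the observed
effective/ineffective split), and τ = 90 s puts the effect above 90% of
plateau by 4–5 min, matching the observed onset. The published group
effect magnitudes exist only as figure bars, so Emax = 0.6 is a declared
convention, not a measured fact — every test is phrased against this
configured truth. Antagonism is competitive (Gaddum):
`d_eff = d/(1 + A/Kb)` with Kb(naloxone) = 2 µM (so 20 µM reverses
almost fully while 10 µM reverses only partially) and Kb(CTAP) = 40 µM
(weak in-assay antagonism). Morphine is offered as a biphasic preset —
an inhibitory Hill minus an excitatory Hill at higher EC50 — reproducing
a non-monotonic dose profile without claiming a mechanism.

**Analgesia.** The escape-response model multiplies target swimming
speed by `(1 + g·S(t)·(1 − E_analgesic))` with stimulus gain g = 3
(taking a ~0.1–1.3 mm/s swimmer into the observed ~0.7–4 mm/s stimulated
range) and stimulus onset tau 30 s. Two deliberate choices here:
(1) analgesia suppresses the stimulus-induced *increment* only, not the
whole speed — opioids at assay concentrations do not slow undisturbed
swimming, and a fully analgesic dose must return a stimulated fish to
control speed, not to zero; (2) the analgesic effect has its own onset
constant (30 s, the stimulus timescale) rather than the 90 s respiratory
onset, because the behavioural suppression is observed within the first
minutes — with a 90 s lag even a saturating dose would leave a large
spurious early escape transient. Analgesic Emax = 0.9, EC50 = 1.5 µM,
h = 2 are conventions of the same standing as Emax above.

**Event process.** Mandible events form a renewal process with
Gamma-distributed inter-event intervals (unit mean, CV =
`rate_noise_cv`, default 0.1) warped through the integrated
instantaneous rate `r_baseline·(1 − E(t))/60`. The Gamma renewal keeps a
closed-form mean rate while avoiding the zero-variance artifacts of a
deterministic clock; CV = 0 degenerates to the deterministic limit
(exactly `r` uniformly spaced events per minute). The first event sits
at half its drawn interval, approximating a stationary start. The trace
is a train of Gaussian pulses (σ = 0.05 s, amplitude 1) at event times
plus additive Gaussian noise (sd 0.05), clipped at zero.

**Video.** The miniature well video renders a Gaussian blob that
displaces a few pixels along a fixed direction following a half-sine
over 0.2 s per event, on a uint8 background with optional pixel noise.
It exists to exercise the frame-difference path end-to-end, not to
mimic optics: no lens blur, no illumination drift, no fish body.

**Swimming.** A persistent random walk: heading diffuses at 90°/√s,
per-step speed is the target speed times (1 + CV·noise), and the wall of
the 10 mm-diameter well reflects the heading specularly (with a clamp to
the disc in the rare corner cases). With all noise at zero, step length
is exactly `speed/sample_rate`, so path-length bookkeeping is testable
in closed form. The same 10 mm well diameter is used for both assay
plates (the nociception plate's well diameter is not printed anywhere
authoritative).

**Cohorts and reproducibility.** Per-fish substreams derive from a
stable hash of (master seed, CRC32 of group label, fish index), so
adding a group to a design never changes any other group's data, and the
same design + seed reproduces a cohort bit-for-bit. Default per-fish
baseline rates are drawn Uniform(60, 115)/min — inside the inclusion
band, spanning the upper part of the observed 15–115/min control range —
because published group sizes count *included* animals and a default
that straddled the 60/min floor would silently halve designed group
sizes. The full 15–115 span is used explicitly where the point is to
stress extraction or inclusion. Baseline speeds are Uniform(0.15, 1.3)
mm/s, inside the observed control range. Insensitive strains (e.g. TU)
are modelled purely as `strain_sensitivity = 0`.

**What passing tests do and do not show.** The generator emulates rate
depression, antagonist reversal, strain insensitivity, escape responses
and analgesia with realistic magnitudes and group sizes, but real traces
carry non-stationary baselines, movement artifacts, tracking dropouts
and optical confounds that are not modelled. Green tests demonstrate
that the analysis chain recovers what the generative model puts in at
the configured noise levels — they do not certify performance on real
video.

## Assay orchestration and problem sizes

Both pipelines follow separate-groups designs (one drug combination per
animal; sequential dosing in a well is deliberately unsupported).
Respiratory runs default to a 60 s baseline plus 7 min of post-drug
recording at 20 Hz — enough to cover the minutes 5–6 endpoint window —
and nociception runs to a 2 min baseline plus 4 min post at 25 Hz;
longer recordings (the full 30 min / 15 min protocols) are a matter of
passing longer durations. Reports embed a config hash, seed and version,
and identical config + seed reproduce a byte-identical report hash.

Degenerate inputs are refused loudly rather than repaired: single-frame
stacks, non-finite trace values, non-uniform trajectory sampling beyond
0.1% relative tolerance, ROIs outside frame bounds, and cohorts in which
an entire group fails QC (the error names the group).

## Known limitations

No pharmacokinetics (bath concentration is assumed constant after
application), no hydrodynamics or multi-fish interaction, no 3-D motion,
no automatic ROI/head detection, no burst/turn classification, and no
repeated-measures statistics. The biphasic morphine preset is a curve
shape, not a mechanism. Angular velocity is reported but the escape
endpoint is velocity; unsigned turning makes direction-of-effect claims
for ω deliberately conservative.
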