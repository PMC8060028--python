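"""Generator: pharmacodynamics, point process, frames, trajectories, cohorts."""

import math

import numpy as np
import pytest

import zfassay as zf
from zfassay.synthetic import (
    BlobGeometry,
    FishParamsDistribution,
    _renewal_events,
    effective_agonist_dose,
    respiratory_effect,
)


class TestDrugEffect:
    def test_zero_dose_and_zero_time(self):
        assert zf.drug_effect(0.0, 300.0) == 0.0
        assert zf.drug_effect(1.0, 0.0) == 0.0

    def test_closed_form_value(self):
        # independent evaluation of E = emax * d^h/(d^h+ec50^h) * (1-exp(-t/tau))
        expected = 0.6 * (1.0 / (1.0 + 0.6**4)) * (1.0 - math.exp(-300.0 / 90.0))
        assert zf.drug_effect(1.0, 300.0) == pytest.approx(expected, rel=1e-12)

    def test_insensitive_strain_feels_nothing(self):
        assert zf.drug_effect(3.0, 600.0, strain_sensitivity=0.0) == 0.0

    def test_monotone_in_dose_and_time(self):
        doses = np.linspace(0, 5, 40)
        e_dose = zf.drug_effect(doses, 300.0)
        assert np.all(np.diff(e_dose) >= 0)
        times = np.linspace(0, 900, 40)
        e_t = zf.drug_effect(1.0, times)
        assert np.all(np.diff(e_t) >= 0)
        assert np.all(e_dose <= 0.6 + 1e-12)

    def test_effective_vs_ineffective_dose_split(self):
        # at 5 min the 1 uM effect is near plateau while 0.4 uM is well below
        e_low = zf.drug_effect(0.4, 300.0)
        e_high = zf.drug_effect(1.0, 300.0)
        assert e_low < e_high
        assert e_high / 0.6 > 0.8

    def test_biphasic_preset_is_nonmonotone(self):
        morphine = zf.DRUG_MODELS["morphine"]
        e = zf.drug_effect(np.array([1.0, 50.0, 200.0]), 600.0, morphine)
        assert e[0] > e[2]  # low dose depresses more than high dose

    @pytest.mark.parametrize("dose,t", [(-1.0, 10.0), (1.0, -5.0)])
    def test_invalid_arguments(self, dose, t):
        with pytest.raises(ValueError):
            zf.drug_effect(dose, t)


class TestAntagonistShift:
    def test_examples(self):
        assert zf.antagonist_shift(1.0, 0.0, 2.0) == 1.0
        assert zf.antagonist_shift(1.0, 2.0, 2.0) == pytest.approx(0.5)
        assert zf.antagonist_shift(1.0, 20.0, 2.0) == pytest.approx(1.0 / 11.0)

    def test_strictly_decreasing_in_antagonist(self):
        a = np.linspace(0, 50, 60)
        d_eff = zf.antagonist_shift(1.0, a, 2.0)
        assert np.all(np.diff(d_eff) < 0)
        assert np.all(d_eff <= 1.0)

    def test_bad_kb(self):
        with pytest.raises(ValueError):
            zf.antagonist_shift(1.0, 1.0, 0.0)

    def test_treatment_lookup(self):
        tr = zf.TreatmentSpec(
            agonist="fentanyl", agonist_um=1.0, antagonist="naloxone", antagonist_um=20.0
        )
        assert effective_agonist_dose(tr, zf.DrugModel()) == pytest.approx(1.0 / 11.0)
        with pytest.raises(ValueError, match="no kb"):
            effective_agonist_dose(
                zf.TreatmentSpec(agonist="fentanyl", agonist_um=1.0,
                                 antagonist="mystery", antagonist_um=1.0),
                zf.DrugModel(),
            )


class TestRespiratoryTrace:
    def test_deterministic_limit(self, no_drug):
        params = zf.FishParams(baseline_rate=60.0, rate_noise_cv=0.0)
        trace, events = zf.simulate_respiratory_trace(
            params, no_drug, zf.DrugModel(), 60.0, 20.0, seed=0, noise_sd=0.0
        )
        assert len(events) == 60
        assert np.allclose(np.diff(events), 1.0)
        assert trace.values.size == 60 * 20

    def test_full_effect_silences_rate(self):
        model = zf.DrugModel(emax=1.0, ec50=0.01, hill=4.0, onset_tau=1.0)
        params = zf.FishParams(baseline_rate=120.0, rate_noise_cv=0.0)
        tr = zf.TreatmentSpec(agonist="x", agonist_um=10.0, application_time=0.0)
        # effect saturates within a few seconds; no events after t = 30 s
        _, events = zf.simulate_respiratory_trace(
            params, tr, model, 120.0, 20.0, seed=1, noise_sd=0.0
        )
        assert np.count_nonzero(events > 30.0) == 0

    def test_event_count_tracks_integrated_rate(self, default_model):
        params = zf.FishParams(baseline_rate=90.0)
        tr = zf.TreatmentSpec(agonist="fentanyl", agonist_um=1.0, application_time=60.0)
        _, events = zf.simulate_respiratory_trace(
            params, tr, default_model, 600.0, 20.0, seed=3
        )
        grid = np.linspace(0, 600, 6001)
        rate = params.baseline_rate / 60.0 * (
            1.0 - respiratory_effect(grid, tr, default_model, params)
        )
        expected = np.trapezoid(rate, grid)
        assert abs(len(events) - expected) <= 3 * np.sqrt(expected)

    def test_seed_reproducibility(self, no_drug, default_model):
        params = zf.FishParams()
        a = zf.simulate_respiratory_trace(params, no_drug, default_model, 60.0, 20.0, seed=9)
        b = zf.simulate_respiratory_trace(params, no_drug, default_model, 60.0, 20.0, seed=9)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1], b[1])

    def test_sample_rate_too_low(self, no_drug, default_model):
        with pytest.raises(ValueError):
            zf.simulate_respiratory_trace(
                zf.FishParams(), no_drug, default_model, 60.0, 5.0, seed=0
            )

    def test_renewal_cv_zero_is_clock(self, rng):
        ev = _renewal_events(rng, 10.0, 0.0)
        assert np.allclose(ev, np.arange(10) + 0.5)


class TestFrameStack:
    def test_no_events_no_noise_frames_identical(self):
        geom = BlobGeometry(duration=1.0)
        stack = zf.simulate_frame_stack(np.array([]), geom, 30.0, noise_sd=0.0)
        assert np.all(stack.frames == stack.frames[0])

    def test_frame_count_arithmetic(self):
        geom = BlobGeometry(duration=10.0)
        stack = zf.simulate_frame_stack(np.array([]), geom, 30.0)
        assert stack.n_frames == 300

    def test_single_event_localized_motion(self):
        geom = BlobGeometry(duration=2.0, event_duration_s=0.2)
        stack = zf.simulate_frame_stack(np.array([1.0]), geom, 30.0, noise_sd=0.0)
        trace = zf.motion_signal(stack, geom.roi)
        moving = trace.values > 0
        # motion only in frames overlapping the event [1.0, 1.2] (+1 frame lag)
        assert moving.any()
        assert np.all(trace.times[moving] >= 1.0 - 1e-9)
        assert np.all(trace.times[moving] <= 1.2 + 2.0 / 30.0)

    def test_blob_outside_bounds(self):
        with pytest.raises(ValueError, match="bounds"):
            BlobGeometry(duration=1.0, blob_center=(2.0, 2.0))


class TestTrajectory:
    def test_zero_speed_is_stationary(self, no_drug, default_model):
        traj = zf.simulate_trajectory(
            zf.FishParams(baseline_speed=0.0), no_drug, default_model, 30.0, 25.0, seed=4
        )
        assert np.allclose(traj.xy, traj.xy[0])

    def test_confined_to_well(self, default_model):
        tr = zf.TreatmentSpec(stimulus="aitc", stimulus_conc=100.0, application_time=10.0)
        traj = zf.simulate_trajectory(
            zf.FishParams(baseline_speed=1.2), tr, default_model, 120.0, 25.0, seed=5
        )
        assert np.all(np.hypot(traj.xy[:, 0], traj.xy[:, 1]) <= 5.0 + 1e-9)

    def test_path_length_no_noise(self, no_drug, default_model):
        params = zf.FishParams(baseline_speed=1.0, speed_noise_cv=0.0)
        traj = zf.simulate_trajectory(params, no_drug, default_model, 60.0, 25.0, seed=6)
        path = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1).sum()
        assert path == pytest.approx(60.0, rel=1e-3)  # wall clamps are rare and tiny

    def test_seed_reproducibility(self, no_drug, default_model):
        params = zf.FishParams()
        a = zf.simulate_trajectory(params, no_drug, default_model, 20.0, 25.0, seed=7)
        b = zf.simulate_trajectory(params, no_drug, default_model, 20.0, 25.0, seed=7)
        assert np.array_equal(a.xy, b.xy)


class TestCohort:
    def dose_response_design(self, seed=0):
        tr = lambda um: zf.TreatmentSpec(
            agonist="fentanyl" if um else None, agonist_um=um, application_time=60.0
        )
        sizes = {"control": (17, 0.0), "f02": (6, 0.2), "f04": (3, 0.4),
                 "f1": (9, 1.0), "f3": (8, 3.0)}
        groups = tuple(
            zf.GroupSpec(label, tr(um), n) for label, (n, um) in sizes.items()
        )
        return zf.CohortDesign(groups, duration=150.0, sample_rate=20.0, seed=seed)

    def test_designed_group_sizes(self):
        ds = zf.simulate_cohort(self.dose_response_design())
        assert len(ds) == 43
        counts = {}
        for rec in ds.records:
            counts[rec.group] = counts.get(rec.group, 0) + 1
        assert counts == {"control": 17, "f02": 6, "f04": 3, "f1": 9, "f3": 8}

    def test_duplicate_labels_rejected(self):
        g = zf.GroupSpec("a", zf.TreatmentSpec(), 2)
        with pytest.raises(ValueError, match="duplicate"):
            zf.CohortDesign((g, g), duration=120.0)

    def test_control_only_truth_is_zero_effect(self):
        g = zf.GroupSpec("control", zf.TreatmentSpec(application_time=60.0), 3)
        ds = zf.simulate_cohort(zf.CohortDesign((g,), duration=120.0, seed=1))
        for rec in ds.records:
            assert np.all(ds.true_effect(rec, np.linspace(0, 120, 50)) == 0.0)

    def test_same_seed_identical_datasets(self):
        d1 = zf.simulate_cohort(self.dose_response_design(seed=2))
        d2 = zf.simulate_cohort(self.dose_response_design(seed=2))
        for r1, r2 in zip(d1.records, d2.records):
            assert np.array_equal(r1.trace.values, r2.trace.values)
            assert np.array_equal(r1.event_times, r2.event_times)

    def test_adding_group_leaves_others_untouched(self):
        base = self.dose_response_design(seed=3)
        extra = zf.CohortDesign(
            base.groups + (zf.GroupSpec("new", zf.TreatmentSpec(), 2),),
            duration=base.duration,
            sample_rate=base.sample_rate,
            seed=3,
        )
        d1 = zf.simulate_cohort(base)
        d2 = zf.simulate_cohort(extra)
        by_id = {r.fish_id: r for r in d2.records}
        for rec in d1.records:
            assert np.array_equal(rec.trace.values, by_id[rec.fish_id].trace.values)

    def test_params_distribution_ranges(self, rng):
        dist = FishParamsDistribution(baseline_rate_range=(15.0, 115.0))
        rates = [dist.sample(rng).baseline_rate for _ in range(200)]
        assert min(rates) >= 15.0 and max(rates) <= 115.0
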