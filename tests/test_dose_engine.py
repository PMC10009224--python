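import numpy as np
import pytest

from lymphodose.circulation import build_default_model, simulate_paths
from lymphodose.dose_engine import (
    BeamSchedule,
    CoursePlan,
    _fraction_seeds,
    accumulate_course,
    fraction_dose,
)
from lymphodose.dvh_io import OrganDVH


def _paths(model, schedule, seed, n):
    return simulate_paths(model, schedule.fraction_duration_s, seed, n)


class TestFractionDose:
    def test_uniform_single_compartment_exact(self, single_compartment_model, uniform_plan_dvh):
        schedule, course = BeamSchedule(), CoursePlan(30)
        paths = _paths(single_compartment_model, schedule, 0, 100)
        dose = fraction_dose(paths, {"lungs": uniform_plan_dvh}, schedule, course, seed=1)
        np.testing.assert_allclose(dose, 66.0 / 30.0, atol=1e-12)

    def test_zero_dose_plan(self, single_compartment_model):
        zero = OrganDVH("lungs", np.array([0.0]), np.array([1.0]), "differential")
        schedule, course = BeamSchedule(), CoursePlan(30)
        paths = _paths(single_compartment_model, schedule, 0, 100)
        dose = fraction_dose(paths, {"lungs": zero}, schedule, course, seed=1)
        np.testing.assert_array_equal(dose, 0.0)

    def test_two_bin_expectation(self, single_compartment_model):
        # 50% @1 GyE, 50% @3 GyE per fraction -> mean element dose 2.0
        dvh = OrganDVH("lungs", np.array([1.0, 3.0]), np.array([0.5, 0.5]), "differential")
        schedule, course = BeamSchedule(), CoursePlan(1)
        paths = _paths(single_compartment_model, schedule, 0, 4000)
        dose = fraction_dose(paths, {"lungs": dvh}, schedule, course, seed=2)
        se = dose.std(ddof=1) / np.sqrt(dose.size)
        assert abs(dose.mean() - 2.0) < 3 * se

    def test_missing_dose_source_dvh_errors(self, default_model, uniform_plan_dvh):
        schedule, course = BeamSchedule(), CoursePlan(30)
        paths = _paths(default_model, schedule, 0, 50)
        with pytest.raises(KeyError, match="heart"):
            fraction_dose(paths, {"lungs": uniform_plan_dvh}, schedule, course, seed=1)

    def test_remainder_accrues_nothing(self, uniform_plan_dvh, two_bin_cumulative):
        model = build_default_model(None)
        schedule, course = BeamSchedule(), CoursePlan(1)
        paths = _paths(model, schedule, 9, 500)
        dose = fraction_dose(
            paths, {"lungs": uniform_plan_dvh, "heart": two_bin_cumulative},
            schedule, course, seed=1,
        )
        # an element that never visited heart or lungs gets exactly zero
        organ_idx = [i for i, c in enumerate(paths.compartments) if paths.dose_sources[c]]
        visited = np.zeros(paths.n_elements, dtype=bool)
        for ci in organ_idx:
            visited[np.unique(paths.elem[paths.comp == ci])] = True
        if (~visited).any():
            np.testing.assert_array_equal(dose[~visited], 0.0)


class TestAccumulateCourse:
    def test_thirty_fraction_degenerate_exact(self, single_compartment_model, uniform_plan_dvh):
        dist = accumulate_course(
            single_compartment_model, {"lungs": uniform_plan_dvh},
            BeamSchedule(), CoursePlan(30), seed=4, n_elements=200,
        )
        np.testing.assert_allclose(dist.doses, 66.0, atol=1e-9)

    def test_mean_dose_conservation(self, default_model):
        lungs = OrganDVH("lungs", np.array([0.0, 10.0, 30.0]), np.array([1.0, 0.6, 0.0]))
        heart = OrganDVH("heart", np.array([0.0, 20.0, 50.0]), np.array([1.0, 0.3, 0.0]))
        expected = 0.105 * lungs.mean_dose + 0.090 * heart.mean_dose
        dist = accumulate_course(
            default_model, {"lungs": lungs, "heart": heart},
            BeamSchedule(), CoursePlan(10), seed=6, n_elements=8000,
        )
        se = dist.doses.std(ddof=1) / np.sqrt(dist.n_elements)
        assert abs(dist.doses.mean() - expected) < 3 * se

    def test_linearity_in_plan_dose(self, default_model, two_bin_cumulative):
        heart = OrganDVH("heart", np.array([0.0, 20.0]), np.array([1.0, 0.4]))
        kw = dict(schedule=BeamSchedule(), course=CoursePlan(3), seed=8, n_elements=400)
        base = accumulate_course(
            default_model, {"lungs": two_bin_cumulative, "heart": heart}, **kw
        )
        lam = 1.7
        scaled_dvhs = {
            "lungs": OrganDVH("lungs", two_bin_cumulative.dose_grid * lam, two_bin_cumulative.volume),
            "heart": OrganDVH("heart", heart.dose_grid * lam, heart.volume),
        }
        scaled = accumulate_course(default_model, scaled_dvhs, **kw)
        np.testing.assert_allclose(scaled.doses, base.doses * lam, rtol=1e-12)

    def test_single_fraction_consistency(self, single_compartment_model):
        dvh = OrganDVH("lungs", np.array([1.0, 3.0]), np.array([0.5, 0.5]), "differential")
        schedule, course = BeamSchedule(), CoursePlan(1)
        dist = accumulate_course(
            single_compartment_model, {"lungs": dvh}, schedule, course, seed=12, n_elements=300
        )
        path_seed, draw_seed = _fraction_seeds(12, 0)
        paths = simulate_paths(single_compartment_model, schedule.fraction_duration_s, path_seed, 300)
        direct = fraction_dose(paths, {"lungs": dvh}, schedule, course, draw_seed)
        np.testing.assert_array_equal(dist.doses, direct)

    def test_fractionation_narrows_distribution(self, default_model, two_bin_cumulative):
        heart = OrganDVH("heart", np.array([0.0, 20.0]), np.array([1.0, 0.4]))
        dvhs = {"lungs": two_bin_cumulative, "heart": heart}
        one = accumulate_course(
            default_model, dvhs, BeamSchedule(), CoursePlan(1), seed=3, n_elements=3000
        )
        thirty = accumulate_course(
            default_model, dvhs, BeamSchedule(), CoursePlan(30), seed=3, n_elements=3000
        )
        # 30 resampled fractions average out path variability
        assert thirty.doses.std() < 30 * one.doses.std()

    def test_determinism(self, default_model, two_bin_cumulative):
        heart = OrganDVH("heart", np.array([0.0, 20.0]), np.array([1.0, 0.4]))
        kw = dict(schedule=BeamSchedule(), course=CoursePlan(2), seed=5, n_elements=200)
        a = accumulate_course(default_model, {"lungs": two_bin_cumulative, "heart": heart}, **kw)
        b = accumulate_course(default_model, {"lungs": two_bin_cumulative, "heart": heart}, **kw)
        np.testing.assert_array_equal(a.doses, b.doses)


class TestBeamSchedule:
    def test_beam_on_overlap_with_gap(self):
        s = BeamSchedule(n_beams=2, beam_on_s=60.0, inter_beam_gap_s=30.0)
        assert s.fraction_duration_s == 150.0
        # visit [50, 100) overlaps [50, 60) of beam 1 and [90, 100) of beam 2
        np.testing.assert_allclose(s.beam_on_overlap(np.array([50.0]), np.array([100.0])), 20.0)
        np.testing.assert_allclose(s.beam_on_overlap(np.array([0.0]), np.array([150.0])), 120.0)

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            BeamSchedule(n_beams=0)
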