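"""Stimulus geometry and schedule generation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohdecode import stimulus as stim


def chord(e1, e2):
    (x1, y1), (x2, y2) = e1.position, e2.position
    return math.hypot(x1 - x2, y1 - y2)


class TestCoherentPath:
    def test_five_elements_on_160_degree_sector(self):
        cfg = stim.build_coherent_path("lower_right")
        path = cfg.path_elements
        assert len(path) == 5
        # radius solves chord = 2 R sin(step/2) with 40-degree steps
        assert cfg.path_radius == pytest.approx(5.5 / (2 * math.sin(math.radians(20))))
        # every neighbouring pair is separated by exactly 5.5 degrees
        for a, b in zip(path, path[1:]):
            assert chord(a, b) == pytest.approx(5.5, abs=1e-9)

    def test_all_path_elements_on_one_circle(self):
        cfg = stim.build_coherent_path("upper_left")
        cx, cy = cfg.path_center
        radial = [math.hypot(e.position[0] - cx, e.position[1] - cy)
                  for e in cfg.path_elements]
        assert np.ptp(radial) < 1e-9
        assert radial[0] == pytest.approx(cfg.path_radius, abs=1e-9)

    def test_orientation_orthogonal_to_tangent(self):
        # on a circle the radial direction is orthogonal to the tangent, so
        # each element's orientation must be the angle of its radius vector
        cfg = stim.build_coherent_path("lower_right", n_elements=3, sector=90.0,
                                       separation=2 * math.sin(math.radians(22.5)),  # R = 1
                                       center_distance=0.5)
        assert cfg.path_radius == pytest.approx(1.0)
        cx, cy = cfg.path_center
        for e in cfg.path_elements:
            radial = math.degrees(math.atan2(e.position[1] - cy, e.position[0] - cx))
            assert (e.orientation - radial) % 180 == pytest.approx(0, abs=1e-9)
            # drift is perpendicular to orientation, i.e. along the tangent
            assert (e.drift_direction - (radial + 90)) % 180 == pytest.approx(0, abs=1e-9)

    def test_rotation_flip_reverses_all_drift_directions(self):
        acw = stim.build_coherent_path("lower_right", rotation="acw")
        cw = stim.build_coherent_path("lower_right", rotation="cw")
        for a, c in zip(acw.elements, cw.elements):
            assert a.position == pytest.approx(c.position)
            assert a.orientation == pytest.approx(c.orientation)
            assert (c.drift_direction - a.drift_direction) % 360 == pytest.approx(180)

    def test_realised_eccentricity_range_near_printed_values(self):
        cfg = stim.build_coherent_path("lower_right")
        lo, hi = cfg.realised_eccentricity_range
        assert lo == pytest.approx(4.1, abs=0.1)
        assert hi == pytest.approx(8.4, abs=0.1)

    def test_curve_element_is_middle_and_in_requested_quadrant(self):
        cfg = stim.build_coherent_path("lower_right")
        curve = cfg.curve_element
        assert cfg.path_elements[2] is curve
        assert 270 < curve.polar_angle < 360

    @pytest.mark.parametrize("kwargs", [
        dict(sector=-10.0), dict(separation=0.0), dict(n_elements=4),
        dict(n_elements=1), dict(rotation="up"), dict(curve_quadrant="lower_left"),
    ])
    def test_rejects_bad_parameters(self, kwargs):
        good = dict(curve_quadrant="lower_right")
        good.update(kwargs)
        with pytest.raises(ValueError):
            stim.build_coherent_path(**good)


class TestIncoherentSwap:
    def test_curve_and_distractor_identical_positions_unchanged(self):
        coh = stim.build_coherent_path("lower_right")
        inc = stim.make_incoherent(coh)
        assert inc.context == "incoherent"
        assert inc.curve_element == coh.curve_element
        assert inc.distractor == coh.distractor
        for a, b in zip(coh.elements, inc.elements):
            assert a.position == pytest.approx(b.position)
            assert a.role == b.role

    def test_only_inducer_orientations_change_pairwise(self):
        coh = stim.build_coherent_path("upper_left")
        inc = stim.make_incoherent(coh)
        cp, ip = coh.path_elements, inc.path_elements
        assert ip[0].orientation == cp[4].orientation
        assert ip[4].orientation == cp[0].orientation
        assert ip[1].orientation == cp[3].orientation
        assert ip[3].orientation == cp[1].orientation

    def test_swap_is_an_involution_on_orientations(self):
        coh = stim.build_coherent_path("lower_right")
        inc = stim.make_incoherent(coh)
        # swapping the swapped assignment back reproduces the coherent one
        again = [inc.path_elements[i].orientation for i in (4, 3, 2, 1, 0)]
        assert again == [e.orientation for e in coh.path_elements]

    def test_neighbour_orientation_difference_multiset_preserved(self):
        def diffs(cfg):
            out = []
            path = cfg.path_elements
            for a, b in zip(path, path[1:]):
                d = abs(a.orientation - b.orientation) % 180
                out.append(round(min(d, 180 - d), 9))
            return sorted(out)

        coh = stim.build_coherent_path("lower_right")
        assert diffs(coh) == diffs(stim.make_incoherent(coh))

    def test_rejects_non_coherent_input(self):
        inc = stim.make_incoherent(stim.build_coherent_path("lower_right"))
        with pytest.raises(ValueError):
            stim.make_incoherent(inc)


class TestDistractor:
    def test_distractor_rules(self):
        cfg = stim.build_coherent_path("lower_right")
        d, c = cfg.distractor, cfg.curve_element
        assert d.eccentricity == pytest.approx(4.1)
        assert (d.polar_angle - c.polar_angle) % 360 == pytest.approx(180)
        assert d.orientation == pytest.approx(c.orientation)
        assert (d.drift_direction - c.drift_direction) % 360 == pytest.approx(180)

    def test_distractor_quadrant_diagonally_opposite(self):
        # any curve angle in the lower-right range maps to the upper-left
        for theta in np.linspace(271, 359, 15):
            opp = (theta + 180) % 360
            assert 90 < opp < 180


class TestDriftSpeed:
    @pytest.mark.parametrize("step,rate,expected", [
        (30.0, 60.0, 5.0),    # the printed parameters
        (0.0, 60.0, 0.0),
        (45.0, 60.0, 7.5),
    ])
    def test_speed(self, step, rate, expected):
        assert stim.carrier_drift_speed(step, rate) == expected

    def test_rejects_nonpositive_frame_rate(self):
        with pytest.raises(ValueError):
            stim.carrier_drift_speed(30.0, -60.0)


class TestRunSchedule:
    def test_main_run_has_108_volumes(self):
        d = stim.generate_run_schedule(rng_seed=7)
        assert d.n_volumes == 108
        assert d.n_retained_volumes == 102
        assert len(d.stimulus_blocks) == 8
        labels = [c for c, *_ in d.stimulus_blocks]
        assert sorted(labels) == sorted(list(stim.CONDITION_LABELS) * 2)

    def test_element_localiser_has_97_volumes(self):
        d = stim.element_localiser_schedule()
        assert d.n_volumes == 97
        assert len(d.stimulus_blocks) == 8

    def test_no_condition_twice_in_a_row(self):
        for seed in range(30):
            d = stim.generate_run_schedule(rng_seed=seed)
            labels = [c for c, *_ in d.stimulus_blocks]
            assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_infeasible_constraint_rejected(self):
        with pytest.raises(ValueError):
            stim.generate_run_schedule(n_conditions=1, reps=2)

    def test_non_multiple_durations_rejected(self):
        with pytest.raises(ValueError):
            stim.generate_run_schedule(block_dur=19.0)

    def test_sampler_uniform_over_valid_orders(self):
        # brute-force enumeration of all valid 8-block sequences
        conds = list(stim.CONDITION_LABELS)
        valid = set()
        for perm in itertools.permutations(conds * 2):
            if all(a != b for a, b in zip(perm, perm[1:])):
                valid.add(perm)
        n_draws = 4000
        counts = {}
        for seed in range(n_draws):
            d = stim.generate_run_schedule(rng_seed=seed)
            order = tuple(c for c, *_ in d.stimulus_blocks)
            assert order in valid
            counts[order] = counts.get(order, 0) + 1
        # chi-square against uniform over the enumerated valid orders
        expected = n_draws / len(valid)
        chi2 = sum((counts.get(o, 0) - expected) ** 2 / expected for o in valid)
        from scipy import stats as sstats
        p = sstats.chi2.sf(chi2, len(valid) - 1)
        assert p > 1e-4

    @given(seed=st.integers(0, 2 ** 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_schedule_pure_function_of_seed(self, seed):
        a = stim.generate_run_schedule(rng_seed=seed)
        b = stim.generate_run_schedule(rng_seed=seed)
        assert a == b

    def test_events_table_roundtrip_fields(self):
        d = stim.generate_run_schedule(rng_seed=3)
        tab = d.to_events_table()
        assert list(tab.columns) == ["onset", "duration", "trial_type"]
        assert (tab.onset.diff().dropna() > 0).all()
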