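"""Controller rules, free-particle closed forms, and pull-run invariants."""

import numpy as np
import pytest

from mscscreen import (
    PullProtocol,
    build_system,
    force_from_acceleration,
    prolonged_contacts,
    run_pull,
    update_acceleration,
)
from mscscreen.steered_pull import PullResult, PullState
from mscscreen.errors import ClashError, NonTerminationError


def make_state(**kwargs):
    defaults = dict(
        positions=np.zeros((1, 3)), velocities=np.zeros((1, 3)),
        current_acceleration=2000.0, max_com_distance=5.0,
        max_distance_at_last_check=5.0,
    )
    defaults.update(kwargs)
    return PullState(**defaults)


class TestController:
    def test_stagnation_increments_by_500(self):
        state = make_state(steps_since_max_increase=400, step_index=3)
        assert update_acceleration(state, PullProtocol()) == 2500.0

    def test_stagnation_below_window_unchanged(self):
        state = make_state(steps_since_max_increase=399, step_index=3)
        assert update_acceleration(state, PullProtocol()) == 2000.0

    def test_speed_at_cap_leaves_acceleration_unchanged(self):
        # growth of 1 Å over 20 steps of 1.25 fs = exactly 4000 m/s
        state = make_state(current_acceleration=3000.0, step_index=20,
                           max_com_distance=6.0, max_distance_at_last_check=5.0)
        assert update_acceleration(state, PullProtocol()) == 3000.0

    def test_scale_down_formula(self):
        # v = 8000 m/s: factor 1-(1-0.5)^2 = 0.75, so 4000 -> 3000
        state = make_state(current_acceleration=4000.0, step_index=20,
                           max_com_distance=7.0, max_distance_at_last_check=5.0)
        assert update_acceleration(state, PullProtocol()) == pytest.approx(3000.0)

    def test_scale_down_clamped_at_minimum(self):
        state = make_state(current_acceleration=2100.0, step_index=20,
                           max_com_distance=7.0, max_distance_at_last_check=5.0)
        assert update_acceleration(state, PullProtocol()) == 2000.0

    def test_off_check_step_no_scaling(self):
        state = make_state(current_acceleration=4000.0, step_index=19,
                           max_com_distance=7.0, max_distance_at_last_check=5.0)
        assert update_acceleration(state, PullProtocol()) == 4000.0


class TestForceConversion:
    @pytest.mark.parametrize("mass,accel,expected", [
        (1.0, 1.0, 0.00166),
        (100.0, 0.0, 0.0),
        (624.24, 2000.0, 2072.4768),
    ])
    def test_printed_constant(self, mass, accel, expected):
        assert force_from_acceleration(mass, accel) == pytest.approx(expected, abs=1e-9)

    def test_positive_mass_required(self):
        with pytest.raises(ValueError):
            force_from_acceleration(0.0, 2000.0)


class TestProtocolValidation:
    def test_increment_bounded_by_minimum(self):
        with pytest.raises(ValueError):
            PullProtocol(a_min=400.0, a_increment=500.0)

    def test_positive_constants_required(self):
        with pytest.raises(ValueError):
            PullProtocol(stop_displacement=-1.0)


class TestBuildSystem:
    def test_free_particle_system(self):
        system = build_system(None, {"positions": [[0.0, 0, 0]], "masses": [624.24]})
        assert system.n_receptor == 0
        assert system.ligand_mass == pytest.approx(624.24)

    def test_clash_detected(self, anchor_structure):
        with pytest.raises(ClashError):
            build_system(anchor_structure,
                         {"positions": [[0.5, 0, 0]], "masses": [10.0]})

    def test_receptor_flags_from_residue_names(self, anchor_structure):
        system = build_system(anchor_structure,
                              {"positions": [[6.0, 0, 0]], "masses": [10.0]})
        assert bool(system.receptor_apolar[0]) is True  # LEU is apolar


@pytest.fixture(scope="module")
def free_particle_result():
    system = build_system(None, {"positions": [[0.0, 0, 0]], "masses": [624.24]})
    return run_pull(system, PullProtocol(temperature=0.0), seed=0)


@pytest.fixture(scope="module")
def bound_ligand_system(anchor_structure):
    # deep apolar well on the pull axis: escape needs controller escalation
    return build_system(
        anchor_structure,
        {"positions": [[3.928, 0, 0]], "masses": [624.24], "epsilon": [40000.0]},
        {"receptor_epsilon": [40000.0]})


class TestFreeParticleClosedForm:
    """a = 2000 pm/ps² = 20 Å/ps²: t* = sqrt(2·15/20) ≈ 1.2247 ps and
    W = m·a·d ≈ 2072.48 pN × 15 Å."""

    @pytest.fixture()
    def result(self, free_particle_result):
        return free_particle_result

    def test_termination_time(self, result):
        assert result.termination_time == pytest.approx(np.sqrt(1.5), rel=0.01)

    def test_total_work(self, result):
        assert result.total_work == pytest.approx(2072.4768 * 15.0, rel=0.01)

    def test_controller_stays_at_floor(self, result):
        assert result.acceleration_series.min() == 2000.0
        assert result.acceleration_series.max() == 2000.0

    def test_displacement_monotone_and_terminal(self, result):
        assert result.displacement_series[-1] >= 15.0
        assert np.all(np.diff(result.displacement_series) >= 0)


class TestBoundLigand:
    @pytest.fixture()
    def bound_result(self, bound_ligand_system):
        return run_pull(bound_ligand_system, PullProtocol(temperature=0.0), seed=0)

    def test_peak_force_exceeds_free_particle_floor(self, bound_result):
        floor = force_from_acceleration(624.24, 2000.0)
        assert bound_result.peak_force > floor

    def test_acceleration_never_below_minimum(self, bound_result):
        assert bound_result.acceleration_series.min() >= 2000.0

    def test_work_exceeds_free_particle_oracle(self, bound_result):
        assert bound_result.total_work > 2072.4768 * 15.0

    def test_bit_reproducible(self, bound_ligand_system, bound_result):
        again = run_pull(bound_ligand_system, PullProtocol(temperature=0.0), seed=0)
        assert again.total_work == bound_result.total_work
        np.testing.assert_array_equal(again.displacement_series,
                                      bound_result.displacement_series)


def test_seeded_thermal_run_reproducible():
    system = build_system(None, {"positions": [[0.0, 0, 0], [1.0, 0, 0]],
                                 "masses": [300.0, 324.24],
                                 "bonds": [(0, 1, 1.0, 10000.0)]})
    a = run_pull(system, PullProtocol(), seed=123)
    b = run_pull(system, PullProtocol(), seed=123)
    assert a.total_work == b.total_work
    np.testing.assert_array_equal(a.displacement_series, b.displacement_series)


def test_non_termination_guard():
    system = build_system(None, {"positions": [[0.0, 0, 0]], "masses": [624.24]})
    with pytest.raises(NonTerminationError):
        run_pull(system, PullProtocol(temperature=0.0, max_steps=10), seed=0)


class TestProlongedContacts:
    @staticmethod
    def make_result(timeline):
        return PullResult(
            peak_force=2072.5, total_work=1.0,
            displacement_series=np.linspace(0, 15, len(timeline)),
            acceleration_series=np.full(len(timeline), 2000.0),
            contact_timeline=timeline, termination_time=1.0,
            n_steps=len(timeline), ligand_mass=624.24)

    def test_persistent_residue_kept(self):
        result = self.make_result([[(96, 0, 4.0)]] * 10)
        assert prolonged_contacts(result, persistence_fraction=0.5) == {96}

    def test_transient_residue_excluded(self):
        timeline = [[(96, 0, 4.0)]] + [[]] * 9  # 10% of steps
        result = self.make_result(timeline)
        assert prolonged_contacts(result, persistence_fraction=0.5) == set()

    def test_empty_timeline(self):
        result = self.make_result([])
        assert prolonged_contacts(result) == set()

    def test_cutoff_can_tighten(self):
        result = self.make_result([[(96, 0, 4.5)]] * 10)
        assert prolonged_contacts(result, contact_cutoff=4.0) == set()
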