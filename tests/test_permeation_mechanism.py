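import numpy as np
import pytest

import knockon as kn
from knockon.scripted import (ScriptStep, build_scripted_trajectory,
                              direct_event_steps, knock_on_script,
                              lone_event_steps, soft_event_steps)
from knockon.trajio import ContractViolation
from knockon.scripted import ScriptError


def scripted(steps, sitemap, species=None):
    species = species or {"Ka": "K", "Kb": "K", "Wa": "W"}
    return build_scripted_trajectory(steps, sitemap, species)


class TestScriptedBuilder:
    def test_empty_script_rejected(self, sitemap):
        with pytest.raises(ScriptError, match="empty"):
            build_scripted_trajectory([], sitemap, {})

    def test_nonpositive_dwell_rejected(self, sitemap):
        with pytest.raises(ScriptError, match="dwell"):
            scripted([ScriptStep(0.0, {"Ka": "S4"})], sitemap)

    def test_teleport_over_occupied_site_names_step(self, sitemap):
        steps = [ScriptStep(1, {"Ka": "Scav", "Kb": "S3"}),
                 ScriptStep(1, {"Ka": "S1", "Kb": "S3"})]
        with pytest.raises(ScriptError, match="step 1"):
            scripted(steps, sitemap)

    def test_single_file_violation_rejected(self, sitemap):
        steps = [ScriptStep(1, {"Ka": "S4", "Kb": "S2"}),
                 ScriptStep(1, {"Ka": "S2", "Kb": "S4"})]
        with pytest.raises(ScriptError, match="single-file"):
            scripted(steps, sitemap)

    def test_codes_reproduce_script(self, sitemap):
        traj = scripted(soft_event_steps(), sitemap)
        states = kn.assign_sites(traj, sitemap)
        assert "0KWK" in states.codes  # water-separated pair
        assert "KWK0" in states.codes


class TestDetectPermeations:
    def test_full_outward_transit_counted_once(self, sitemap):
        steps = [ScriptStep(1, {"Ka": s}) for s in
                 ("intracellular", "Scav", "S4", "S3", "S2", "S1", "S0",
                  "extracellular")]
        traj = scripted(steps, sitemap)
        events = kn.detect_permeations(traj, sitemap)
        assert len(events) == 1
        assert events[0].direction == "outward"
        assert events[0].ion_id == "Ka"

    def test_aborted_entry_is_no_event(self, sitemap):
        steps = [ScriptStep(1, {"Ka": "intracellular"}),
                 ScriptStep(1, {"Ka": "S4"}),
                 ScriptStep(1, {"Ka": "intracellular"})]
        assert kn.detect_permeations(scripted(steps, sitemap),
                                     sitemap) == []

    def test_backstep_within_filter_still_one_event(self, sitemap):
        seq = ("intracellular", "Scav", "S4", "S3", "S4", "S3", "S2", "S1",
               "S0", "extracellular")
        steps = [ScriptStep(1, {"Ka": s}) for s in seq]
        events = kn.detect_permeations(scripted(steps, sitemap), sitemap)
        assert len(events) == 1

    def test_inward_event_counted_separately(self, sitemap):
        seq = ("extracellular", "S0", "S1", "S2", "S3", "S4", "Scav",
               "intracellular")
        steps = [ScriptStep(1, {"Ka": s}) for s in seq]
        events = kn.detect_permeations(scripted(steps, sitemap), sitemap)
        assert [e.direction for e in events] == ["inward"]

    @pytest.mark.parametrize("seed", range(8))
    def test_random_scripts_match_bookkeeping(self, sitemap, seed):
        rng = np.random.default_rng(seed)
        n_soft = int(rng.integers(0, 5))
        n_direct = int(rng.integers(0, 5))
        n_lone = int(rng.integers(0, 3))
        if n_soft + n_direct + n_lone == 0:
            n_lone = 1
        steps, species = knock_on_script(n_soft, n_direct, n_lone)
        traj = build_scripted_trajectory(steps, sitemap, species)
        events = kn.detect_permeations(traj, sitemap)
        outward = [e for e in events if e.direction == "outward"]
        assert len(outward) == n_soft + n_direct + n_lone


class TestCurrent:
    def test_no_events_zero_current(self, sitemap, tiny_traj):
        cur = kn.compute_current([], tiny_traj)
        assert cur.current_pa == 0.0

    def test_hand_unit_conversion_16_events_250_ns(self):
        # 16 * e / 250 ns = 1.025e-2 nA = 10.25 pA
        traj = kn.Trajectory(np.linspace(0, 250e3, 251),
                             [kn.Particle("K1", "K", np.zeros(251))])
        events = [kn.PermeationEvent("K1", 10.0 + i, 1000.0 * (i + 1),
                                     "outward") for i in range(16)]
        cur = kn.compute_current(events, traj)
        assert cur.current_pa == pytest.approx(10.2539, abs=2e-3)

    def test_current_linear_in_event_count(self):
        traj = kn.Trajectory(np.linspace(0, 100e3, 101),
                             [kn.Particle("K1", "K", np.zeros(101))])
        def cur(n):
            ev = [kn.PermeationEvent("K1", 1.0, 50.0 + i, "outward")
                  for i in range(n)]
            return kn.compute_current(ev, traj).current_pa
        assert cur(30) == pytest.approx(3 * cur(10))

    def test_discard_excludes_early_events(self):
        traj = kn.Trajectory(np.linspace(0, 100e3, 101),
                             [kn.Particle("K1", "K", np.zeros(101))])
        ev = [kn.PermeationEvent("K1", 1.0, 10e3, "outward"),
              kn.PermeationEvent("K1", 1.0, 90e3, "outward")]
        cur = kn.compute_current(ev, traj, discard_time_ns=50.0)
        assert cur.n_outward == 1
        assert cur.duration_ns == pytest.approx(50.0)

    def test_zero_analysed_duration_rejected(self, tiny_traj):
        with pytest.raises(ContractViolation):
            kn.compute_current([], tiny_traj, discard_time_ns=1.0)

    def test_ratio(self):
        a = kn.CurrentResult(9, 0, 10, 0.9, 1.8)
        b = kn.CurrentResult(5, 0, 10, 0.5, 1.0)
        assert kn.current_ratio(a, b) == pytest.approx(1.8)
        assert kn.current_ratio(a, a) == 1.0
        with pytest.raises(ZeroDivisionError):
            kn.current_ratio(a, kn.CurrentResult(0, 0, 10, 0.0, 0.0))


class TestMechanism:
    def _events_states(self, steps, sitemap, species=None):
        steps = [ScriptStep(1, {})] + steps  # everyone starts intracellular
        traj = build_scripted_trajectory(
            steps, sitemap, species or {"Ka": "K", "Kb": "K", "Wa": "W"})
        events = kn.detect_permeations(traj, sitemap)
        states = kn.assign_sites(traj, sitemap)
        return events, states

    def test_kwkw_pattern_is_soft(self, sitemap):
        events, states = self._events_states(soft_event_steps(), sitemap)
        outward = [e for e in events if e.direction == "outward"]
        assert kn.classify_event(outward[0], states) == "soft"

    def test_kkkk_pattern_is_direct(self, sitemap):
        events, states = self._events_states(direct_event_steps(), sitemap)
        outward = [e for e in events if e.direction == "outward"]
        assert kn.classify_event(outward[0], states) == "direct"

    def test_vacancy_between_ions_counts_direct(self, sitemap):
        # ions at S1 and S3 with a vacancy at S2: unscreened repulsion
        steps = [ScriptStep(1, {"Ka": "Scav"}),
                 ScriptStep(1, {"Ka": "S4"}),
                 ScriptStep(1, {"Ka": "S3", "Kb": "Scav"}),
                 ScriptStep(1, {"Ka": "S1", "Kb": "S3"}),
                 ScriptStep(1, {"Ka": "S0", "Kb": "S3"}),
                 ScriptStep(1, {"Ka": "extracellular", "Kb": "S3"}),
                 ScriptStep(1, {"Kb": "Scav"})]
        events, states = self._events_states(steps, sitemap)
        outward = [e for e in events if e.direction == "outward"]
        assert kn.classify_event(outward[0], states) == "direct"

    def test_lone_transit_unassigned(self, sitemap):
        events, states = self._events_states(lone_event_steps(), sitemap)
        assert kn.classify_event(events[0], states) == "unassigned"

    def test_window_coverage_required(self, sitemap):
        events, states = self._events_states(soft_event_steps(), sitemap)
        outward = [e for e in events if e.direction == "outward"]
        with pytest.raises(ContractViolation, match="cover"):
            kn.classify_event(outward[0], states[:3])

    def test_classification_invariant_to_outside_frames(self, sitemap):
        steps = soft_event_steps() + [ScriptStep(30, {})] \
            + direct_event_steps()
        events, states = self._events_states(steps, sitemap)
        outward = [e for e in events if e.direction == "outward"]
        assert kn.classify_event(outward[0], states) == "soft"
        assert kn.classify_event(outward[1], states) == "direct"

    @pytest.mark.parametrize("n_soft,n_direct,soft_pct,direct_pct", [
        (3, 13, 18.75, 81.25),    # 3 of 16 events water-mediated
        (3, 37, 7.50, 92.50),     # 3 of 40
        (35, 33, 51.47, 48.53),   # 35 of 68
        (0, 5, 0.00, 100.00),
    ])
    def test_census_percentages(self, sitemap, n_soft, n_direct, soft_pct,
                                direct_pct):
        steps, species = knock_on_script(n_soft, n_direct)
        traj = build_scripted_trajectory(steps, sitemap, species)
        events = kn.detect_permeations(traj, sitemap)
        states = kn.assign_sites(traj, sitemap)
        cen = kn.mechanism_census(events, states)
        assert cen.n_soft == n_soft
        assert cen.n_direct == n_direct
        assert cen.pct_2dp("soft") == soft_pct
        assert cen.pct_2dp("direct") == direct_pct
        assert cen.soft_pct + cen.direct_pct == pytest.approx(100.0)

    def test_three_of_seven_rounds_to_42p9(self, sitemap):
        steps, species = knock_on_script(3, 4)
        traj = build_scripted_trajectory(steps, sitemap, species)
        events = kn.detect_permeations(traj, sitemap)
        states = kn.assign_sites(traj, sitemap)
        cen = kn.mechanism_census(events, states)
        assert round(cen.soft_pct, 1) == 42.9

    def test_random_scripts_classified_exactly(self, sitemap):
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            n_soft = int(rng.integers(1, 6))
            n_direct = int(rng.integers(1, 6))
            steps, species = knock_on_script(n_soft, n_direct)
            traj = build_scripted_trajectory(steps, sitemap, species)
            events = kn.detect_permeations(traj, sitemap)
            states = kn.assign_sites(traj, sitemap)
            cen = kn.mechanism_census(events, states)
            assert (cen.n_soft, cen.n_direct) == (n_soft, n_direct)

    def test_zero_assigned_events_rejected(self, sitemap):
        steps, species = knock_on_script(0, 0, n_lone=2)
        traj = build_scripted_trajectory(steps, sitemap, species)
        events = kn.detect_permeations(traj, sitemap)
        states = kn.assign_sites(traj, sitemap)
        with pytest.raises(ContractViolation):
            kn.mechanism_census(events, states)
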