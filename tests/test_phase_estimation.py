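"""Dwell/exit estimator: classification, pooling, arithmetic, bootstrap,
and equivalence with an independent frame-walking recount."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuccikit.errors import (
    EmptyInputError,
    InvalidParameterError,
    NoTransitionsError,
)
from fuccikit.phase_estimation import (
    CellCycleEstimate,
    PhaseDwellSummary,
    bootstrap_ci,
    classify_track,
    count_phase_exits,
    cycle_ratio,
    estimate_cell_cycle,
    estimate_phase_duration,
    filter_active_germaria,
    infer_s_duration,
    summarize_tracks,
)
from fuccikit.synthetic_data import (
    ImagingConfig,
    ReporterConfig,
    simulate_imaging,
    simulate_population,
)
from fuccikit.track_io import CellTrack, Frame


def _track(states, dt=20.0, cell_id="c", germarium_id="g", layer="1"):
    """Build a track from compact state codes: G1, S0 (colorless), S (RFP-only),
    G2, M."""
    code = {
        "G1": (True, False, False),
        "S0": (False, False, False),
        "S": (False, True, False),
        "G2": (True, True, False),
        "M": (True, True, True),
    }
    frames = [Frame(i * dt, *code[s]) for i, s in enumerate(states)]
    return CellTrack(cell_id=cell_id, germarium_id=germarium_id, layer=layer, frames=frames)


class TestClassifyTrack:
    def test_g1_then_colorless_is_one_g1_exit_into_s(self):
        c = classify_track(_track(["G1", "G1", "S0"]))
        assert c.valid and not c.s_start_ambiguous
        assert [iv.phase for iv in c.intervals] == ["G1", "S"]
        g1, s = c.intervals
        assert (g1.start_min, g1.end_min) == (0.0, 30.0)  # midpoint of 20..40
        assert g1.exit_observed and not g1.entry_observed
        assert s.entry_observed and not s.exit_observed

    def test_mitotic_frame_bounded_by_midpoints(self):
        c = classify_track(_track(["G2", "M", "G1", "G1"]))
        assert [iv.phase for iv in c.intervals] == ["G2", "M", "G1"]
        m = c.intervals[1]
        assert (m.start_min, m.end_min) == (10.0, 30.0)
        assert m.entry_observed and m.exit_observed
        assert sum(iv.exit_observed for iv in c.intervals if iv.phase == "M") == 1

    def test_all_g2_is_single_censored_interval(self):
        c = classify_track(_track(["G2", "G2", "G2"]))
        assert [iv.phase for iv in c.intervals] == ["G2"]
        iv = c.intervals[0]
        assert not iv.entry_observed and not iv.exit_observed
        assert iv.dwell_min == 40.0

    def test_cyclic_order_violation_flags_track(self):
        c = classify_track(_track(["G2", "G1"]))
        assert not c.valid and "G2 -> G1" in c.reason

    def test_colorless_start_is_s_with_ambiguity_flag(self):
        c = classify_track(_track(["S0", "S", "G2"]))
        assert c.valid and c.s_start_ambiguous
        assert c.intervals[0].phase == "S"


class TestSummarizeTracks:
    def test_hand_count_two_cells_one_exit(self):
        # cell A: 60 min in G2, censored; cell B: 60 min in G2 then mitosis
        # (B's G2/M boundary = midpoint of frames at 50 and 70 -> G2 ends at 60)
        a = _track(["G2", "G2", "G2", "G2"], cell_id="a")  # frames 0..60
        b = CellTrack(
            cell_id="b",
            germarium_id="g",
            layer="1",
            frames=[
                Frame(0.0, True, True),
                Frame(50.0, True, True),
                Frame(70.0, True, True, mitotic=True),
            ],
        )
        s = summarize_tracks([a, b], "G2")
        assert s.total_observed_min == pytest.approx(120.0)
        assert s.exits == 1
        assert s.cells_tracked == 2

    def test_whole_window_in_phase_counts_time_but_no_exit(self):
        s = summarize_tracks([_track(["G2"] * 8)], "G2")
        assert s.total_observed_min == pytest.approx(140.0)
        assert s.exits == 0

    def test_ambiguous_s_start_excluded_from_s_sums(self):
        t = _track(["S0", "S", "G2"])
        assert summarize_tracks([t], "S").total_observed_min == 0.0
        included = summarize_tracks([t], "S", include_ambiguous_s_start=True)
        assert included.total_observed_min == pytest.approx(30.0)
        # the same track still contributes to G2
        assert summarize_tracks([t], "G2").total_observed_min == pytest.approx(10.0)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_tracks([], "G2")

    def test_invalid_tracks_are_skipped(self):
        bad = _track(["G2", "G1"], cell_id="bad")
        good = _track(["G2", "G2"], cell_id="good")
        s = summarize_tracks([bad, good], "G2")
        assert s.cells_tracked == 1 and s.total_observed_min == pytest.approx(20.0)


def _oracle_summary(tracks, phase):
    """Independent frame-walking recount: half of each transition gap goes to
    each flanking phase; exits counted per transition."""
    succ = {"G1": "S", "S": "G2", "G2": "M", "M": "G1"}
    total, exits = 0.0, 0
    for tr in tracks:
        labels = []
        for f in tr.frames:
            if f.mitotic:
                labels.append("M")
            elif f.gfp and f.rfp:
                labels.append("G2")
            elif f.gfp:
                labels.append("G1")
            else:
                labels.append("S")
        if any(a != b and succ[a] != b for a, b in zip(labels, labels[1:])):
            continue  # ambiguous track
        ambiguous_prefix = (
            labels[0] == "S" and not tr.frames[0].rfp and not tr.frames[0].mitotic
        )
        in_prefix = ambiguous_prefix
        for i in range(len(labels) - 1):
            a, b = labels[i], labels[i + 1]
            gap = tr.frames[i + 1].time_min - tr.frames[i].time_min
            if a == b:
                if a == phase and not in_prefix:
                    total += gap
            else:
                if a == phase and not in_prefix:
                    total += gap / 2
                    exits += 1
                if b == phase:
                    total += gap / 2
                in_prefix = False
    return total, exits


class TestOracleEquivalence:
    @pytest.mark.parametrize("phase", ["G1", "S", "G2", "M"])
    def test_summary_matches_frame_walk_recount(self, wt_durations, phase):
        pop = simulate_population(wt_durations, 400, seed=17, n_germaria=8)
        tracks = simulate_imaging(
            pop,
            wt_durations,
            ReporterConfig(),
            ImagingConfig(window_min=300, frame_interval_min=20, dropout_prob=0.05, seed=18),
        )
        s = summarize_tracks(tracks, phase)
        total, exits = _oracle_summary(tracks, phase)
        assert s.total_observed_min == pytest.approx(total, rel=1e-12)
        assert s.exits == exits


class TestEstimatePhaseDuration:
    @pytest.mark.parametrize(
        "total,exits,expected",
        [(8432, 16, 527), (1621, 20, 81), (100, 4, 25)],
    )
    def test_printed_totals_reproduce_durations(self, total, exits, expected):
        s = PhaseDwellSummary("G2", total, exits, cells_tracked=92)
        assert round(estimate_phase_duration(s)) == expected

    def test_zero_exits_raise(self):
        s = PhaseDwellSummary("G2", 500.0, 0, 5)
        with pytest.raises(NoTransitionsError):
            estimate_phase_duration(s)


class TestInferSDuration:
    def test_wild_type_layer1(self):
        assert round(infer_s_duration(81, 527, 17, 0.337)) == 318

    def test_layer2(self):
        assert round(infer_s_duration(407, 1958, 20, 0.26)) == 838

    def test_zero_fraction_gives_zero(self):
        assert infer_s_duration(81, 527, 17, 0.0) == 0.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            infer_s_duration(81, 527, 17, 1.0)

    @given(st.floats(min_value=0, max_value=0.95), st.floats(min_value=0.01, max_value=0.95))
    @settings(deadline=None)
    def test_monotone_in_s_fraction(self, f1, f2):
        lo, hi = sorted([f1, f2])
        assert infer_s_duration(81, 527, 17, lo) <= infer_s_duration(81, 527, 17, hi)


class TestCycleRatio:
    def test_layer2_over_layer1(self):
        assert cycle_ratio(3223, 943) == 3.4

    def test_uniform_jak_ratio(self):
        assert cycle_ratio(1957, 797) == 2.5

    def test_identical_estimates_give_one(self):
        est = CellCycleEstimate(81, 318, 527, 17, s_fraction_used=0.337, n_cells=92)
        assert cycle_ratio(est, est) == 1.0


class TestGermariumFilter:
    def test_inert_germaria_dropped(self):
        active = _track(["G1", "S0"], cell_id="a", germarium_id="gA")
        inert = _track(["G2", "G2"], cell_id="b", germarium_id="gB")
        kept, dropped = filter_active_germaria([active, inert])
        assert dropped == 1
        assert {t.germarium_id for t in kept} == {"gA"}

    def test_exit_counts(self):
        t = _track(["G1", "S0", "S"], cell_id="a")
        assert count_phase_exits([t], "G1") == 1
        assert count_phase_exits([t], "S") == 0


class TestBootstrap:
    def test_identical_germaria_degenerate_interval(self):
        tracks = [
            _track(["G2", "G2", "M"], cell_id=f"c{g}", germarium_id=f"g{g}")
            for g in range(4)
        ]
        res = bootstrap_ci(tracks, "G2", n_reps=100, seed=1)
        assert res.lower_min == res.upper_min == pytest.approx(res.point_estimate_min)

    def test_zero_reps_rejected(self):
        tracks = [
            _track(["G2", "M"], cell_id="a", germarium_id="g1"),
            _track(["G2", "M"], cell_id="b", germarium_id="g2"),
        ]
        with pytest.raises(InvalidParameterError):
            bootstrap_ci(tracks, "G2", n_reps=0, seed=1)

    def test_single_germarium_rejected(self):
        with pytest.raises(InvalidParameterError):
            bootstrap_ci([_track(["G2", "M"])], "G2", n_reps=10, seed=1)

    def test_coverage_on_steady_state_simulations(self, wt_durations):
        # 95% germarium-bootstrap interval should cover the true G2 duration
        # in at least 90% of independent simulated experiments
        covered = 0
        n_meta = 20
        for rep in range(n_meta):
            pop = simulate_population(wt_durations, 600, seed=1000 + rep, n_germaria=15)
            tracks = simulate_imaging(
                pop,
                wt_durations,
                ReporterConfig(),
                ImagingConfig(window_min=150, frame_interval_min=20, seed=2000 + rep),
            )
            res = bootstrap_ci(tracks, "G2", n_reps=200, seed=3000 + rep)
            covered += res.lower_min <= 527 <= res.upper_min
        assert covered >= 0.9 * n_meta


class TestEstimateCellCycle:
    def test_full_pipeline_on_simulation(self, wt_durations):
        pop = simulate_population(wt_durations, 1500, seed=31, n_germaria=15)
        tracks = simulate_imaging(
            pop,
            wt_durations,
            ReporterConfig(),
            ImagingConfig(window_min=150, frame_interval_min=20, seed=32),
        )
        est = estimate_cell_cycle(tracks, s_fraction=318 / 943)
        assert est.g1_min == pytest.approx(81, rel=0.15)
        assert est.g2_min == pytest.approx(527, rel=0.15)
        assert est.total_min == est.g1_min + est.s_min + est.g2_min + est.m_min

    def test_deduced_fractions_match_fixed_sample_fractions(self):
        # self-consistency: the estimated cycle's G1 and G2/M shares agree
        # with the fixed-image phase fractions that fed the S inference
        est = CellCycleEstimate(
            g1_min=1621 / 20,
            s_min=infer_s_duration(1621 / 20, 8432 / 16, 17, 0.337),
            g2_min=8432 / 16,
            m_min=17,
            s_fraction_used=0.337,
            n_cells=92,
        )
        g1_share = 100 * est.g1_min / est.total_min
        g2m_share = 100 * (est.g2_min + est.m_min) / est.total_min
        assert round(g1_share, 1) == 8.6
        assert round(g2m_share, 1) == 57.7
        # fixed-sample FUCCI fractions: 7.8% G1, 58.6% G2/M
        assert abs(g1_share - 7.8) < 1.5
        assert abs(g2m_share - 58.6) < 1.5
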