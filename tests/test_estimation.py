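"""Timing extraction, rates, summary fitting, matrices, ratios, heatmaps."""

import math

import numpy as np
import pytest

from socialgaze.agent import AgentEvent, AgentEventLog, Dwell, default_macro
from socialgaze.defaults import AOI_LABELS, OO_TRANSITIONS, PO_TRANSITIONS
from socialgaze.estimation import (
    attention_ratios,
    attention_table,
    build_heatmap,
    estimate_rates,
    estimate_transition_matrix,
    extract_timing,
    fit_summary_table,
    summary_to_frame,
)
from socialgaze.parsing import DwellEvent, Fixation
from socialgaze.participant import ParticipantProfile, simulate_block, simulate_participant


def agent_log(duration, *events):
    evs = [AgentEvent(0, "straight", "STRAIGHT", "IJA", "entry")]
    for onset, target, cause in events:
        evs.append(AgentEvent(onset, "x", target, "IJA", cause))
    return AgentEventLog(duration=duration, events=tuple(evs))


class TestExtractTiming:
    def test_follow_latency_forced(self):
        log = agent_log(30_000, (1000, "O3", "ija_bid"))
        dwells = [DwellEvent("O3", 1463, 2463)]
        obs = extract_timing(log, dwells, "RJA")
        vals = {o.parameter_name: o.value for o in obs}
        assert vals["t_follow_RJA"] == 463
        assert vals["t_object_RJA"] == 1000

    def test_unfollowed_bid_dwell(self):
        log = agent_log(30_000)  # agent never shifts to an object
        dwells = [DwellEvent("A", 0, 1970), DwellEvent("O1", 2000, 3590)]
        obs = extract_timing(log, dwells, "IJA")
        vals = {o.parameter_name: o.value for o in obs}
        assert vals["t_back_IJA"] == 1590
        assert vals["t_straight_IJA"] == 1970

    def test_followed_bid_timed_from_agent_arrival(self):
        log = agent_log(30_000, (2450, "O1", "follow"))
        dwells = [DwellEvent("A", 0, 1970), DwellEvent("O1", 2000, 3590)]
        obs = extract_timing(log, dwells, "IJA")
        vals = {o.parameter_name: o.value for o in obs}
        assert vals["t_object_IJA"] == 3590 - 2450
        assert "t_back_IJA" not in vals

    def test_noninteractive_dwell_classification(self):
        log = agent_log(30_000)
        dwells = [DwellEvent("O2", 0, 700), DwellEvent("A", 800, 2300)]
        obs = extract_timing(log, dwells, "OO")
        vals = {o.parameter_name: o.value for o in obs}
        assert vals["t_object_OO"] == 700
        assert vals["t_agent_OO"] == 1500

    def test_block_end_censoring(self):
        log = agent_log(30_000)
        dwells = [DwellEvent("O2", 29_000, 30_000)]
        assert extract_timing(log, dwells, "OO") == []

    def test_responses_conserve_bids(self, profile):
        """Every agent bid yields exactly one of response / non-response."""
        alog, dwells = simulate_block("RJA", profile, 60_000, seed=8)
        bids = alog.shifts_to_objects()
        obs = extract_timing(alog, dwells, "RJA")
        follows = [o for o in obs if o.parameter_name == "t_follow_RJA"]
        assert 0 < len(follows) <= len(bids)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            extract_timing(agent_log(1000), [], "XX")


class TestRates:
    def test_bid_rate_arithmetic(self):
        log = agent_log(30_000, *[(1000 * (i + 1), "O1", "ija_bid") for i in range(9)])
        rates = estimate_rates([("RJA", log, [])])
        assert rates.agent_bids_per_min == pytest.approx(18.0)
        assert rates.response_fraction == 0.0

    def test_zero_exposure_signalled(self):
        rates = estimate_rates([])
        assert math.isnan(rates.agent_bids_per_min)
        assert math.isnan(rates.response_fraction)

    def test_response_fraction_recovery(self):
        profile = ParticipantProfile(response_probability=0.85)
        blocks = []
        rng = np.random.default_rng(17)
        nbids = 0
        while nbids < 500:
            alog, dwells = simulate_block("RJA", profile, 30_000, rng)
            blocks.append(("RJA", alog, dwells))
            nbids += len(alog.shifts_to_objects())
        rates = estimate_rates(blocks)
        assert abs(rates.response_fraction - 0.85) < 0.04


class TestFitSummaryTable:
    def test_exgauss_recovery_event_level(self):
        gen = ParticipantProfile().law("t_follow_RJA")
        obs = []
        from socialgaze.estimation import TimingObservation
        for p in range(33):
            for v in gen.sample(100, seed=p):
                obs.append(TimingObservation("t_follow_RJA", v, f"p{p}", "b0"))
        summaries, skipped = fit_summary_table(obs, candidates=("exgauss",))
        assert not skipped
        s = summaries[0]
        assert s.family == "exgauss"
        assert s.est_mean == pytest.approx(474.0, abs=10.0)

    def test_insufficient_data_reported(self):
        from socialgaze.estimation import TimingObservation
        obs = [TimingObservation("t_agent_PO", 100.0, "p0", "b0")] * 3
        summaries, skipped = fit_summary_table(obs)
        assert summaries == [] and "t_agent_PO" in skipped


class TestTransitionMatrix:
    def test_trivial_alternation(self):
        tm = estimate_transition_matrix({"p0": [["O1", "O2", "O1", "O2"]]})
        assert tm["O1", "O2"] == 1.0
        assert tm["O2", "O1"] == 1.0

    def test_undefined_rows_nan_and_rows_stochastic(self):
        tm = estimate_transition_matrix({"p0": [["O1", "O2", "O1"]]})
        assert np.isnan(tm.probs[AOI_LABELS.index("O3")]).all()
        for i in (0, 1):
            assert tm.probs[i].sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("state, matrix, a, b", [
        ("OO", OO_TRANSITIONS, "O1", "O2"),
        ("PO", PO_TRANSITIONS, "O4", "A"),
    ])
    def test_recovery_from_simulated_blocks(self, profile, state, matrix, a, b):
        rng = np.random.default_rng(23)
        blocks, total = [], 0
        while total < 10_000:
            dwells = simulate_participant(state, profile, 30_000, rng)
            blocks.append([d.target for d in dwells])
            total += max(len(dwells) - 1, 0)
        tm = estimate_transition_matrix({"p0": blocks})
        i, j = AOI_LABELS.index(a), AOI_LABELS.index(b)
        assert abs(tm[a, b] - matrix[i, j]) < 0.03
        sums = np.nansum(tm.probs, axis=1)
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)


class TestAttentionRatios:
    def test_on_aoi_ratio_forced(self):
        r_aoi, _ = attention_ratios([DwellEvent("O1", 0, 25_200)], 30_000)
        assert r_aoi == pytest.approx(0.84)

    def test_face_object_ratio_bounds(self):
        _, r = attention_ratios([DwellEvent("A", 0, 2000)], 30_000)
        assert r == 1.0
        _, r = attention_ratios([DwellEvent("A", 0, 2000), DwellEvent("O1", 2100, 8100)], 30_000)
        assert r == pytest.approx(0.25)

    def test_no_dwells_undefined(self):
        r_aoi, r_a_o = attention_ratios([], 30_000)
        assert r_aoi == 0.0 and math.isnan(r_a_o)

    def test_translation_invariance(self):
        base = [DwellEvent("A", 0, 2000), DwellEvent("O1", 2100, 8100)]
        shifted = [DwellEvent(d.aoi, d.onset + 500, d.offset + 500) for d in base]
        assert attention_ratios(base, 30_000) == attention_ratios(shifted, 30_000)

    def test_table_aggregates_per_participant_state(self):
        blocks = [("p0", "OO", 30_000.0, [DwellEvent("O1", 0, 15_000)]),
                  ("p0", "OO", 30_000.0, [DwellEvent("A", 0, 15_000)])]
        df = attention_table(blocks)
        assert len(df) == 1
        assert df.loc[0, "r_aoi"] == pytest.approx(0.5)
        assert df.loc[0, "r_a_o"] == pytest.approx(0.5)


class TestHeatmap:
    def test_single_fixation_argmax_at_position(self):
        hm = build_heatmap([Fixation(0, 300, 400.0, 300.0, 10)], downsample=4)
        iy, ix = np.unravel_index(np.argmax(hm.grid), hm.grid.shape)
        assert abs(ix * 4 - 400) <= 8 and abs(iy * 4 - 300) <= 8

    def test_mirror_symmetry(self):
        fx = [Fixation(0, 500, 760.0, 540.0, 10), Fixation(500, 1000, 1160.0, 540.0, 10)]
        hm = build_heatmap(fx, canvas=(1920, 1080), downsample=4)
        flipped = hm.mass[:, ::-1]
        assert np.allclose(hm.mass, flipped, atol=1e-9 + hm.mass.max() * 1e-9)

    def test_mass_linear_in_duration(self):
        fx = [Fixation(0, 300, 400.0, 400.0, 10), Fixation(300, 900, 1400.0, 700.0, 10)]
        hm = build_heatmap(fx, downsample=2)
        left = hm.mass[:, : hm.mass.shape[1] // 2].sum()
        right = hm.mass[:, hm.mass.shape[1] // 2 :].sum()
        assert right / left == pytest.approx(2.0, rel=1e-6)

    def test_degenerate_variance_uses_min_radius(self):
        hm = build_heatmap([Fixation(0, 300, 500.0, 500.0, 10)], min_radius=5.0)
        assert hm.radius == 5.0

    def test_requires_fixations(self):
        with pytest.raises(ValueError):
            build_heatmap([])


def test_summary_frame_columns():
    from socialgaze.estimation import TimingObservation
    gen = ParticipantProfile().law("t_object_RJA")
    obs = [TimingObservation("t_object_RJA", v, f"p{p}", "b0")
           for p in range(3) for v in gen.sample(50, seed=p)]
    summaries, _ = fit_summary_table(obs)
    df = summary_to_frame(summaries)
    assert list(df["parameter"]) == ["t_object_RJA"]
    for col in ("raw_mean", "raw_sd", "family", "mu", "rho", "eta", "est_mean", "est_sd"):
        assert col in df.columns
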