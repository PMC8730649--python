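"""Quantization, interval algebra and per-epoch presence computation.

The interval arithmetic is cross-checked against an independent brute-force
oracle that samples membership on a 1 ms lattice.
"""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neopain import (
    HoldEvent,
    PhaseStartSet,
    clip_interval_to_epoch,
    compute_epoch_results,
    merge_intervals,
    percent_time_present,
    quantize_time,
    validate_template,
)
from neopain.errors import (
    DegenerateIntervalError,
    NegativeTimeError,
    PhaseStartError,
    UnknownIndicatorError,
    UnknownPhaseError,
)

EXPERT_STARTS = PhaseStartSet(
    {"baseline1": 0.0, "baseline2": 60.0, "stick": 120.0, "recovery": 240.0}
)


def sampling_oracle(intervals, window=None, step_ms=1):
    """Union length of half-open intervals by 1 ms midpoint sampling."""
    if window is None:
        if not intervals:
            return 0.0
        window = (min(a for a, _ in intervals), max(b for _, b in intervals))
    lo, hi = window
    n = int(round((hi - lo) * 1000 / step_ms))
    if n <= 0:
        return 0.0
    t = lo + (np.arange(n) + 0.5) * (step_ms / 1000.0)
    member = np.zeros(n, dtype=bool)
    for a, b in intervals:
        member |= (t >= a) & (t < b)
    return member.sum() * step_ms / 1000.0


class TestQuantize:
    @pytest.mark.parametrize(
        "raw, expected",
        [(1.2, 1.2), (1.31, 1.4), (1.3, 1.4), (0.0, 0.0), (0.09, 0.0)],
    )
    def test_examples(self, raw, expected):
        assert quantize_time(raw) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(NegativeTimeError):
            quantize_time(-0.1)

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(0, 1e4, allow_nan=False))
    def test_moves_at_most_half_quantum_and_lands_on_grid(self, t):
        q = quantize_time(t)
        assert abs(q - t) <= 0.1 + 1e-9
        assert round(q * 5) == pytest.approx(q * 5, abs=1e-6)


grid_intervals = st.lists(
    st.tuples(st.integers(0, 400), st.integers(1, 100)).map(
        lambda ab: (ab[0] / 5, (ab[0] + ab[1]) / 5)
    ),
    max_size=12,
)


class TestMergeIntervals:
    @pytest.mark.parametrize(
        "raw, merged",
        [
            ([(0.0, 5.0), (3.0, 8.0)], [(0.0, 8.0)]),
            ([(0.0, 2.0), (4.0, 6.0)], [(0.0, 2.0), (4.0, 6.0)]),
            ([], []),
            ([(0.0, 2.0), (2.0, 4.0)], [(0.0, 4.0)]),  # adjacency coalesces
        ],
    )
    def test_examples(self, raw, merged):
        assert merge_intervals(raw) == merged

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateIntervalError):
            merge_intervals([(2.0, 2.0)])

    @settings(derandomize=True, max_examples=200)
    @given(grid_intervals)
    def test_idempotent_and_matches_oracle(self, raw):
        merged = merge_intervals(raw)
        assert merge_intervals(merged) == merged
        # disjoint and sorted
        for (a1, b1), (a2, b2) in zip(merged, merged[1:]):
            assert b1 < a2
        total = sum(b - a for a, b in merged)
        assert total == pytest.approx(sampling_oracle(raw), abs=1e-9)


class TestClip:
    @pytest.mark.parametrize(
        "iv, epoch, expected",
        [
            ((25.0, 35.0), (0.0, 30.0), (25.0, 30.0)),
            ((5.0, 10.0), (0.0, 30.0), (5.0, 10.0)),
            ((40.0, 50.0), (0.0, 30.0), None),
            ((0.0, 30.0), (30.0, 60.0), None),  # half-open boundary
        ],
    )
    def test_examples(self, iv, epoch, expected):
        assert clip_interval_to_epoch(iv, epoch) == expected


class TestPercentTimePresent:
    def test_ten_of_thirty_seconds(self):
        ev = [HoldEvent("brow_bulge", "stick", 2.0, 12.0)]
        r = percent_time_present(ev, (0.0, 30.0), "brow_bulge")
        assert r.seconds_present == 10.0
        assert r.fraction_present == pytest.approx(1 / 3)

    def test_no_events_zero(self):
        r = percent_time_present([], (0.0, 30.0), "brow_bulge")
        assert (r.seconds_present, r.fraction_present) == (0.0, 0.0)

    def test_full_epoch_saturates(self):
        ev = [HoldEvent("brow_bulge", "stick", 0.0, 30.0)]
        r = percent_time_present(ev, (0.0, 30.0), "brow_bulge")
        assert (r.seconds_present, r.fraction_present) == (30.0, 1.0)

    def test_overlapping_holds_union_not_sum(self):
        ev = [
            HoldEvent("brow_bulge", "stick", 0.0, 10.0),
            HoldEvent("brow_bulge", "stick", 5.0, 15.0),
        ]
        r = percent_time_present(ev, (0.0, 30.0), "brow_bulge")
        assert r.seconds_present == 15.0

    def test_unknown_indicator_rejected(self):
        with pytest.raises(UnknownIndicatorError):
            percent_time_present(
                [], (0.0, 30.0), "smile",
                measure_indicators=("brow_bulge",),
            )


class TestComputeEpochResults:
    def test_empty_log_zero_fills_all_36_passes(self, expert):
        res = compute_epoch_results([], expert, EXPERT_STARTS)
        assert len(res) == 36
        assert all(r.seconds_present == 0.0 for r in res)

    def test_saturated_log_all_fractions_one(self, expert):
        events = [
            HoldEvent(ind, p.name, s, s + p.duration_s)
            for p, s in zip(expert.phases, [0.0, 60.0, 120.0, 240.0])
            for ind in expert.measure.behavioral_indicators
        ]
        res = compute_epoch_results(events, expert, EXPERT_STARTS)
        assert all(r.fraction_present == 1.0 for r in res)

    def test_boundary_spanning_hold_split_conserves_duration(self, expert):
        # stick starts at 120; hold spans epochs 0/1 boundary at 150
        ev = [HoldEvent("eye_squeeze", "stick", 144.0, 156.0)]
        res = compute_epoch_results(ev, expert, EXPERT_STARTS)
        by_key = {
            (r.phase, r.epoch_index): r.seconds_present
            for r in res
            if r.indicator == "eye_squeeze" and r.phase == "stick"
        }
        assert by_key[("stick", 0)] == 6.0
        assert by_key[("stick", 1)] == 6.0
        assert sum(by_key.values()) == 12.0

    def test_outside_event_dropped_with_warning(self, expert, caplog):
        ev = [HoldEvent("brow_bulge", "stick", 500.0, 510.0)]
        with caplog.at_level("WARNING", logger="neopain.events"):
            res = compute_epoch_results(ev, expert, EXPERT_STARTS)
        assert all(r.seconds_present == 0.0 for r in res)
        assert any("outside scheduled epochs" in m for m in caplog.messages)

    def test_unknown_phase_is_error(self, expert):
        ev = [HoldEvent("brow_bulge", "swaddle", 0.0, 1.0)]
        with pytest.raises(UnknownPhaseError):
            compute_epoch_results(ev, expert, EXPERT_STARTS)

    def test_overlapping_phase_starts_rejected(self, expert):
        bad = PhaseStartSet(
            {"baseline1": 0.0, "baseline2": 30.0, "stick": 120.0, "recovery": 240.0}
        )
        with pytest.raises(PhaseStartError):
            compute_epoch_results([], expert, bad)

    def test_missing_phase_start_rejected(self, expert):
        with pytest.raises(PhaseStartError):
            compute_epoch_results([], expert, PhaseStartSet({"stick": 0.0}))


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.tuples(st.integers(0, 595), st.integers(1, 80)).map(
            lambda ab: (ab[0] / 5, min(120.0, (ab[0] + ab[1]) / 5))
        ),
        max_size=8,
    )
)
def test_conservation_across_epoch_splits(intervals):
    """Presence summed over a phase's epochs equals the merged-events length
    clipped to the phase span."""
    template = validate_template(
        {
            "template_id": "t",
            "measure": "PIPP",
            "phases": [{"name": "stick", "n_epochs": 4, "epoch_length_s": 30.0}],
        }
    )
    events = [
        HoldEvent("brow_bulge", "stick", a, b) for a, b in intervals if a < b
    ]
    res = compute_epoch_results(
        events, template, PhaseStartSet({"stick": 0.0})
    )
    total = sum(
        r.seconds_present for r in res if r.indicator == "brow_bulge"
    )
    merged = merge_intervals([(ev.start_s, ev.end_s) for ev in events])
    clipped = [
        c for iv in merged if (c := clip_interval_to_epoch(iv, (0.0, 120.0)))
    ]
    assert total == pytest.approx(sum(b - a for a, b in clipped), abs=1e-9)


def test_stored_times_are_on_grid_after_raw_ingest():
    """Raw key timestamps quantize onto the 0.2 s grid on ingest."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        a = float(rng.uniform(0, 100))
        b = a + float(rng.uniform(0.3, 20))
        ev = HoldEvent.from_raw("brow_bulge", "stick", a, b)
        for t in (ev.start_s, ev.end_s):
            assert round(t * 5) == pytest.approx(t * 5, abs=1e-6)
        assert abs(ev.start_s - a) <= 0.1 + 1e-9
        assert abs(ev.end_s - b) <= 0.1 + 1e-9
        dur = ev.end_s - ev.start_s
        assert round(dur * 5) == pytest.approx(dur * 5, abs=1e-6)
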