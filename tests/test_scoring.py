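"""Scoring-table audit, subscore lookups, total composition, session scoring."""
import pytest
from hypothesis import given, settings, strategies as st

from neopain import (
    ContextInfo,
    EpochIndicatorResult,
    EpochPhysioDelta,
    SubscoreSet,
    compose_total,
    default_table,
    facial_subscore,
    ga_subscore,
    hr_subscore,
    score_session,
    spo2_subscore,
    state_subscore,
)
from neopain.errors import (
    MeasureMismatchError,
    NegativeDeltaError,
    ScoringTableError,
    UnknownIndicatorError,
)
from neopain.scoring import NumericBins, parse_table


def subs(bb=0, es=0, nf=0, hr=0, sp=0, ga=0, state=0):
    return SubscoreSet(bb, es, nf, hr, sp, ga, state)


class TestTableAudit:
    def test_default_tables_load_and_cover_seven_indicators(
        self, pipp_table, pipp_r_table
    ):
        for table in (pipp_table, pipp_r_table):
            assert len(table.bins) == 7
        assert not pipp_table.conditional_contextual
        assert pipp_r_table.conditional_contextual

    @pytest.mark.parametrize(
        "edges, scores",
        [
            ((0.0, 0.1, 0.4, 1.0), (0, 1, 2)),            # 3 bins
            ((0.0, 0.4, 0.1, 0.7, 1.0), (0, 1, 2, 3)),    # unordered edges
            ((0.0, 0.1, 0.4, 0.7, 0.9), (0, 1, 2, 3)),    # gap at top
            ((0.0, 0.1, 0.4, 0.7, 1.0), (0, 2, 1, 3)),    # non-monotone
            ((0.0, 0.1, 0.4, 0.7, 1.0), (0, 1, 2, 2)),    # not a permutation
        ],
    )
    def test_structural_defects_rejected(self, edges, scores):
        with pytest.raises(ScoringTableError):
            NumericBins(domain=(0.0, 1.0), edges=edges, scores=scores)

    def test_table_indicator_set_must_match_measure(self, pipp_table):
        doc = {
            "table_id": "bad",
            "measure": "PIPP",
            "indicators": {
                "brow_bulge": {
                    "edges": [0.0, 0.1, 0.4, 0.7, 1.0],
                    "scores": [0, 1, 2, 3],
                }
            },
        }
        with pytest.raises(ScoringTableError):
            parse_table(doc)


class TestSubscores:
    @pytest.mark.parametrize(
        "fraction, expected", [(0.0, 0), (0.3333, 1), (0.5, 2), (1.0, 3)]
    )
    def test_facial_bins(self, pipp_table, fraction, expected):
        assert facial_subscore(fraction, pipp_table, "brow_bulge") == expected

    def test_facial_unknown_indicator(self, pipp_table):
        with pytest.raises(UnknownIndicatorError):
            facial_subscore(0.5, pipp_table, "grimace")

    @pytest.mark.parametrize(
        "delta, expected", [(0.0, 0), (22.0, 2), (1000.0, 3), (None, None)]
    )
    def test_hr_bins(self, pipp_table, delta, expected):
        assert hr_subscore(delta, pipp_table) == expected

    @pytest.mark.parametrize(
        "delta, expected", [(0.0, 0), (7.0, 2), (50.0, 3), (None, None)]
    )
    def test_spo2_bins(self, pipp_table, delta, expected):
        assert spo2_subscore(delta, pipp_table) == expected

    def test_negative_delta_rejected(self, pipp_table):
        with pytest.raises(NegativeDeltaError):
            hr_subscore(-1.0, pipp_table)

    @pytest.mark.parametrize(
        "ga, expected", [(40.0, 0), (33.0, 1), (30.0, 2), (25.0, 3)]
    )
    def test_ga_bins_lower_age_scores_higher(self, pipp_table, ga, expected):
        ctx = ContextInfo(corrected_ga_weeks=ga, behavioral_state="active_awake")
        assert ga_subscore(ctx, pipp_table) == expected

    @pytest.mark.parametrize(
        "state, expected",
        [
            ("active_awake", 0),
            ("quiet_awake", 1),
            ("active_sleep", 2),
            ("quiet_sleep", 3),
        ],
    )
    def test_state_categories(self, pipp_table, state, expected):
        assert state_subscore(state, pipp_table) == expected


class TestComposeTotal:
    def test_pipp_maximum_is_21(self):
        total, _ = compose_total(subs(3, 3, 3, 3, 3, 3, 3), "PIPP")
        assert total == 21

    def test_all_zero_totals_zero(self):
        for measure in ("PIPP", "PIPP-R"):
            total, _ = compose_total(subs(), measure)
            assert total == 0

    def test_pipp_r_conditional_contextual_suppressed(self):
        # no facial/physio response: contextual subscores do not count
        total, _ = compose_total(subs(ga=3, state=2), "PIPP-R")
        assert total == 0

    def test_pipp_r_contextual_added_when_core_positive(self):
        total, _ = compose_total(subs(bb=1, ga=3, state=2), "PIPP-R")
        assert total == 6

    def test_pipp_counts_contextual_unconditionally(self):
        total, _ = compose_total(subs(ga=3, state=2), "PIPP")
        assert total == 5

    def test_missing_core_subscore_makes_total_missing(self):
        total, flags = compose_total(
            SubscoreSet(3, 3, None, 3, 3, 3, 3), "PIPP"
        )
        assert total is None
        assert "missing:nasolabial_furrow" in flags

    def test_pipp_r_zero_core_total_defined_despite_missing_contextual(self):
        total, _ = compose_total(
            SubscoreSet(0, 0, 0, 0, 0, None, None), "PIPP-R"
        )
        assert total == 0

    def test_unknown_measure_rejected(self):
        with pytest.raises(MeasureMismatchError):
            compose_total(subs(), "FLACC")


@settings(derandomize=True, max_examples=200)
@given(
    st.floats(0, 1), st.floats(0, 1),
    st.floats(0, 200), st.floats(0, 200),
    st.sampled_from(["PIPP", "PIPP-R"]),
)
def test_subscores_and_totals_monotone_in_measurements(
    f1, f2, d1, d2, measure
):
    """Increasing any measurement never decreases its subscore or the total."""
    table = default_table(measure)
    lo_f, hi_f = sorted((f1, f2))
    lo_d, hi_d = sorted((d1, d2))
    assert facial_subscore(lo_f, table, "brow_bulge") <= facial_subscore(
        hi_f, table, "brow_bulge"
    )
    assert hr_subscore(lo_d, table) <= hr_subscore(hi_d, table)
    assert spo2_subscore(lo_d, table) <= spo2_subscore(hi_d, table)
    base = dict(es=1, nf=0, hr=1, sp=0, ga=2, state=1)
    t_lo, _ = compose_total(
        subs(bb=facial_subscore(lo_f, table, "brow_bulge"), **base), measure
    )
    t_hi, _ = compose_total(
        subs(bb=facial_subscore(hi_f, table, "brow_bulge"), **base), measure
    )
    assert t_lo <= t_hi


class TestScoreSession:
    @staticmethod
    def _facial(template, fraction):
        return [
            EpochIndicatorResult(p.name, k, ind, fraction * 30.0, fraction)
            for p in template.phases
            for k in range(p.n_epochs)
            for ind in template.measure.behavioral_indicators
        ]

    @staticmethod
    def _deltas(template, hr, sp):
        return [
            EpochPhysioDelta(p.name, k, hr, sp)
            for p in template.scored_phases
            for k in range(p.n_epochs)
        ]

    def test_one_result_per_scored_epoch(self, expert, pipp_table):
        ctx = ContextInfo(33.0, "active_awake")
        results = score_session(
            self._facial(expert, 0.5),
            self._deltas(expert, 10.0, 3.0),
            ctx,
            expert,
            pipp_table,
        )
        assert len(results) == 8  # 4 stick + 4 recovery; baselines excluded
        assert {r.phase for r in results} == {"stick", "recovery"}

    def test_maximal_session_totals_21(self, expert, pipp_table):
        ctx = ContextInfo(25.0, "quiet_sleep")
        results = score_session(
            self._facial(expert, 1.0),
            self._deltas(expert, 100.0, 50.0),
            ctx,
            expert,
            pipp_table,
        )
        assert all(r.total == 21 for r in results)
        for r in results:
            assert all(v == 3 for v in r.subscores.as_dict().values())

    def test_missing_physio_gives_missing_totals(self, expert, pipp_table):
        ctx = ContextInfo(33.0, "active_awake")
        results = score_session(
            self._facial(expert, 0.5), [], ctx, expert, pipp_table
        )
        assert all(r.total is None for r in results)
        assert all(r.subscores.brow_bulge is not None for r in results)
        assert all("no_physio" in r.flags for r in results)

    def test_measure_mismatch_rejected(self, expert, pipp_r_table):
        with pytest.raises(MeasureMismatchError):
            score_session([], [], None, expert, pipp_r_table)
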