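import itertools

import pytest

from pcmckit import pcmc_core as core
from pcmckit.behavior_io import ValidationError

from conftest import make_event, make_session


class TestPercent:
    def test_simple(self):
        assert core.percent(1, 4) == 25.0

    def test_rounding(self):
        assert core.percent(2, 19) == 10.5
        assert core.percent(5, 24) == 20.8

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            core.percent(1, 0)


class TestFirstAffiliationMinute:
    def test_contact_at_75s_is_minute_2(self):
        s = make_session(events=[make_event(t=75.0)])
        assert core.first_affiliation_minute(s, core.OPPONENT_ONLY) == 2

    def test_only_aggression_is_absent(self):
        s = make_session(
            events=[make_event(t=30.0, behavior="aggression_nonphysical", actor="B",
                               recipient="A")]
        )
        assert core.first_affiliation_minute(s, core.OPPONENT_ONLY) is None

    def test_opponent_only_ignores_third_party(self):
        s = make_session(events=[make_event(t=30.0, recipient="C")])
        assert core.first_affiliation_minute(s, core.OPPONENT_ONLY) is None
        assert core.first_affiliation_minute(s, core.ANY_PARTNER) == 1

    def test_boundary_event_at_60s_is_minute_2(self):
        s = make_session(events=[make_event(t=60.0)])
        assert core.first_affiliation_minute(s, core.OPPONENT_ONLY) == 2

    def test_affiliation_toward_focal_counts(self):
        s = make_session(events=[make_event(t=45.0, actor="B", recipient="A",
                                            behavior="groom_give")])
        assert core.first_affiliation_minute(s, core.OPPONENT_ONLY) == 1

    def test_vocal_needs_orientation_and_range(self):
        far = make_session(events=[make_event(t=10.0, behavior="vocalization",
                                              oriented=True, distance=6.0)])
        assert core.first_affiliation_minute(far, core.OPPONENT_ONLY) is None
        near = make_session(events=[make_event(t=10.0, behavior="vocalization",
                                               oriented=True, distance=4.0)])
        assert core.first_affiliation_minute(near, core.OPPONENT_ONLY) == 1
        away = make_session(events=[make_event(t=10.0, behavior="vocalization",
                                               oriented=False, distance=3.0)])
        assert core.first_affiliation_minute(away, core.OPPONENT_ONLY) is None


class TestTimeframeClassification:
    def test_pc_first_minute_attracted(self):
        assert core.classify_pair_at_timeframe(1, None, 1) == "attracted"

    def test_mc_first_minute_dispersed(self):
        assert core.classify_pair_at_timeframe(3, 1, 1) == "dispersed"

    def test_tie_is_neutral(self):
        assert core.classify_pair_at_timeframe(2, 2, 2) == "neutral"

    def test_double_absent_neutral_everywhere(self):
        for t in core.MINUTES:
            assert core.classify_pair_at_timeframe(None, None, t) == "neutral"

    def test_invalid_timeframe(self):
        with pytest.raises(ValueError):
            core.classify_pair_at_timeframe(1, None, 6)

    def test_brute_force_36_cases(self):
        """Per-timeframe labels must partition the pair-level categories over
        all 36 (pc_minute, mc_minute) combinations."""
        domain = [None, 1, 2, 3, 4, 5]
        for pc_m, mc_m in itertools.product(domain, domain):
            overall = core.classify_pair(pc_m, mc_m)
            labels = [core.classify_pair_at_timeframe(pc_m, mc_m, t) for t in core.MINUTES]
            # brute-force expected overall label
            pc_eff = pc_m if pc_m is not None else 99
            mc_eff = mc_m if mc_m is not None else 99
            expected = (
                "attracted" if pc_eff < mc_eff
                else "dispersed" if mc_eff < pc_eff
                else "neutral"
            )
            assert overall == expected
            n_att = labels.count("attracted")
            n_dis = labels.count("dispersed")
            assert n_att <= 1 and n_dis <= 1
            assert not (n_att and n_dis)
            if overall == "attracted":
                assert n_att == 1 and labels[pc_m - 1] == "attracted"
            elif overall == "dispersed":
                assert n_dis == 1 and labels[mc_m - 1] == "dispersed"
            else:
                assert n_att == n_dis == 0


def _cls(subject, overall, pc_m=None, mc_m=None):
    per_tf = tuple(core.classify_pair_at_timeframe(pc_m, mc_m, t) for t in core.MINUTES)
    return core.PairClassification(
        pair_id=f"{subject}-{pc_m}-{mc_m}", subject=subject, role="victim",
        pc_minute=pc_m, mc_minute=mc_m, overall=overall, per_timeframe=per_tf,
    )


class TestSubjectProportions:
    def test_subject_with_two_pairs_excluded(self):
        cs = [_cls("A", "neutral")] * 2 + [_cls("B", "neutral")] * 3
        props = core.subject_proportions(cs)
        assert [p.subject for p in props] == ["B"]

    def test_one_of_three_attracted_at_t1(self):
        cs = [
            _cls("A", "attracted", pc_m=1, mc_m=None),
            _cls("A", "neutral"),
            _cls("A", "neutral"),
        ]
        props = core.subject_proportions(cs)
        assert props[0].attracted_by_timeframe[0] == pytest.approx(1 / 3)
        assert props[0].conciliatory_tendency == pytest.approx(1 / 3)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            assert core.subject_proportions([]) == []

    def test_per_timeframe_sums_match_overall(self, small_dataset):
        _, pairs, _, _ = small_dataset
        props = core.subject_proportions(core.classify_pairs(pairs), min_pairs=1)
        for p in props:
            assert sum(p.attracted_by_timeframe) == pytest.approx(p.attracted_overall)
            assert sum(p.dispersed_by_timeframe) == pytest.approx(p.dispersed_overall)


class TestPooledProportions:
    def test_pooled_fractions(self):
        cs = [
            _cls("A", "attracted", pc_m=1, mc_m=None),
            _cls("B", "dispersed", mc_m=2),
            _cls("B", "neutral"),
            _cls("C", "neutral"),
        ]
        pooled = core.pooled_proportions(cs)
        assert pooled["attracted"][0] == pytest.approx(0.25)
        assert pooled["dispersed"][1] == pytest.approx(0.25)
        assert sum(pooled["attracted"]) == pytest.approx(0.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            core.pooled_proportions([])


class TestConciliatoryTendency:
    def test_all_attracted_is_one(self):
        cs = [_cls("A", "attracted", pc_m=1) for _ in range(3)]
        props = core.subject_proportions(cs)
        assert core.conciliatory_tendency(props) == pytest.approx(1.0)

    def test_balanced_is_zero(self):
        cs = (
            [_cls("A", "attracted", pc_m=1) for _ in range(2)]
            + [_cls("A", "dispersed", mc_m=1) for _ in range(2)]
        )
        props = core.subject_proportions(cs)
        assert core.conciliatory_tendency(props) == pytest.approx(0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            core.conciliatory_tendency([])


class TestVocalGiven:
    def test_oriented_within_range(self):
        s = make_session(events=[make_event(behavior="vocalization", oriented=True,
                                            distance=4.0)])
        assert core.vocal_given(s) is True

    def test_beyond_range(self):
        s = make_session(events=[make_event(behavior="vocalization", oriented=True,
                                            distance=6.0)])
        assert core.vocal_given(s) is False

    def test_not_oriented(self):
        s = make_session(events=[make_event(behavior="vocalization", oriented=False,
                                            distance=3.0)])
        assert core.vocal_given(s) is False

    def test_received_vocal_does_not_count(self):
        s = make_session(events=[make_event(actor="B", recipient="A",
                                            behavior="vocalization",
                                            oriented=True, distance=2.0)])
        assert core.vocal_given(s) is False

    def test_third_party_excluded_in_opponent_scope(self):
        s = make_session(events=[make_event(recipient="C", behavior="vocalization",
                                            oriented=True, distance=2.0)])
        assert core.vocal_given(s, core.OPPONENT_ONLY) is False
        assert core.vocal_given(s, core.ANY_PARTNER) is True


class TestAggressionExposure:
    def _aggr(self, t, actor="B", recipient="A"):
        return make_event(t=t, actor=actor, recipient=recipient,
                          behavior="aggression_nonphysical")

    def test_aggression_after_affiliation(self):
        s = make_session(events=[make_event(t=90.0), self._aggr(100.0)])
        assert core.aggression_exposure(s, 90.0) is True

    def test_first_minute_excluded_without_affiliation(self):
        s = make_session(events=[self._aggr(30.0)])
        assert core.aggression_exposure(s, None) is False

    def test_late_aggression_without_affiliation(self):
        s = make_session(events=[self._aggr(200.0)])
        assert core.aggression_exposure(s, None) is True

    def test_aggression_before_affiliation_not_counted(self):
        s = make_session(events=[self._aggr(50.0), make_event(t=120.0)])
        assert core.aggression_exposure(s, 120.0) is False

    def test_third_party_aggression_not_counted(self):
        s = make_session(events=[self._aggr(200.0, actor="C")])
        assert core.aggression_exposure(s, None) is False

    def test_mc_session_rejected(self):
        s = make_session(kind="MC")
        with pytest.raises(ValueError):
            core.aggression_exposure(s, None)


class TestBehaviorType:
    def test_vocal_only(self):
        s = make_session(events=[make_event(behavior="vocalization", oriented=True,
                                            distance=2.0)])
        assert core.affiliation_behavior_type(s) == "vocal_only"

    def test_vocal_with_contact(self):
        s = make_session(events=[
            make_event(t=10.0, behavior="vocalization", oriented=True, distance=2.0),
            make_event(t=20.0, behavior="contact"),
        ])
        assert core.affiliation_behavior_type(s) == "vocal_with_contact_or_approach"

    def test_contact_only(self):
        s = make_session(events=[make_event(behavior="approach")])
        assert core.affiliation_behavior_type(s) == "contact_or_approach_only"

    def test_no_affiliation(self):
        s = make_session()
        assert core.affiliation_behavior_type(s) is None
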