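import warnings
from datetime import datetime

import pytest

from pcmckit import behavior_io as bio
from pcmckit.behavior_io import (
    AdapterError,
    PCMCPair,
    SchemaError,
    ValidationError,
    pair_pc_mc,
    read_census,
    read_deposited_dataset,
    read_events,
    validate_postponement,
    write_census,
    write_deposited_dataset,
    write_events,
)

from conftest import make_event, make_session


def _write_tables(tmp_path, sessions):
    ev, se = tmp_path / "events.csv", tmp_path / "sessions.csv"
    write_events(sessions, ev, se)
    return ev, se


class TestReadEvents:
    def test_round_trip_two_sessions(self, tmp_path):
        sessions = [
            make_session(
                session_id="s1",
                events=[make_event(session_id="s1", t=75.0),
                        make_event(session_id="s1", t=10.0, behavior="approach")],
            ),
            make_session(
                session_id="s2", kind="MC",
                date_time=datetime(2013, 6, 3, 10, 30),
                events=[make_event(session_id="s2", t=200.0, behavior="vocalization",
                                   oriented=True, distance=3.0)],
            ),
        ]
        ev, se = _write_tables(tmp_path, sessions)
        back = read_events(ev, se)
        assert len(back) == 2
        by_id = {s.session_id: s for s in back}
        # events come back time-sorted
        assert [e.t for e in by_id["s1"].events] == [10.0, 75.0]
        assert by_id["s2"].events[0].distance_m == 3.0
        assert by_id["s2"].events[0].oriented_at_recipient is True
        for s in sessions:
            got = by_id[s.session_id]
            assert got.sorted_copy() == s.sorted_copy()

    def test_out_of_range_time_names_row(self, tmp_path):
        s = make_session(events=[make_event(t=100.0)])
        ev, se = _write_tables(tmp_path, [s])
        text = ev.read_text().replace("100.0", "305")
        ev.write_text(text)
        with pytest.raises(ValidationError, match=r"row 2"):
            read_events(ev, se)

    def test_unknown_behavior_rejected(self, tmp_path):
        s = make_session(events=[make_event(behavior="contact")])
        ev, se = _write_tables(tmp_path, [s])
        ev.write_text(ev.read_text().replace("contact", "cartwheel"))
        with pytest.raises(ValidationError, match="cartwheel"):
            read_events(ev, se)

    def test_missing_column_is_schema_error(self, tmp_path):
        s = make_session(events=[make_event()])
        ev, se = _write_tables(tmp_path, [s])
        lines = ev.read_text().splitlines()
        lines[0] = lines[0].replace("behavior", "behaviour")
        ev.write_text("\n".join(lines))
        with pytest.raises(SchemaError, match="behavior"):
            read_events(ev, se)

    def test_empty_file_with_header_warns(self, tmp_path):
        ev, se = _write_tables(tmp_path, [])
        with pytest.warns(UserWarning, match="empty"):
            assert read_events(ev, se) == []

    def test_vocal_row_requires_distance(self, tmp_path):
        with pytest.raises(ValidationError, match="distance"):
            make_event(behavior="vocalization", oriented=True, distance=None).validate()

    def test_tsv_dialect(self, tmp_path):
        sessions = [make_session(events=[make_event()])]
        ev, se = tmp_path / "e.tsv", tmp_path / "s.tsv"
        write_events(sessions, ev, se, dialect="tsv")
        assert "\t" in ev.read_text().splitlines()[0]
        back = read_events(ev, se, dialect="tsv")
        assert back[0].sorted_copy() == sessions[0].sorted_copy()


class TestPairing:
    def _pc(self, **kw):
        kw.setdefault("session_id", "pc1")
        kw.setdefault("date_time", datetime(2013, 6, 1, 10, 0))
        return make_session(kind="PC", **kw)

    def _mc(self, **kw):
        kw.setdefault("session_id", "mc1")
        return make_session(kind="MC", **kw)

    def test_valid_pair_two_days_later(self):
        pc = self._pc()
        mc = self._mc(date_time=datetime(2013, 6, 3, 10, 30))
        pairs, unmatched = pair_pc_mc([pc, mc])
        assert len(pairs) == 1 and not unmatched
        assert pairs[0].pc is pc and pairs[0].mc is mc

    def test_beyond_two_weeks_unmatched(self):
        pc = self._pc()
        mc = self._mc(date_time=datetime(2013, 6, 21, 10, 0))
        pairs, unmatched = pair_pc_mc([pc, mc])
        assert not pairs and unmatched == [pc, mc]

    def test_beyond_two_hours_unmatched(self):
        pc = self._pc()
        mc = self._mc(date_time=datetime(2013, 6, 4, 14, 30))
        pairs, unmatched = pair_pc_mc([pc, mc])
        assert not pairs and len(unmatched) == 2

    def test_mc_earlier_than_pc_unmatched(self):
        pc = self._pc()
        mc = self._mc(date_time=datetime(2013, 5, 30, 10, 0))
        pairs, unmatched = pair_pc_mc([pc, mc])
        assert not pairs and len(unmatched) == 2

    def test_duplicate_candidates_pick_earliest(self, caplog):
        pc = self._pc()
        mc_late = self._mc(session_id="mcB", date_time=datetime(2013, 6, 5, 10, 0))
        mc_early = self._mc(session_id="mcA", date_time=datetime(2013, 6, 2, 10, 0))
        with caplog.at_level("WARNING", logger="pcmckit.behavior_io"):
            pairs, unmatched = pair_pc_mc([pc, mc_late, mc_early])
        assert pairs[0].mc is mc_early
        assert [s.session_id for s in unmatched] == ["mcB"]
        assert any("eligible MCs" in r.message for r in caplog.records)

    def test_stable_under_permutation(self):
        sessions = []
        for i in range(6):
            sessions.append(
                self._pc(session_id=f"pc{i}", date_time=datetime(2013, 6, 1 + i, 10, 0))
            )
            sessions.append(
                self._mc(session_id=f"mc{i}", date_time=datetime(2013, 6, 3 + i, 10, 15))
            )
        ref = {(p.pc.session_id, p.mc.session_id) for p in pair_pc_mc(sessions)[0]}
        for shift in (1, 3, 5):
            perm = sessions[shift:] + sessions[:shift]
            got = {(p.pc.session_id, p.mc.session_id) for p in pair_pc_mc(perm)[0]}
            assert got == ref

    def test_partition_every_session_once(self):
        sessions = [
            self._pc(session_id="pc1"),
            self._mc(session_id="mc1", date_time=datetime(2013, 6, 2, 10, 0)),
            self._pc(session_id="pc2", focal="C", opponent="D"),
        ]
        pairs, unmatched = pair_pc_mc(sessions)
        seen = [s.session_id for p in pairs for s in (p.pc, p.mc)]
        seen += [s.session_id for s in unmatched]
        assert sorted(seen) == sorted(s.session_id for s in sessions)

    def test_conflict_attributes_must_match(self):
        pc = self._pc(conflict_physical=True)
        mc = self._mc(date_time=datetime(2013, 6, 3, 10, 0), conflict_physical=False)
        pairs, unmatched = pair_pc_mc([pc, mc])
        assert not pairs


class TestPostponement:
    def test_renewed_at_20s_postpones(self):
        assert validate_postponement(100.0, [120.0]) is False

    def test_renewed_at_45s_ok(self):
        assert validate_postponement(100.0, [145.0]) is True

    def test_no_renewed_ok(self):
        assert validate_postponement(100.0, []) is True

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            validate_postponement(-1.0, [])


class TestPairInvariants:
    def test_pair_validation_rejects_focal_mismatch(self):
        pc = make_session(session_id="pc", kind="PC")
        mc = make_session(
            session_id="mc", kind="MC", focal="Z",
            date_time=datetime(2013, 6, 3, 10, 0),
        )
        with pytest.raises(ValidationError, match="focal"):
            PCMCPair(pair_id="x", pc=pc, mc=mc).validate()


class TestXlsxAdapter:
    def test_round_trip(self, tmp_path, small_dataset):
        _, pairs, census, _ = small_dataset
        path = tmp_path / "dataset.xlsx"
        write_deposited_dataset(pairs[:10], path, census=census[:20])
        back_pairs, back_census = read_deposited_dataset(path)
        assert len(back_pairs) == 10
        for orig, got in zip(pairs[:10], back_pairs):
            assert got.pair_id == orig.pair_id
            assert got.pc.sorted_copy() == orig.pc.sorted_copy()
            assert got.mc.sorted_copy() == orig.mc.sorted_copy()
        assert back_census == census[:20]

    def test_renamed_column_is_adapter_error(self, tmp_path, small_dataset):
        import openpyxl

        _, pairs, _, _ = small_dataset
        path = tmp_path / "dataset.xlsx"
        write_deposited_dataset(pairs[:3], path)
        wb = openpyxl.load_workbook(path)
        ws = wb["sessions"]
        for cell in ws[1]:
            if cell.value == "focal":
                cell.value = "subject_name"
        wb.save(path)
        with pytest.raises(AdapterError, match="focal"):
            read_deposited_dataset(path)

    def test_missing_sheet_is_adapter_error(self, tmp_path, small_dataset):
        import openpyxl

        _, pairs, _, _ = small_dataset
        path = tmp_path / "dataset.xlsx"
        write_deposited_dataset(pairs[:3], path)
        wb = openpyxl.load_workbook(path)
        del wb["census"]
        wb.save(path)
        with pytest.raises(AdapterError, match="census"):
            read_deposited_dataset(path)


class TestCensusIO:
    def test_round_trip(self, tmp_path, small_dataset):
        _, _, census, _ = small_dataset
        path = tmp_path / "census.csv"
        write_census(census, path)
        assert read_census(path) == census

    def test_social_requires_partners(self):
        from datetime import date

        from pcmckit.behavior_io import CensusRecord

        rec = CensusRecord(
            census_id="c1", date=date(2013, 6, 1), female="A",
            state="social", partners=frozenset(),
        )
        with pytest.raises(ValidationError, match="partners"):
            rec.validate()
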