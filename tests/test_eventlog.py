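"""Data structuration: parsing, spell resolution, trace building."""
import datetime as dt
import io

import pytest

from bowtiepm.eventlog import (
    HospitalSpell,
    IndexSpec,
    SchemaConfig,
    SpellIntegrityError,
    build_traces,
    parse_episodes,
    read_log,
    resolve_spells,
    write_log,
)
from bowtiepm.mapping import UNMAPPED
from bowtiepm.synth import ArtifactRates, generate_cohort, sepsis_demo_spec

from conftest import records_to_log

HEADER = "patient_id,spell_id,episode_start,episode_end,los_days,setting,admission_method,age,diag_01,diag_02\n"


def parse(rows: str, schema: SchemaConfig | None = None):
    return parse_episodes(io.StringIO(HEADER + rows), schema)


class TestParseEpisodes:
    def test_blank_fields_stay_blank(self):
        result = parse("p1,s1,2016-03-01,,,outpatient,,45,M54.5,\n")
        (ep,) = result.episodes
        assert ep.end_date is None and ep.los_days is None
        assert ep.setting == "outpatient"
        assert ep.diagnoses == ("M54.5",)

    def test_empty_file_with_header_gives_empty_list(self):
        result = parse("")
        assert result.episodes == [] and result.errors == []

    def test_date_dialect_normalization(self):
        schema = SchemaConfig(date_format="%d/%m/%Y")
        result = parse("p1,s1,01/03/2016,05/03/2016,4,inpatient,21,45,J18.9,\n", schema)
        (ep,) = result.episodes
        assert ep.start_date == dt.date(2016, 3, 1)
        assert ep.end_date == dt.date(2016, 3, 5)

    def test_bad_rows_reported_with_row_numbers(self):
        result = parse(
            "p1,s1,2016-03-01,,2,inpatient,21,45,J18.9,\n"
            "p2,s2,not-a-date,,,inpatient,21,50,J18.9,\n"
            "p3,s3,2016-05-01,,,inpatient,21,50,,\n"
        )
        assert len(result.episodes) == 1
        assert [row for row, _ in result.errors] == [2, 3]

    def test_missing_mandatory_column_is_fatal(self):
        with pytest.raises(ValueError, match="patient_id"):
            parse_episodes(io.StringIO("spell_id,episode_start,diag_01\ns1,2016-01-01,A41.9\n"))


class TestResolveSpells:
    def test_day_care_flag_requires_both_fields_blank(self):
        result = parse(
            "p1,s1,2016-03-01,,,inpatient,21,45,J18.9,\n"
            "p1,s2,2016-04-01,2016-04-03,2,inpatient,21,45,J18.9,\n"
        )
        spells, removed = resolve_spells(result.episodes)
        assert removed == 0
        flags = {s.spell_id: s.day_care for s in spells}
        assert flags == {"s1": True, "s2": False}

    def test_orphaned_episodes_removed_and_counted(self):
        rows = "".join(
            f"p{i},{'s%d' % i if i not in (3, 7) else ''},2016-0{i % 9 + 1}-01,,1,inpatient,21,45,J18.9,\n"
            for i in range(1, 11)
        )
        spells, removed = resolve_spells(parse(rows).episodes)
        assert removed == 2
        assert len(spells) == 8

    def test_first_episode_primary_diagnosis_retained(self):
        result = parse(
            "p1,s1,2016-03-01,2016-03-05,4,inpatient,21,45,J18.9,N39.0\n"
            "p1,s1,2016-03-01,2016-03-05,4,inpatient,,45,N39.0,\n"
        )
        spells, _ = resolve_spells(result.episodes)
        (spell,) = spells
        assert spell.primary_diagnosis == "J18.9"
        assert spell.admission_date == dt.date(2016, 3, 1)

    def test_spell_shared_across_patients_is_integrity_error(self):
        result = parse(
            "p1,shared,2016-03-01,,1,inpatient,21,45,J18.9,\n"
            "p2,shared,2016-04-01,,1,inpatient,21,50,N39.0,\n"
        )
        with pytest.raises(SpellIntegrityError):
            resolve_spells(result.episodes)


def spell(pid, sid, date, diagnosis, age=50):
    return HospitalSpell(
        patient_id=pid,
        spell_id=sid,
        admission_date=date,
        discharge_date=None,
        day_care=False,
        primary_diagnosis=diagnosis,
        age=age,
    )


class TestBuildTraces:
    def test_first_index_admission_anchors_the_trace(self, mapping):
        spells = [
            spell("p1", "a", dt.date(2016, 3, 1), "A41.9"),
            spell("p1", "b", dt.date(2016, 7, 1), "A40.1"),
        ]
        log = build_traces(spells, mapping)
        (trace,) = log.traces
        assert trace.index_date == dt.date(2016, 3, 1)
        # The later sepsis admission is an ordinary post-index event.
        assert trace.classes("post") == ["Septicemia"]
        assert log.index_class == "Septicemia"

    def test_window_boundaries_inclusive_at_730_and_365(self, mapping):
        index_date = dt.date(2016, 6, 15)
        spells = [
            spell("p1", "idx", index_date, "A41.9"),
            spell("p1", "a", index_date - dt.timedelta(days=731), "J18.9"),
            spell("p1", "b", index_date - dt.timedelta(days=730), "N39.0"),
            spell("p1", "c", index_date + dt.timedelta(days=365), "J18.9"),
            spell("p1", "d", index_date + dt.timedelta(days=366), "N39.0"),
        ]
        log = build_traces(spells, mapping)
        (trace,) = log.traces
        assert trace.classes("pre") == ["Urinary tract infections (UTI)"]
        assert [e.offset_days for e in trace.pre_events] == [-730]
        assert trace.classes("post") == ["Pneumonia"]
        assert [e.offset_days for e in trace.post_events] == [365]

    def test_age_filter_is_strictly_greater_than_13(self, mapping):
        spells = [
            spell("p13", "a", dt.date(2016, 3, 1), "A41.9", age=13),
            spell("p14", "b", dt.date(2016, 4, 1), "A41.9", age=14),
        ]
        log = build_traces(spells, mapping)
        assert [t.patient_id for t in log.traces] == ["p14"]
        assert log.manifest["exclusions"]["age_not_above_minimum"] == 1

    def test_patient_without_index_event_excluded_with_reason(self, mapping):
        log = build_traces([spell("p1", "a", dt.date(2016, 3, 1), "J18.9")], mapping)
        assert log.traces == []
        assert log.manifest["exclusions"]["no_index_event"] == 1

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            IndexSpec(pre_window_days=-1)

    def test_unmapped_codes_fall_to_sentinel_class(self, mapping):
        spells = [
            spell("p1", "idx", dt.date(2016, 3, 1), "A41.9"),
            spell("p1", "a", dt.date(2016, 1, 1), "ZZ99"),
        ]
        log = build_traces(spells, mapping)
        assert log.traces[0].classes("pre") == [UNMAPPED]


class TestRoundTrip:
    def test_clean_cohort_reproduces_generated_sequences(self):
        spec = sepsis_demo_spec(n_patients=40, noise_rate=0.0, artifact_rates=ArtifactRates())
        spec = spec.model_copy(update={"underage_fraction": 0.0})
        records, truth = generate_cohort(spec, seed=13)
        log = records_to_log(records)
        assert len(log.traces) == spec.n_patients
        for trace in log.traces:
            path = truth.per_patient_paths[trace.patient_id]
            assert trace.classes("pre") == list(path.pre)
            assert trace.classes("post") == list(path.post)

    def test_spell_collapse_conserves_coded_events(self):
        spec = sepsis_demo_spec(n_patients=30, noise_rate=0.0, artifact_rates=ArtifactRates())
        spec = spec.model_copy(update={"underage_fraction": 0.0})
        records, _ = generate_cohort(spec, seed=21)
        parsed = parse_episodes(io.StringIO(records.to_csv(index=False)))
        spells, removed = resolve_spells(parsed.episodes)
        assert removed == 0
        log = records_to_log(records)
        assert log.manifest["coded_events"] == len(spells)

    def test_canonical_csv_round_trip(self, tmp_path, demo_log):
        path = tmp_path / "log.csv"
        write_log(demo_log, path, tmp_path / "manifest.json")
        back = read_log(path)
        assert back.index_class == demo_log.index_class
        assert len(back.traces) == len(demo_log.traces)
        original = {t.patient_id: (t.classes("pre"), t.classes("post")) for t in demo_log.traces}
        for trace in back.traces:
            assert (trace.classes("pre"), trace.classes("post")) == original[trace.patient_id]
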