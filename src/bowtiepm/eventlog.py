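"""Structuring raw hospital-episode records into an index-aligned event log.

The pipeline mirrors how national hospital activity extracts (such as
England's Hospital Episode Statistics) are prepared for process mining:

1. :func:`parse_episodes` — read a delimited flat file of episodes,
   normalize timestamps to day granularity and keep missing fields blank so
   inpatient and outpatient activity live in one table.
2. :func:`resolve_spells` — collapse the episodes of each continuous
   hospital stay (spell) into a single record carrying the primary
   diagnosis of its first episode; stays with neither discharge date nor
   length of stay are flagged as day care; episodes with no spell linkage
   are dropped and counted.
3. :func:`build_traces` — anchor each patient on their first index
   admission (by default a sepsis admission, ICD-10 ``A40``/``A41`` and
   derivatives, in the study year), apply the age filter, map primary
   diagnoses to meta-code event classes and keep coded events dated within
   the look-back / follow-up windows (default 730 days before to 365 days
   after), producing one time-ordered trace per patient.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .mapping import ClassMapping, load_default_mapping

__all__ = [
    "RawEpisode",
    "HospitalSpell",
    "CodedEvent",
    "PatientTrace",
    "EventLog",
    "SchemaConfig",
    "IndexSpec",
    "ParseResult",
    "SpellIntegrityError",
    "parse_episodes",
    "resolve_spells",
    "build_traces",
    "write_log",
    "read_log",
]

Side = Literal["pre", "post"]


class SpellIntegrityError(ValueError):
    """A spell identifier is shared by episodes of different patients."""


class SchemaConfig(BaseModel):
    """Column map and dialect for a delimited episode extract."""

    patient_id: str = "patient_id"
    spell_id: str = "spell_id"
    start_date: str = "episode_start"
    end_date: str = "episode_end"
    los_days: str = "los_days"
    setting: str = "setting"
    admission_method: str = "admission_method"
    age: str = "age"
    diagnosis_columns: list[str] = Field(default_factory=lambda: ["diag_01", "diag_02", "diag_03"])
    date_format: str = "%Y-%m-%d"
    drop_columns: list[str] = Field(default_factory=list)
    delimiter: str = ","


@dataclass(frozen=True)
class RawEpisode:
    """One consultant episode as read from the source extract."""

    patient_id: str
    spell_id: str
    start_date: dt.date
    end_date: Optional[dt.date]
    los_days: Optional[int]
    setting: str  # "inpatient" | "outpatient"
    diagnoses: tuple[str, ...]  # position 1 = primary
    admission_method: str = ""
    age: Optional[int] = None
    source_row: int = -1  # 1-based data row in the input, for diagnostics


@dataclass(frozen=True)
class HospitalSpell:
    """A continuous hospital stay, collapsed to one diagnostic event."""

    patient_id: str
    spell_id: str
    admission_date: dt.date
    discharge_date: Optional[dt.date]
    day_care: bool
    primary_diagnosis: str
    setting: str = "inpatient"
    age: Optional[int] = None
    source_order: int = 0  # input order of the first episode, for tie-breaks


@dataclass(frozen=True)
class CodedEvent:
    patient_id: str
    event_class: str
    event_date: Optional[dt.date]
    offset_days: int


@dataclass(frozen=True)
class PatientTrace:
    """A patient's coded events aligned on the index admission date."""

    patient_id: str
    age_at_index: Optional[int]
    index_date: Optional[dt.date]
    pre_events: tuple[CodedEvent, ...]
    post_events: tuple[CodedEvent, ...]

    def side(self, side: Side) -> tuple[CodedEvent, ...]:
        return self.pre_events if side == "pre" else self.post_events

    def classes(self, side: Side) -> list[str]:
        return [e.event_class for e in self.side(side)]


@dataclass
class EventLog:
    """The process-mining input: one trace per patient plus bookkeeping."""

    traces: list[PatientTrace]
    index_class: str
    class_universe: set[str] = field(default_factory=set)
    manifest: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.class_universe:
            universe = {self.index_class}
            for t in self.traces:
                universe.update(t.classes("pre"))
                universe.update(t.classes("post"))
            self.class_universe = universe

    def __len__(self) -> int:
        return len(self.traces)

    def sequences(self, side: Side) -> list[list[str]]:
        return [t.classes(side) for t in self.traces]


@dataclass
class ParseResult:
    episodes: list[RawEpisode]
    errors: list[tuple[int, str]]  # (1-based data row, message)


class IndexSpec(BaseModel):
    """Cohort definition around the index admission."""

    index_prefixes: tuple[str, ...] = ("A40", "A41")
    study_start: dt.date = dt.date(2016, 1, 1)
    study_end: dt.date = dt.date(2016, 12, 31)
    pre_window_days: int = Field(default=730, ge=0)
    post_window_days: int = Field(default=365, ge=0)
    min_age: int = 13  # strictly-greater filter: age must exceed this
    on_unmapped: str = "sentinel"

    @field_validator("index_prefixes")
    @classmethod
    def _nonempty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("index_prefixes must not be empty")
        return v


def _parse_date(text: str, fmt: str) -> Optional[dt.date]:
    text = text.strip()
    if not text:
        return None
    return dt.datetime.strptime(text, fmt).date()


def parse_episodes(source, schema: SchemaConfig | None = None) -> ParseResult:
    """Read a delimited episode extract into :class:`RawEpisode` records.

    Rows whose mandatory fields fail to parse (bad dates, inpatient rows
    with no diagnosis) are skipped and reported with their row number;
    a missing mandatory column raises immediately.
    """
    schema = schema or SchemaConfig()
    df = pd.read_csv(source, dtype=str, sep=schema.delimiter, keep_default_na=False)
    for col in schema.drop_columns:
        if col in df.columns:
            df = df.drop(columns=col)
    for col in (schema.patient_id, schema.start_date):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    diag_cols = [c for c in schema.diagnosis_columns if c in df.columns]
    if not diag_cols:
        raise ValueError("no diagnosis columns present")

    episodes: list[RawEpisode] = []
    errors: list[tuple[int, str]] = []
    have = df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(have, row))
        setting = rec.get(schema.setting, "").strip().lower() or "inpatient"
        try:
            start = _parse_date(rec[schema.start_date], schema.date_format)
            if start is None:
                raise ValueError("blank start date")
            end = _parse_date(rec.get(schema.end_date, ""), schema.date_format)
        except ValueError as exc:
            errors.append((i, f"unparseable date: {exc}"))
            continue
        los_text = rec.get(schema.los_days, "").strip()
        los = None
        if los_text:
            try:
                los = int(los_text)
                if los < 0:
                    raise ValueError
            except ValueError:
                errors.append((i, f"bad length of stay {los_text!r}"))
                continue
        diagnoses = tuple(d for d in (rec.get(c, "").strip() for c in diag_cols) if d)
        if setting == "inpatient" and not diagnoses:
            errors.append((i, "inpatient episode with no diagnosis"))
            continue
        age_text = rec.get(schema.age, "").strip()
        age = int(age_text) if age_text else None
        episodes.append(
            RawEpisode(
                patient_id=rec[schema.patient_id].strip(),
                spell_id=rec.get(schema.spell_id, "").strip(),
                start_date=start,
                end_date=end,
                los_days=los,
                setting=setting,
                diagnoses=diagnoses,
                admission_method=rec.get(schema.admission_method, "").strip(),
                age=age,
                source_row=i,
            )
        )
    return ParseResult(episodes=episodes, errors=errors)


def resolve_spells(episodes: Sequence[RawEpisode]) -> tuple[list[HospitalSpell], int]:
    """Collapse episodes into hospital spells.

    Episodes with no spell linkage are removed (their count is returned).
    Within a spell the primary diagnosis of the first episode is retained;
    other diagnoses made during the same stay are discarded.  Stays with
    neither a discharge date nor a length of stay are labeled day care.
    """
    owner: dict[str, str] = {}
    for ep in episodes:
        if not ep.spell_id:
            continue
        prev = owner.setdefault(ep.spell_id, ep.patient_id)
        if prev != ep.patient_id:
            raise SpellIntegrityError(
                f"spell {ep.spell_id!r} spans patients {prev!r} and {ep.patient_id!r}"
            )

    removed = sum(1 for ep in episodes if not ep.spell_id)
    groups: dict[tuple[str, str], list[tuple[int, RawEpisode]]] = {}
    for order, ep in enumerate(episodes):
        if not ep.spell_id:
            continue
        groups.setdefault((ep.patient_id, ep.spell_id), []).append((order, ep))

    spells: list[HospitalSpell] = []
    for (pid, sid), members in groups.items():
        members.sort(key=lambda pair: (pair[1].start_date, pair[0]))
        first_order, first = members[0]
        admission = first.start_date
        ends = [ep.end_date for _, ep in members if ep.end_date is not None]
        discharge = max(ends) if ends else None
        if discharge is not None and discharge < admission:
            discharge = None  # defensively treat impossible discharges as missing
        day_care = all(ep.end_date is None and ep.los_days is None for _, ep in members)
        spells.append(
            HospitalSpell(
                patient_id=pid,
                spell_id=sid,
                admission_date=admission,
                discharge_date=discharge,
                day_care=day_care,
                primary_diagnosis=first.diagnoses[0] if first.diagnoses else "",
                setting=first.setting,
                age=first.age,
                source_order=first_order,
            )
        )
    spells.sort(key=lambda s: (s.patient_id, s.admission_date, s.source_order))
    return spells, removed


def _matches_prefix(code: str, prefixes: Iterable[str]) -> bool:
    from .mapping import normalize_code

    norm = normalize_code(code)
    return any(norm.startswith(normalize_code(p)) for p in prefixes)


def build_traces(
    spells: Sequence[HospitalSpell],
    mapping: ClassMapping | None = None,
    index_spec: IndexSpec | None = None,
) -> EventLog:
    """Build index-aligned, windowed patient traces from resolved spells.

    Per patient, the index is the earliest spell inside the study period
    whose primary diagnosis matches an index prefix.  Patients whose age at
    index does not exceed ``min_age`` (or with no index spell) are excluded
    with counted reasons.  Every other spell becomes one coded event, kept
    iff its day offset falls in ``[-pre_window, -1]`` or
    ``[+1, +post_window]``; later index-matching admissions are kept as
    ordinary post-index events.
    """
    mapping = mapping or load_default_mapping()
    spec = index_spec or IndexSpec()

    by_patient: dict[str, list[HospitalSpell]] = {}
    for sp in spells:
        by_patient.setdefault(sp.patient_id, []).append(sp)

    exclusions = {"no_index_event": 0, "age_not_above_minimum": 0, "missing_age": 0}
    traces: list[PatientTrace] = []
    index_class = mapping.lookup(spec.index_prefixes[0], on_unmapped="sentinel")

    for pid in sorted(by_patient):
        patient_spells = sorted(by_patient[pid], key=lambda s: (s.admission_date, s.source_order))
        candidates = [
            s
            for s in patient_spells
            if spec.study_start <= s.admission_date <= spec.study_end
            and _matches_prefix(s.primary_diagnosis, spec.index_prefixes)
        ]
        if not candidates:
            exclusions["no_index_event"] += 1
            continue
        index_spell = candidates[0]
        if index_spell.age is None:
            exclusions["missing_age"] += 1
            continue
        if index_spell.age <= spec.min_age:
            exclusions["age_not_above_minimum"] += 1
            continue

        pre: list[tuple[int, int, str, CodedEvent]] = []
        post: list[tuple[int, int, str, CodedEvent]] = []
        for seq, sp in enumerate(patient_spells):
            if sp is index_spell:
                continue
            offset = (sp.admission_date - index_spell.admission_date).days
            label = mapping.lookup(sp.primary_diagnosis, on_unmapped=spec.on_unmapped)
            ev = CodedEvent(pid, label, sp.admission_date, offset)
            if -spec.pre_window_days <= offset <= -1:
                pre.append((offset, seq, label, ev))
            elif 1 <= offset <= spec.post_window_days:
                post.append((offset, seq, label, ev))
        pre.sort(key=lambda t: t[:3])
        post.sort(key=lambda t: t[:3])
        traces.append(
            PatientTrace(
                patient_id=pid,
                age_at_index=index_spell.age,
                index_date=index_spell.admission_date,
                pre_events=tuple(t[3] for t in pre),
                post_events=tuple(t[3] for t in post),
            )
        )

    log = EventLog(traces=traces, index_class=index_class)
    log.manifest = {
        "patients_seen": len(by_patient),
        "patients_kept": len(traces),
        "exclusions": exclusions,
        "coded_events": sum(len(t.pre_events) + len(t.post_events) + 1 for t in traces),
        "index_class": index_class,
        "windows": {"pre_days": spec.pre_window_days, "post_days": spec.post_window_days},
    }
    return log


# ---------------------------------------------------------------------------
# Canonical on-disk form: CSV of (patient_id, event_class, offset_days, side)
# plus an optional JSON manifest.


def write_log(log: EventLog, path: str | Path, manifest_path: str | Path | None = None) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "event_class", "offset_days", "side"])
        for t in log.traces:
            for ev in t.pre_events:
                w.writerow([t.patient_id, ev.event_class, ev.offset_days, "pre"])
            w.writerow([t.patient_id, log.index_class, 0, "index"])
            for ev in t.post_events:
                w.writerow([t.patient_id, ev.event_class, ev.offset_days, "post"])
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(log.manifest, indent=2, default=str))


def read_log(path: str | Path) -> EventLog:
    """Rebuild an :class:`EventLog` from the canonical CSV form.

    Calendar dates and ages are not stored in the canonical form, so the
    rebuilt traces carry offsets only.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "event_class": str, "side": str})
    index_classes = df.loc[df["side"] == "index", "event_class"].unique()
    if len(index_classes) != 1:
        raise ValueError(f"expected exactly one index class, found {list(index_classes)}")
    traces = []
    for pid, grp in df.groupby("patient_id", sort=True):
        pre = grp[grp["side"] == "pre"].sort_values("offset_days", kind="stable")
        post = grp[grp["side"] == "post"].sort_values("offset_days", kind="stable")
        traces.append(
            PatientTrace(
                patient_id=str(pid),
                age_at_index=None,
                index_date=None,
                pre_events=tuple(
                    CodedEvent(str(pid), r.event_class, None, int(r.offset_days))
                    for r in pre.itertuples(index=False)
                ),
                post_events=tuple(
                    CodedEvent(str(pid), r.event_class, None, int(r.offset_days))
                    for r in post.itertuples(index=False)
                ),
            )
        )
    return EventLog(traces=traces, index_class=str(index_classes[0]))
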