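"""Synthetic hospital-episode cohorts with a planted bow-tie pathway.

National hospital-activity extracts are not publicly redistributable, so
every downstream stage of this package is exercised on synthetic cohorts
that emulate their statistical shape: per-patient episode records with
spell linkage, inpatient and outpatient settings, day-granularity
timestamps, blank outpatient-only fields, and configurable data artifacts
(stays with no discharge date, episodes orphaned from any stay, duplicate
same-day secondary-diagnosis rows).

Each patient receives exactly one index admission (sepsis by default)
dated inside the study year.  The diagnostic history before the index is a
first-order Markov walk over non-index event classes, optionally finished
by a separate "entry" draw that controls which class immediately precedes
the index admission; the follow-up after the index starts from an "exit"
draw and continues with its own Markov walk.  Transitions whose
probability reaches ``dominance_threshold`` are the *planted* bow-tie
edges that discovery is expected to recover.  Event days are order
statistics of uniform draws inside the look-back / follow-up windows,
without replacement so each admission falls on a distinct day.

Randomness is organized as one stream per patient, derived from
``(seed, patient index)``, so enlarging the cohort never reshuffles the
patients already generated.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .mapping import ClassMapping, load_default_mapping
from .model import BowTieModel, ProcessModel

__all__ = [
    "ArtifactRates",
    "PathwaySpec",
    "GroundTruth",
    "ArtifactCounts",
    "PlantedPath",
    "generate_cohort",
    "inject_artifacts",
    "planted_bowtie",
    "sepsis_demo_spec",
]

EPISODE_COLUMNS = [
    "patient_id",
    "spell_id",
    "episode_start",
    "episode_end",
    "los_days",
    "setting",
    "admission_method",
    "age",
    "diag_01",
    "diag_02",
]


class ArtifactRates(BaseModel):
    """Per-artifact injection probabilities (all in [0, 1])."""

    missing_discharge: float = Field(default=0.0, ge=0.0, le=1.0)
    unlinked_episode: float = Field(default=0.0, ge=0.0, le=1.0)
    duplicate_diagnosis: float = Field(default=0.0, ge=0.0, le=1.0)

    def any_active(self) -> bool:
        return any(v > 0 for v in (self.missing_discharge, self.unlinked_episode, self.duplicate_diagnosis))


class PathwaySpec(BaseModel):
    """Ground-truth description of a synthetic cohort.

    Transition rows are dictionaries keyed by class label; every row must
    sum to one.  ``pre_to_index`` is the distribution of the class of the
    *last* admission before the index (the planted entry edges of the
    bow-tie); ``index_to_post`` likewise governs the first admission after
    the index.  When either is ``None`` the corresponding boundary event is
    simply the end (start) of the Markov walk.
    """

    class_labels: list[str]
    index_class: str = "Septicemia"
    pre_transition: dict[str, dict[str, float]]
    post_transition: dict[str, dict[str, float]]
    pre_start: Optional[dict[str, float]] = None
    pre_to_index: Optional[dict[str, float]] = None
    index_to_post: Optional[dict[str, float]] = None
    planted_pre_edges: Optional[list[tuple[str, str]]] = None
    planted_post_edges: Optional[list[tuple[str, str]]] = None
    dominance_threshold: float = 0.3
    events_per_patient_pre: tuple[int, int] = (2, 8)
    events_per_patient_post: tuple[int, int] = (1, 4)
    noise_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    pre_window_days: int = Field(default=730, ge=1)
    post_window_days: int = Field(default=365, ge=1)
    n_patients: int = Field(gt=0)
    study_year: int = 2016
    index_code: str = "A41.9"
    age_range: tuple[int, int] = (14, 95)
    underage_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    outpatient_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    extra_episode_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    artifact_rates: ArtifactRates = Field(default_factory=ArtifactRates)
    code_map: Optional[dict[str, str]] = None  # class label -> emitted ICD-10 code

    @model_validator(mode="after")
    def _check(self) -> "PathwaySpec":
        if not self.class_labels:
            raise ValueError("class_labels must not be empty")
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("class_labels contains duplicates")
        if self.index_class in self.class_labels:
            raise ValueError("index_class must not appear in class_labels")
        if self.dominance_threshold <= 1.0 / len(self.class_labels):
            raise ValueError("dominance_threshold must exceed 1/len(class_labels)")
        for name, matrix in (("pre_transition", self.pre_transition), ("post_transition", self.post_transition)):
            for row_label in self.class_labels:
                row = matrix.get(row_label)
                if row is None:
                    raise ValueError(f"{name} missing row for class {row_label!r}")
                if set(row) - set(self.class_labels):
                    raise ValueError(f"{name} row {row_label!r} references unknown classes")
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name} row {row_label!r} sums to {total}, expected 1")
        for name, dist in (
            ("pre_start", self.pre_start),
            ("pre_to_index", self.pre_to_index),
            ("index_to_post", self.index_to_post),
        ):
            if dist is None:
                continue
            if set(dist) - set(self.class_labels):
                raise ValueError(f"{name} references unknown classes")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")
        for name, edges in (
            ("planted_pre_edges", self.planted_pre_edges),
            ("planted_post_edges", self.planted_post_edges),
        ):
            if edges is None:
                continue
            known = set(self.class_labels) | {self.index_class}
            for a, b in edges:
                if a not in known or b not in known:
                    raise ValueError(f"{name} references unknown class in ({a!r}, {b!r})")
        for name, rng_ in (
            ("events_per_patient_pre", self.events_per_patient_pre),
            ("events_per_patient_post", self.events_per_patient_post),
        ):
            lo, hi = rng_
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative (low, high) range")
        if self.events_per_patient_pre[1] > self.pre_window_days:
            raise ValueError("events_per_patient_pre exceeds pre_window_days")
        if self.events_per_patient_post[1] > self.post_window_days:
            raise ValueError("events_per_patient_post exceeds post_window_days")
        return self

    # -- planted structure ---------------------------------------------------

    def resolved_planted_pre_edges(self) -> set[tuple[str, str]]:
        """Planted pre edges; derived from dominant transitions if unset."""
        if self.planted_pre_edges is not None:
            return set(map(tuple, self.planted_pre_edges))
        edges = {
            (a, b)
            for a, row in self.pre_transition.items()
            for b, p in row.items()
            if p >= self.dominance_threshold
        }
        if self.pre_to_index:
            edges |= {
                (c, self.index_class)
                for c, p in self.pre_to_index.items()
                if p >= self.dominance_threshold
            }
        return edges

    def resolved_planted_post_edges(self) -> set[tuple[str, str]]:
        if self.planted_post_edges is not None:
            return set(map(tuple, self.planted_post_edges))
        edges = {
            (a, b)
            for a, row in self.post_transition.items()
            for b, p in row.items()
            if p >= self.dominance_threshold
        }
        if self.index_to_post:
            edges |= {
                (self.index_class, c)
                for c, p in self.index_to_post.items()
                if p >= self.dominance_threshold
            }
        return edges


@dataclass(frozen=True)
class PlantedPath:
    pre: tuple[str, ...]
    post: tuple[str, ...]


@dataclass(frozen=True)
class ArtifactCounts:
    missing_discharge_spells: int = 0
    unlinked_episodes: int = 0
    duplicate_episodes: int = 0


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    planted_pre_model: ProcessModel
    planted_post_model: ProcessModel
    per_patient_paths: dict[str, PlantedPath]
    ages: dict[str, int] = field(default_factory=dict)
    index_dates: dict[str, dt.date] = field(default_factory=dict)
    artifact_counts: ArtifactCounts = ArtifactCounts()


def planted_bowtie(spec: PathwaySpec) -> BowTieModel:
    """The ground-truth bow-tie implied by the planted edges."""
    pre_edges = spec.resolved_planted_pre_edges()
    post_edges = spec.resolved_planted_post_edges()
    join_pre = frozenset(a for a, b in pre_edges if b == spec.index_class)
    join_post = frozenset(b for a, b in post_edges if a == spec.index_class)
    pre_internal = {(a, b) for a, b in pre_edges if spec.index_class not in (a, b)}
    post_internal = {(a, b) for a, b in post_edges if spec.index_class not in (a, b)}
    pre_nodes = {c for e in pre_internal for c in e} | join_pre
    post_nodes = {c for e in post_internal for c in e} | join_post
    return BowTieModel(
        index_class=spec.index_class,
        pre=ProcessModel(frozenset(pre_nodes), frozenset(pre_internal)),
        post=ProcessModel(frozenset(post_nodes), frozenset(post_internal)),
        join_pre=join_pre,
        join_post=join_post,
    )


def _dist_arrays(dist: dict[str, float], labels: list[str]) -> np.ndarray:
    p = np.array([dist.get(lab, 0.0) for lab in labels], dtype=float)
    return p / p.sum()


def _walk(
    rng: np.random.Generator,
    labels: list[str],
    matrix: np.ndarray,
    start_p: np.ndarray,
    length: int,
) -> list[int]:
    if length <= 0:
        return []
    states = [int(rng.choice(len(labels), p=start_p))]
    for _ in range(length - 1):
        states.append(int(rng.choice(len(labels), p=matrix[states[-1]])))
    return states


def generate_cohort(spec: PathwaySpec, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate raw episode records and the planted ground truth.

    Returns a DataFrame in the flat-file schema consumed by
    :func:`bowtiepm.eventlog.parse_episodes` (dates formatted yyyy-mm-dd,
    blanks for missing fields) and a :class:`GroundTruth` carrying the
    pre-noise class sequences.  The same ``(spec, seed)`` yields
    byte-identical output.  Artifacts configured on the spec are injected
    before returning.
    """
    mapping = load_default_mapping()
    code_of = _build_code_map(spec, mapping)
    labels = spec.class_labels
    li = {lab: i for i, lab in enumerate(labels)}
    pre_mat = np.array([[spec.pre_transition[a].get(b, 0.0) for b in labels] for a in labels])
    post_mat = np.array([[spec.post_transition[a].get(b, 0.0) for b in labels] for a in labels])
    uniform = np.full(len(labels), 1.0 / len(labels))
    pre_start = _dist_arrays(spec.pre_start, labels) if spec.pre_start else uniform
    pre_entry = _dist_arrays(spec.pre_to_index, labels) if spec.pre_to_index else None
    post_exit = _dist_arrays(spec.index_to_post, labels) if spec.index_to_post else None

    year_start = dt.date(spec.study_year, 1, 1)
    year_days = (dt.date(spec.study_year + 1, 1, 1) - year_start).days
    base = int(seed) % 2**32

    rows: list[dict] = []
    paths: dict[str, PlantedPath] = {}
    ages: dict[str, int] = {}
    index_dates: dict[str, dt.date] = {}

    for i in range(spec.n_patients):
        rng = np.random.default_rng([base, i])
        pid = f"P{i:06d}"
        if spec.underage_fraction and rng.random() < spec.underage_fraction:
            age = int(rng.integers(1, 14))
        else:
            age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        index_date = year_start + dt.timedelta(days=int(rng.integers(0, year_days)))

        lo, hi = spec.events_per_patient_pre
        n_pre = int(rng.integers(lo, hi + 1))
        if pre_entry is not None and n_pre > 0:
            walk = _walk(rng, labels, pre_mat, pre_start, n_pre - 1)
            walk.append(int(rng.choice(len(labels), p=pre_entry)))
        else:
            walk = _walk(rng, labels, pre_mat, pre_start, n_pre)
        pre_classes = [labels[s] for s in walk]

        lo, hi = spec.events_per_patient_post
        n_post = int(rng.integers(lo, hi + 1))
        if post_exit is not None and n_post > 0:
            walk = [int(rng.choice(len(labels), p=post_exit))]
            walk.extend(_walk(rng, labels, post_mat, post_mat[walk[0]], n_post - 1))
        else:
            walk = _walk(rng, labels, post_mat, uniform, n_post)
        post_classes = [labels[s] for s in walk]

        paths[pid] = PlantedPath(tuple(pre_classes), tuple(post_classes))
        ages[pid] = age
        index_dates[pid] = index_date

        pre_offsets = np.sort(rng.choice(np.arange(-spec.pre_window_days, 0), size=n_pre, replace=False))
        post_offsets = np.sort(rng.choice(np.arange(1, spec.post_window_days + 1), size=n_post, replace=False))

        observed_pre = [
            labels[int(rng.integers(len(labels)))] if rng.random() < spec.noise_rate else c
            for c in pre_classes
        ]
        observed_post = [
            labels[int(rng.integers(len(labels)))] if rng.random() < spec.noise_rate else c
            for c in post_classes
        ]

        spell_no = 0

        def emit_event(cls: str, date: dt.date) -> None:
            nonlocal spell_no
            spell_no += 1
            sid = f"{pid}-S{spell_no:03d}"
            outpatient = rng.random() < spec.outpatient_fraction
            if outpatient:
                rows.append(
                    {
                        "patient_id": pid,
                        "spell_id": sid,
                        "episode_start": date.isoformat(),
                        "episode_end": "",
                        "los_days": "",
                        "setting": "outpatient",
                        "admission_method": "",
                        "age": age,
                        "diag_01": code_of[cls],
                        "diag_02": "",
                    }
                )
                return
            los = int(rng.integers(1, 15))
            secondary = code_of[labels[int(rng.integers(len(labels)))]]
            rows.append(
                {
                    "patient_id": pid,
                    "spell_id": sid,
                    "episode_start": date.isoformat(),
                    "episode_end": (date + dt.timedelta(days=los)).isoformat(),
                    "los_days": los,
                    "setting": "inpatient",
                    "admission_method": "21",
                    "age": age,
                    "diag_01": code_of[cls],
                    "diag_02": secondary,
                }
            )
            if rng.random() < spec.extra_episode_rate:
                # A second consultant episode within the same stay.
                mid = date + dt.timedelta(days=int(rng.integers(0, los + 1)))
                rows.append(
                    {
                        "patient_id": pid,
                        "spell_id": sid,
                        "episode_start": mid.isoformat(),
                        "episode_end": (date + dt.timedelta(days=los)).isoformat(),
                        "los_days": los,
                        "setting": "inpatient",
                        "admission_method": "",
                        "age": age,
                        "diag_01": secondary,
                        "diag_02": "",
                    }
                )

        for cls, off in zip(observed_pre, pre_offsets):
            emit_event(cls, index_date + dt.timedelta(days=int(off)))

        # The index admission itself: always a linked inpatient stay.
        spell_no += 1
        los = int(rng.integers(1, 22))
        rows.append(
            {
                "patient_id": pid,
                "spell_id": f"{pid}-S{spell_no:03d}",
                "episode_start": index_date.isoformat(),
                "episode_end": (index_date + dt.timedelta(days=los)).isoformat(),
                "los_days": los,
                "setting": "inpatient",
                "admission_method": "21",
                "age": age,
                "diag_01": spec.index_code,
                "diag_02": code_of[labels[int(rng.integers(len(labels)))]],
            }
        )
        for cls, off in zip(observed_post, post_offsets):
            emit_event(cls, index_date + dt.timedelta(days=int(off)))

    records = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    counts = ArtifactCounts()
    if spec.artifact_rates.any_active():
        records, counts = inject_artifacts(
            records, spec.artifact_rates, seed, protect_codes=(spec.index_code,)
        )
    truth = GroundTruth(
        planted_pre_model=planted_bowtie(spec).pre,
        planted_post_model=planted_bowtie(spec).post,
        per_patient_paths=paths,
        ages=ages,
        index_dates=index_dates,
        artifact_counts=counts,
    )
    return records, truth


def _build_code_map(spec: PathwaySpec, mapping: ClassMapping) -> dict[str, str]:
    code_of: dict[str, str] = {}
    for lab in spec.class_labels:
        if spec.code_map and lab in spec.code_map:
            code_of[lab] = spec.code_map[lab]
        else:
            try:
                code_of[lab] = mapping.representative_code(lab)
            except KeyError as exc:
                raise ValueError(
                    f"class label {lab!r} is not in the bundled meta-code table; "
                    "supply code_map entries for custom labels"
                ) from exc
    return code_of


def inject_artifacts(
    records: pd.DataFrame,
    rates: ArtifactRates | dict,
    seed: int,
    protect_codes: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, ArtifactCounts]:
    """Degrade clean episode records with HES-like recording artifacts.

    With the configured probabilities, an inpatient stay loses its
    discharge date and length of stay, an episode is orphaned from its
    spell (blank spell id), or a stay gains a duplicate same-timestamp
    episode carrying a secondary diagnosis.  Episodes whose primary code is
    in ``protect_codes`` (the index admissions) are never orphaned, so the
    cohort anchor survives.  Returns the degraded records and the injected
    counts for bookkeeping.
    """
    if isinstance(rates, dict):
        rates = ArtifactRates(**rates)
    rng = np.random.default_rng([int(seed) % 2**32, 0x5EED])
    df = records.copy(deep=True)

    inpatient = df["setting"] == "inpatient"
    spells = df.loc[inpatient, "spell_id"].unique()
    n_missing = 0
    if rates.missing_discharge > 0 and len(spells):
        hit = spells[rng.random(len(spells)) < rates.missing_discharge]
        mask = df["spell_id"].isin(hit)
        df.loc[mask, ["episode_end", "los_days"]] = ""
        n_missing = len(hit)

    n_unlinked = 0
    if rates.unlinked_episode > 0 and len(df):
        eligible = ~df["diag_01"].isin(protect_codes)
        hit = eligible & (rng.random(len(df)) < rates.unlinked_episode)
        df.loc[hit, "spell_id"] = ""
        n_unlinked = int(hit.sum())

    n_dup = 0
    dup_rows = []
    if rates.duplicate_diagnosis > 0:
        firsts = df[inpatient & (df["spell_id"] != "")].drop_duplicates("spell_id")
        hit = rng.random(len(firsts)) < rates.duplicate_diagnosis
        for _, row in firsts[hit].iterrows():
            dup = row.copy()
            dup["diag_01"] = row["diag_02"] if row["diag_02"] else row["diag_01"]
            dup["diag_02"] = ""
            dup_rows.append(dup)
        n_dup = len(dup_rows)
    if dup_rows:
        df = pd.concat([df, pd.DataFrame(dup_rows)], ignore_index=True)

    return df, ArtifactCounts(n_missing, n_unlinked, n_dup)


def sepsis_demo_spec(
    n_patients: int = 500,
    noise_rate: float = 0.05,
    artifact_rates: ArtifactRates | None = None,
) -> PathwaySpec:
    """The package's reference synthetic cohort: a 10-class sepsis bow-tie.

    The class palette follows the conditions most often seen around sepsis
    admissions (pneumonia, UTI, cancers, anemia, fractures ...), with six
    dominant pre-index transitions planted for recovery experiments,
    recurrent UTI as a planted self-loop among them, and an unstructured
    follow-up period.
    """
    classes = [
        "Pneumonia",
        "Urinary tract infections (UTI)",
        "Other gastrointestinal disorders",
        "Cancer of breast",
        "Secondary malignancies",
        "Leukemias",
        "Anemia",
        "Fracture of lower limb",
        "Biliary tract disease",
        "Skin and subcutaneous tissue infections",
    ]
    planted = {
        ("Urinary tract infections (UTI)", "Urinary tract infections (UTI)"): 0.6,
        ("Cancer of breast", "Secondary malignancies"): 0.7,
        ("Secondary malignancies", "Anemia"): 0.65,
        ("Anemia", "Fracture of lower limb"): 0.65,
        ("Fracture of lower limb", "Skin and subcutaneous tissue infections"): 0.65,
        ("Biliary tract disease", "Other gastrointestinal disorders"): 0.7,
    }
    # Pathway entry points carry extra starting mass so each planted chain
    # is well populated at cohort scale.
    entry = {"Cancer of breast": 0.2, "Urinary tract infections (UTI)": 0.2, "Biliary tract disease": 0.2}

    def row(src: str) -> dict[str, float]:
        targets = {b: p for (a, b), p in planted.items() if a == src}
        rest = [c for c in classes if c not in targets]
        remainder = 1.0 - sum(targets.values())
        share = remainder / len(rest)
        out = {c: share for c in rest}
        out.update(targets)
        return out

    pre_transition = {c: row(c) for c in classes}
    rest_start = (1.0 - sum(entry.values())) / (len(classes) - len(entry))
    pre_start = {c: entry.get(c, rest_start) for c in classes}
    uniform_row = {c: 1.0 / len(classes) for c in classes}
    post_transition = {c: dict(uniform_row) for c in classes}
    pre_to_index = {
        "Pneumonia": 0.28,
        "Urinary tract infections (UTI)": 0.2,
        "Other gastrointestinal disorders": 0.16,
        **{c: 0.36 / 7 for c in classes if c not in (
            "Pneumonia", "Urinary tract infections (UTI)", "Other gastrointestinal disorders")},
    }
    return PathwaySpec(
        class_labels=classes,
        index_class="Septicemia",
        pre_transition=pre_transition,
        post_transition=post_transition,
        pre_start=pre_start,
        pre_to_index=pre_to_index,
        planted_pre_edges=sorted(planted),
        planted_post_edges=[],
        dominance_threshold=0.3,
        noise_rate=noise_rate,
        n_patients=n_patients,
        underage_fraction=0.05,
        artifact_rates=artifact_rates
        or ArtifactRates(missing_discharge=0.05, unlinked_episode=0.01, duplicate_diagnosis=0.05),
    )
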