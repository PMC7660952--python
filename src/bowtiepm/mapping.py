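"""ICD-10 meta-code grouping.

Hospital diagnoses arrive as ICD-10 codes (``A41.9``, ``N39.0`` ...).  For
pathway mining these are far too granular, so they are grouped into a few
hundred clinically meaningful "coded event" classes in the style of the
AHRQ Clinical Classifications Software (CCS).  The bundled default table
defines exactly 220 classes keyed by ICD-10 prefixes; lookup uses
longest-prefix semantics so that, for example, ``N39.0`` resolves to the
urinary-tract-infection class while any other ``N39.x`` code falls back to
the broader genitourinary-symptoms class.

Users may substitute their own table (e.g. the full CCS release) via
:meth:`ClassMapping.from_csv`.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "UNMAPPED",
    "ClassMapping",
    "load_default_mapping",
    "map_event_class",
    "normalize_code",
]

#: Sentinel event class returned for codes outside the mapping's universe.
UNMAPPED = "UNMAPPED"


def normalize_code(code: str) -> str:
    """Canonical form of an ICD-10 code: dots/spaces stripped, upper-cased."""
    return code.replace(".", "").replace(" ", "").strip().upper()


class UnmappedCodeError(KeyError):
    """Raised when a code has no prefix match and the policy is ``error``."""


@dataclass(frozen=True)
class ClassMapping:
    """Prefix-keyed grouping of ICD-10 codes into event classes.

    Parameters
    ----------
    entries
        Mapping from *normalized* ICD-10 prefix to event-class label.
        Longest matching prefix wins on lookup.
    """

    entries: Mapping[str, str]
    _rep_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for prefix, label in self.entries.items():
            if not prefix or prefix != normalize_code(prefix):
                raise ValueError(f"prefix {prefix!r} is not normalized")
            if not label:
                raise ValueError(f"empty class label for prefix {prefix!r}")

    @property
    def class_count(self) -> int:
        """Number of distinct event-class labels."""
        return len(set(self.entries.values()))

    @property
    def labels(self) -> set[str]:
        return set(self.entries.values())

    def lookup(self, code: str, *, on_unmapped: str = "sentinel") -> str:
        """Map one ICD-10 code to its event class.

        ``on_unmapped`` is either ``"sentinel"`` (return :data:`UNMAPPED`)
        or ``"error"``.
        """
        norm = normalize_code(code)
        if not norm:
            raise ValueError("empty ICD-10 code")
        for stop in range(len(norm), 0, -1):
            label = self.entries.get(norm[:stop])
            if label is not None:
                return label
        if on_unmapped == "error":
            raise UnmappedCodeError(code)
        return UNMAPPED

    def representative_code(self, label: str) -> str:
        """A concrete ICD-10 code that maps back to ``label``.

        Used by the synthetic cohort generator so that every emitted code
        round-trips through :meth:`lookup`.
        """
        if label in self._rep_cache:
            return self._rep_cache[label]
        for prefix, lab in self.entries.items():
            if lab != label:
                continue
            code = self._format_code(prefix)
            if self.lookup(code) == label:
                self._rep_cache[label] = code
                return code
        raise KeyError(f"no representative code for class {label!r}")

    @staticmethod
    def _format_code(prefix: str) -> str:
        # Pad short prefixes to a plausible 3-char category, then add a
        # 4th digit so the emitted code looks like real coding practice.
        base = (prefix + "99")[:3]
        tail = prefix[3:] if len(prefix) > 3 else "9"
        return f"{base}.{tail}"

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str]]) -> "ClassMapping":
        return cls(entries={normalize_code(p): lab for p, lab in entries})

    @classmethod
    def from_csv(cls, source: str | Path | io.TextIOBase) -> "ClassMapping":
        """Load a two-column ``icd10_prefix,event_class`` table."""
        if isinstance(source, (str, Path)):
            fh = open(source, newline="")
            close = True
        else:
            fh, close = source, False
        try:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                raise ValueError("empty mapping file")
            entries = {}
            for row in reader:
                if not row or not row[0].strip():
                    continue
                prefix, label = normalize_code(row[0]), row[1].strip()
                if prefix in entries and entries[prefix] != label:
                    raise ValueError(f"prefix {prefix!r} mapped to two classes")
                entries[prefix] = label
            return cls(entries=entries)
        finally:
            if close:
                fh.close()


@lru_cache(maxsize=1)
def load_default_mapping() -> ClassMapping:
    """The bundled 220-class CCS-style meta-code table."""
    ref = resources.files("bowtiepm").joinpath("data/meta_codes.csv")
    with ref.open("r", newline="") as fh:
        return ClassMapping.from_csv(fh)


def map_event_class(code: str, mapping: ClassMapping, *, on_unmapped: str = "sentinel") -> str:
    """Functional wrapper around :meth:`ClassMapping.lookup`."""
    return mapping.lookup(code, on_unmapped=on_unmapped)
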