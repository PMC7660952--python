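"""Process models and the replayability (replay-fitness) score.

A process model here is deliberately simple: a set of event-class nodes and
a set of directed edges between them (self-loops allowed, for recurrent
admissions).  Model quality is measured by *replayability*: each patient
trace is projected onto the model's nodes, the first projected event always
replays, and each subsequent projected event replays iff the succession
from the previous projected class is an edge of the model.  The score is
the pooled fraction of replayed events over all events on the chosen side
of the log, so it lives in [0, 1], is 0 for the empty model and 1 for the
model containing every observed class and every observed direct
succession.

Scoring the same log against many candidate models is the inner loop of
the discovery metaheuristic, so :func:`replayability` runs on a compiled
integer representation of the log (cached per side) and evaluates each
model with vectorized numpy lookups; :func:`replay_trace` is the plain
reference implementation of the same semantics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .eventlog import EventLog, Side

__all__ = [
    "ProcessModel",
    "BowTieModel",
    "SizeConstraints",
    "Support",
    "SuccessionUniverse",
    "ReplayResult",
    "succession_universe",
    "replay_trace",
    "replayability",
    "within_constraints",
]


@dataclass(frozen=True)
class ProcessModel:
    """A directed graph over event classes; hashable and canonical."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) has endpoint outside nodes")

    @classmethod
    def empty(cls) -> "ProcessModel":
        return cls(frozenset(), frozenset())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def signature(self) -> tuple:
        """Canonical hashable identity used for tabu bookkeeping."""
        return (tuple(sorted(self.nodes)), tuple(sorted(self.edges)))

    def to_dict(self) -> dict:
        return {
            "nodes": sorted(self.nodes),
            "edges": [list(e) for e in sorted(self.edges)],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ProcessModel":
        return cls(
            nodes=frozenset(data["nodes"]),
            edges=frozenset((a, b) for a, b in data["edges"]),
        )


@dataclass(frozen=True)
class BowTieModel:
    """Two model halves joined at the index class (ground-truth container)."""

    index_class: str
    pre: ProcessModel
    post: ProcessModel
    join_pre: frozenset[str] = frozenset()  # classes with an edge into the index
    join_post: frozenset[str] = frozenset()  # classes the index feeds into


@dataclass(frozen=True)
class SizeConstraints:
    """Complexity threshold: hard caps on model size to avoid overfitting."""

    max_nodes: int
    max_edges: int

    def __post_init__(self) -> None:
        if self.max_nodes < 1:
            raise ValueError("max_nodes must be >= 1")
        if self.max_edges < 0:
            raise ValueError("max_edges must be >= 0")


def within_constraints(model: ProcessModel, constraints: SizeConstraints) -> bool:
    return model.n_nodes <= constraints.max_nodes and model.n_edges <= constraints.max_edges


class Support(NamedTuple):
    events: int
    patients: int


@dataclass
class SuccessionUniverse:
    """Candidate nodes and directly-follows edges observed in the log."""

    nodes: dict[str, Support]
    edges: dict[tuple[str, str], Support]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"candidate edge ({a!r}, {b!r}) outside candidate nodes")

    @property
    def candidate_nodes(self) -> set[str]:
        return set(self.nodes)

    @property
    def candidate_edges(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def complete_model(self) -> ProcessModel:
        """The model containing every candidate node and edge."""
        return ProcessModel(frozenset(self.nodes), frozenset(self.edges))


def succession_universe(log: EventLog, side: Side) -> SuccessionUniverse:
    """Tally candidate nodes and adjacent-pair edges on one side of the log.

    Supports are counted both as raw event/succession counts and as
    distinct-patient counts.
    """
    node_events: dict[str, int] = {}
    node_patients: dict[str, set[str]] = {}
    edge_events: dict[tuple[str, str], int] = {}
    edge_patients: dict[tuple[str, str], set[str]] = {}
    for trace in log.traces:
        seq = trace.classes(side)
        for label in seq:
            node_events[label] = node_events.get(label, 0) + 1
            node_patients.setdefault(label, set()).add(trace.patient_id)
        for a, b in zip(seq, seq[1:]):
            edge_events[(a, b)] = edge_events.get((a, b), 0) + 1
            edge_patients.setdefault((a, b), set()).add(trace.patient_id)
    return SuccessionUniverse(
        nodes={k: Support(v, len(node_patients[k])) for k, v in node_events.items()},
        edges={k: Support(v, len(edge_patients[k])) for k, v in edge_events.items()},
    )


@dataclass(frozen=True)
class ReplayResult:
    replayed_events: int
    total_events: int

    def __post_init__(self) -> None:
        if self.replayed_events > self.total_events:
            raise ValueError("replayed_events cannot exceed total_events")

    @property
    def score(self) -> float:
        return self.replayed_events / self.total_events if self.total_events else 0.0


def replay_trace(sequence: Sequence[str], model: ProcessModel) -> ReplayResult:
    """Replay one event sequence on a model (reference implementation).

    The "previous" event for the edge check is the previous *projected*
    event (one whose class is a model node), whether or not it replayed.
    """
    total = len(sequence)
    replayed = 0
    prev: Optional[str] = None
    for label in sequence:
        if label not in model.nodes:
            continue
        if prev is None or (prev, label) in model.edges:
            replayed += 1
        prev = label
    return ReplayResult(replayed, total)


class _CompiledSide:
    """Integer-encoded side of a log for fast repeated scoring."""

    def __init__(self, log: EventLog, side: Side) -> None:
        classes = sorted({c for t in log.traces for c in t.classes(side)})
        self.classes = classes
        self.index_of = {c: i for i, c in enumerate(classes)}
        events: list[int] = []
        tids: list[int] = []
        for tid, trace in enumerate(log.traces):
            for label in trace.classes(side):
                events.append(self.index_of[label])
                tids.append(tid)
        self.events = np.asarray(events, dtype=np.int64)
        self.tids = np.asarray(tids, dtype=np.int64)
        self.n_traces = len(log.traces)

    def masks(self, model: ProcessModel) -> tuple[np.ndarray, np.ndarray]:
        c = len(self.classes)
        node_mask = np.zeros(c, dtype=bool)
        for label in model.nodes:
            i = self.index_of.get(label)
            if i is not None:
                node_mask[i] = True
        edge_mask = np.zeros((c, c), dtype=bool)
        for a, b in model.edges:
            ia, ib = self.index_of.get(a), self.index_of.get(b)
            if ia is not None and ib is not None:
                edge_mask[ia, ib] = True
        return node_mask, edge_mask

    def score(self, model: ProcessModel, trace_sel: Optional[np.ndarray] = None) -> ReplayResult:
        keep = np.ones(len(self.events), dtype=bool) if trace_sel is None else trace_sel[self.tids]
        total = int(keep.sum())
        if total == 0:
            return ReplayResult(0, 0)
        node_mask, edge_mask = self.masks(model)
        proj = keep & node_mask[self.events]
        ev = self.events[proj]
        tid = self.tids[proj]
        if len(ev) == 0:
            return ReplayResult(0, total)
        first = np.empty(len(ev), dtype=bool)
        first[0] = True
        first[1:] = tid[1:] != tid[:-1]
        follows = edge_mask[ev[:-1], ev[1:]] & ~first[1:]
        replayed = int(first.sum()) + int(follows.sum())
        return ReplayResult(replayed, total)


def compiled_side(log: EventLog, side: Side) -> _CompiledSide:
    key = ("compiled", side)
    if key not in log._cache:
        log._cache[key] = _CompiledSide(log, side)
    return log._cache[key]


def replayability(
    model: ProcessModel,
    log: EventLog,
    side: Side,
    sample_size: int | None = None,
    seed: int | np.random.Generator | None = None,
    trace_averaged: bool = False,
) -> float:
    """Pooled replay fitness of ``model`` on one side of the log.

    ``sample_size=None`` scores every trace exactly; an integer draws that
    many traces without replacement (Monte Carlo scoring) under ``seed``.
    ``trace_averaged=True`` averages per-trace fractions instead of pooling
    events, giving every patient equal weight.
    """
    if sample_size is not None and sample_size <= 0:
        raise ValueError("sample_size must be positive")
    comp = compiled_side(log, side)
    trace_sel = None
    if sample_size is not None and sample_size < comp.n_traces:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
            0 if seed is None else seed % 2**32
        )
        chosen = rng.choice(comp.n_traces, size=sample_size, replace=False)
        trace_sel = np.zeros(comp.n_traces, dtype=bool)
        trace_sel[chosen] = True
    if not trace_averaged:
        return comp.score(model, trace_sel).score
    # Trace-averaged variant: plain loop; only used at desk scale.
    ratios = []
    for tid, trace in enumerate(log.traces):
        if trace_sel is not None and not trace_sel[tid]:
            continue
        seq = trace.classes(side)
        if not seq:
            continue
        ratios.append(replay_trace(seq, model).score)
    return float(np.mean(ratios)) if ratios else 0.0
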