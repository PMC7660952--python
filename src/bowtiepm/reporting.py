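"""Output surfaces: weighted bow-tie graphs, frequency tables, exports.

All headline counts are *distinct patients*, not raw events: a node's
weight is the number of patients with at least one replayed event of that
class on that side, and an edge's weight is the number of patients whose
replay traverses that succession at least once.  Event-count weighting is
available behind a flag for diagnostic use.

Graphs export to Graphviz DOT (with a left-to-right bow-tie layout hint),
GraphML, or a lossless JSON form.  Because the same clinical class can
appear both before and after the index admission, graph node identifiers
are side-qualified (``pre:UTI`` vs ``post:UTI``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .discovery import BowTieResult
from .eventlog import EventLog, Side
from .mapping import ClassMapping

__all__ = [
    "TOP10_SOS_CODES",
    "WeightedBowTie",
    "SosAllocation",
    "annotate_patient_counts",
    "event_frequency_table",
    "recurrence_counts",
    "allocate_sos_codes",
    "export_graph",
]

#: The ten "suspicion of sepsis" ICD-10 codes most often flagged ahead of a
#: sepsis admission, in their published ranking.
TOP10_SOS_CODES = (
    "J18.1",  # Lobar pneumonia, unspecified
    "J18.9",  # Pneumonia, unspecified
    "N39.0",  # Urinary tract infection, site not specified
    "J18.0",  # Bronchopneumonia, unspecified
    "A41.9",  # Sepsis, unspecified
    "J69.0",  # Pneumonitis due to food and vomit
    "J44.0",  # COPD with acute lower respiratory infection
    "J22.X",  # Unspecified acute lower respiratory infection
    "L03.1",  # Cellulitis of other parts of limb
    "K63.1",  # Perforation of intestine (non-traumatic)
)


@dataclass(frozen=True)
class WeightedNode:
    label: str
    side: str  # pre | index | post
    patient_count: int


@dataclass(frozen=True)
class WeightedEdge:
    source: str
    target: str
    side: str  # pre | post | join
    patient_count: int


@dataclass
class WeightedBowTie:
    """A bow-tie graph annotated with patient-count weights."""

    index_class: str
    nodes: list[WeightedNode]
    edges: list[WeightedEdge]
    total_patients: int
    total_events: int

    def to_dict(self) -> dict:
        return {
            "index_class": self.index_class,
            "total_patients": self.total_patients,
            "total_events": self.total_events,
            "nodes": [[n.label, n.side, n.patient_count] for n in self.nodes],
            "edges": [[e.source, e.target, e.side, e.patient_count] for e in self.edges],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "WeightedBowTie":
        return cls(
            index_class=data["index_class"],
            nodes=[WeightedNode(*row) for row in data["nodes"]],
            edges=[WeightedEdge(*row) for row in data["edges"]],
            total_patients=data["total_patients"],
            total_events=data["total_events"],
        )


def _replay_walk(seq: Sequence[str], nodes: frozenset, edges: frozenset):
    """Yield (event_class, replayed, traversed_edge_or_None) per projected event."""
    prev = None
    for label in seq:
        if label not in nodes:
            continue
        if prev is None:
            yield label, True, None
        elif (prev, label) in edges:
            yield label, True, (prev, label)
        else:
            yield label, False, None
        prev = label


def annotate_patient_counts(
    bowtie: BowTieResult,
    log: EventLog,
    count_events: bool = False,
) -> WeightedBowTie:
    """Weight a discovered bow-tie by the patients following each pathway.

    Per the replay semantics, a patient counts toward a node if at least
    one of their events of that class replays on that side, and toward an
    edge if their replay traverses that succession.  The index node's
    weight is the full cohort.  With ``count_events=True`` raw event and
    traversal counts are reported instead.
    """
    sides = {"pre": bowtie.pre.best_model, "post": bowtie.post.best_model}
    node_hits: dict[tuple[str, str], set | int] = {}
    edge_hits: dict[tuple[str, str, str], set | int] = {}

    def bump(store, key, pid):
        if count_events:
            store[key] = store.get(key, 0) + 1
        else:
            store.setdefault(key, set()).add(pid)

    for trace in log.traces:
        for side, model in sides.items():
            for label, replayed, edge in _replay_walk(
                trace.classes(side), model.nodes, model.edges
            ):
                if replayed:
                    bump(node_hits, (side, label), trace.patient_id)
                if edge is not None:
                    bump(edge_hits, (side, *edge), trace.patient_id)

    def size(v):
        return v if count_events else len(v)

    nodes = [WeightedNode(bowtie.index_class, "index", len(log.traces))]
    for side, model in sides.items():
        for label in sorted(model.nodes):
            nodes.append(WeightedNode(label, side, size(node_hits.get((side, label), set() if not count_events else 0))))
    edges = []
    for side, model in sides.items():
        for a, b in sorted(model.edges):
            edges.append(WeightedEdge(a, b, side, size(edge_hits.get((side, a, b), set() if not count_events else 0))))
    for (a, b), n in sorted(bowtie.join_edges.items()):
        side = "join"
        edges.append(WeightedEdge(a, b, side, n))
    total_events = sum(len(t.pre_events) + len(t.post_events) + 1 for t in log.traces)
    return WeightedBowTie(
        index_class=bowtie.index_class,
        nodes=nodes,
        edges=edges,
        total_patients=len(log.traces),
        total_events=total_events,
    )


def event_frequency_table(log: EventLog, side: Side, top_k: int | None = None) -> pd.DataFrame:
    """Distinct-patient counts per event class, most frequent first.

    Ties are broken lexicographically by class label.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    patients: dict[str, set[str]] = {}
    for trace in log.traces:
        for label in trace.classes(side):
            patients.setdefault(label, set()).add(trace.patient_id)
    rows = sorted(
        ((label, len(pids)) for label, pids in patients.items()),
        key=lambda t: (-t[1], t[0]),
    )
    df = pd.DataFrame(rows, columns=["event_class", "patients"])
    return df.head(top_k) if top_k is not None else df


def recurrence_counts(log: EventLog, event_class: str, side: Side, min_admissions: int = 1) -> int:
    """Patients with at least ``min_admissions`` events of a class on a side.

    This is the computation behind statements like "N patients had at
    least one admission for UTI before their index sepsis episode, and M
    had at least two".
    """
    if min_admissions < 1:
        raise ValueError("min_admissions must be >= 1")
    return sum(
        1
        for trace in log.traces
        if sum(1 for c in trace.classes(side) if c == event_class) >= min_admissions
    )


@dataclass
class SosAllocation:
    """Suspicion-of-sepsis codes grouped under their coded event classes."""

    rows: list[tuple[str, list[str]]]  # (event class, codes) in first-seen order
    in_model: dict[str, bool] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return [label for label, _ in self.rows]


def allocate_sos_codes(
    codes: Sequence[str],
    mapping: ClassMapping,
    model: Optional[BowTieResult] = None,
) -> SosAllocation:
    """Group SOS ICD-10 codes by their coded event class.

    When a discovery result is supplied, each class row is flagged as
    represented or not in the final model (pre half, post half, or the
    index node itself).  Unmappable codes land in the sentinel row.
    """
    if not codes:
        raise ValueError("codes must not be empty")
    rows: dict[str, list[str]] = {}
    for code in codes:
        label = mapping.lookup(code)
        rows.setdefault(label, []).append(code)
    in_model: dict[str, bool] = {}
    if model is not None:
        present = (
            set(model.pre.best_model.nodes)
            | set(model.post.best_model.nodes)
            | {model.index_class}
        )
        in_model = {label: label in present for label in rows}
    return SosAllocation(rows=list(rows.items()), in_model=in_model)


# ---------------------------------------------------------------------------
# Export


def _qualified(side: str, label: str) -> str:
    return f"{side}:{label}"


def _edge_endpoints(e: WeightedEdge, index_class: str) -> tuple[str, str]:
    if e.side in ("pre", "post"):
        return _qualified(e.side, e.source), _qualified(e.side, e.target)
    # Join edges connect a half to the central index node.
    if e.target == index_class:
        return _qualified("pre", e.source), _qualified("index", e.target)
    return _qualified("index", e.source), _qualified("post", e.target)


def to_networkx(weighted: WeightedBowTie) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in weighted.nodes:
        g.add_node(_qualified(n.side, n.label), label=n.label, side=n.side, weight=n.patient_count)
    for e in weighted.edges:
        u, v = _edge_endpoints(e, weighted.index_class)
        g.add_edge(u, v, side=e.side, weight=e.patient_count)
    return g


def _dot_escape(s: str) -> str:
    return s.replace('"', '\\"')


def _to_dot(weighted: WeightedBowTie) -> str:
    lines = [
        "digraph bowtie {",
        "  rankdir=LR;",  # pre -> index -> post reads left to right
        "  node [shape=circle];",
    ]
    for side in ("pre", "index", "post"):
        members = [n for n in weighted.nodes if n.side == side]
        if not members:
            continue
        lines.append(f"  subgraph cluster_{side} {{")
        lines.append(f'    label="{side}";')
        for n in members:
            nid = _dot_escape(_qualified(n.side, n.label))
            lines.append(
                f'    "{nid}" [label="{_dot_escape(n.label)}" weight="{n.patient_count}"];'
            )
        lines.append("  }")
    for e in weighted.edges:
        u, v = _edge_endpoints(e, weighted.index_class)
        lines.append(
            f'  "{_dot_escape(u)}" -> "{_dot_escape(v)}" [weight="{e.patient_count}" '
            f'label="{e.patient_count}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(weighted: WeightedBowTie, fmt: str, path: str | Path) -> Path:
    """Write the weighted bow-tie as DOT, GraphML, or JSON.

    The JSON form round-trips losslessly through
    :meth:`WeightedBowTie.from_dict`.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "dot":
        path.write_text(_to_dot(weighted))
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(weighted), path)
    elif fmt == "json":
        path.write_text(json.dumps(weighted.to_dict(), indent=2))
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected dot, graphml, or json)")
    return path
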