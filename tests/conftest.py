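"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's optimized code paths:
``oracle_replay`` is a plain walk over one sequence, ``oracle_score``
pools it over a log, and ``exhaustive_optimum`` enumerates every feasible
model on tiny instances.
"""
from __future__ import annotations

import io
import itertools

import pytest

from bowtiepm.eventlog import CodedEvent, EventLog, PatientTrace
from bowtiepm.mapping import load_default_mapping


def make_log(pre=None, post=None, index_class="Septicemia") -> EventLog:
    """Build an in-memory event log from {patient: [classes]} dicts."""
    pre = pre or {}
    post = post or {}
    traces = []
    for pid in sorted(set(pre) | set(post)):
        pseq = list(pre.get(pid, []))
        oseq = list(post.get(pid, []))
        traces.append(
            PatientTrace(
                patient_id=pid,
                age_at_index=50,
                index_date=None,
                pre_events=tuple(
                    CodedEvent(pid, c, None, -(len(pseq) - i)) for i, c in enumerate(pseq)
                ),
                post_events=tuple(CodedEvent(pid, c, None, i + 1) for i, c in enumerate(oseq)),
            )
        )
    return EventLog(traces=traces, index_class=index_class)


def oracle_replay(seq, nodes, edges) -> tuple[int, int]:
    """Reference replayer: (replayed, total) for one sequence."""
    replayed = 0
    prev = None
    for c in seq:
        if c not in nodes:
            continue
        if prev is None or (prev, c) in edges:
            replayed += 1
        prev = c
    return replayed, len(seq)


def oracle_score(log: EventLog, side, nodes, edges) -> float:
    """Pooled replay fitness computed trace by trace."""
    num = den = 0
    for trace in log.traces:
        r, t = oracle_replay(trace.classes(side), nodes, edges)
        num += r
        den += t
    return num / den if den else 0.0


def exhaustive_optimum(log: EventLog, side, max_nodes, max_edges):
    """Enumerate every feasible model on a tiny instance; return (score, models)."""
    seqs = log.sequences(side)
    cand_nodes = sorted({c for s in seqs for c in s})
    cand_edges = sorted({(a, b) for s in seqs for a, b in zip(s, s[1:])})
    best = 0.0
    argmax = []
    for r in range(0, min(max_nodes, len(cand_nodes)) + 1):
        for nodes in itertools.combinations(cand_nodes, r):
            node_set = set(nodes)
            internal = [e for e in cand_edges if e[0] in node_set and e[1] in node_set]
            for k in range(0, min(max_edges, len(internal)) + 1):
                for edges in itertools.combinations(internal, k):
                    s = oracle_score(log, side, node_set, set(edges))
                    if s > best + 1e-12:
                        best, argmax = s, [(node_set, set(edges))]
                    elif abs(s - best) <= 1e-12:
                        argmax.append((node_set, set(edges)))
    return best, argmax


def records_to_log(records, mapping=None, index_spec=None):
    """Run the full structuration pipeline on an in-memory episode table."""
    from bowtiepm.eventlog import build_traces, parse_episodes, resolve_spells

    parsed = parse_episodes(io.StringIO(records.to_csv(index=False)))
    spells, removed = resolve_spells(parsed.episodes)
    log = build_traces(spells, mapping or load_default_mapping(), index_spec)
    log.manifest["episodes_removed_unlinked"] = removed
    return log


@pytest.fixture(scope="session")
def mapping():
    return load_default_mapping()


@pytest.fixture(scope="session")
def demo_cohort():
    """A mid-size synthetic cohort shared by discovery-level tests."""
    from bowtiepm.synth import generate_cohort, sepsis_demo_spec

    spec = sepsis_demo_spec(n_patients=200)
    records, truth = generate_cohort(spec, seed=7)
    return spec, records, truth


@pytest.fixture(scope="session")
def demo_log(demo_cohort):
    _, records, _ = demo_cohort
    return records_to_log(records)
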