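"""Constructive tabu-search discovery of size-constrained process models.

The search maximizes replay fitness under a hard complexity threshold.
One run proceeds in three steps:

1. *Initialization* — a feasible starting model is drawn at random from
   the succession universe (support-weighted) and becomes both the current
   and the global solution.
2. *Neighborhood* — small "smart" edits of the current solution generate
   neighbor models: add/remove a node, add/remove an edge, or swap a node
   (rewiring the highest-support edges of the incoming node).  Every class
   observed in the log remains eligible at every iteration.
3. *Selection* — the best-scoring non-tabu neighbor becomes the new
   current solution (even when it scores worse than the current one, which
   is how tabu search escapes local optima); its signature is censored for
   ``tabu_tenure`` iterations.  The global solution is replaced only on
   strict improvement.

The run stops after ``patience`` consecutive iterations without improving
the global solution (default 25) or after ``max_iterations`` in total
(default 500).

The bow-tie driver :func:`discover_bowtie` runs this search independently
on the pre-index and post-index halves of the log under their respective
constraints (defaults 25 nodes / 40 edges before the index, 15 / 25
after) and joins the halves at the index class with patient-supported
entry and exit edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .eventlog import EventLog, Side
from .model import (
    ProcessModel,
    SizeConstraints,
    SuccessionUniverse,
    compiled_side,
    succession_universe,
    within_constraints,
)

__all__ = [
    "SearchParams",
    "DiscoveryResult",
    "BowTieResult",
    "initial_model",
    "neighborhood",
    "tabu_search",
    "discover_bowtie",
    "DEFAULT_PRE_CONSTRAINTS",
    "DEFAULT_POST_CONSTRAINTS",
]

DEFAULT_PRE_CONSTRAINTS = SizeConstraints(max_nodes=25, max_edges=40)
DEFAULT_POST_CONSTRAINTS = SizeConstraints(max_nodes=15, max_edges=25)


class SearchParams(BaseModel):
    """Metaheuristic configuration."""

    max_iterations: int = Field(default=500, ge=1)
    patience: int = Field(default=25, ge=1)
    tabu_tenure: int = Field(default=50, ge=0)
    neighbors_per_iteration: int = Field(default=30, ge=1)
    mc_sample_size: Optional[int] = Field(default=None, gt=0)  # None = exact scoring
    seed: int = 0
    hill_climb: bool = False  # strict mode: never move to a worse current solution
    node_weighting: Literal["support", "uniform"] = "support"


@dataclass
class DiscoveryResult:
    best_model: ProcessModel
    best_score: float
    iterations_run: int
    plateau_length_at_stop: int
    score_history: list[tuple[float, float]]  # (current, global) per iteration
    stop_reason: Literal["plateau", "budget"]

    def to_dict(self) -> dict:
        return {
            "best_model": self.best_model.to_dict(),
            "best_score": self.best_score,
            "iterations_run": self.iterations_run,
            "plateau_length_at_stop": self.plateau_length_at_stop,
            "score_history": [list(pair) for pair in self.score_history],
            "stop_reason": self.stop_reason,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DiscoveryResult":
        return cls(
            best_model=ProcessModel.from_dict(data["best_model"]),
            best_score=data["best_score"],
            iterations_run=data["iterations_run"],
            plateau_length_at_stop=data["plateau_length_at_stop"],
            score_history=[tuple(p) for p in data["score_history"]],
            stop_reason=data["stop_reason"],
        )


@dataclass
class BowTieResult:
    index_class: str
    pre: DiscoveryResult
    post: DiscoveryResult
    join_edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "index_class": self.index_class,
            "pre": self.pre.to_dict(),
            "post": self.post.to_dict(),
            "join_edges": [[a, b, n] for (a, b), n in sorted(self.join_edges.items())],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BowTieResult":
        return cls(
            index_class=data["index_class"],
            pre=DiscoveryResult.from_dict(data["pre"]),
            post=DiscoveryResult.from_dict(data["post"]),
            join_edges={(a, b): n for a, b, n in data["join_edges"]},
        )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed % 2**32)


def initial_model(
    universe: SuccessionUniverse,
    constraints: SizeConstraints,
    seed: int | np.random.Generator = 0,
    node_weighting: str = "support",
) -> ProcessModel:
    """Draw a random feasible starting model from the universe.

    Nodes are sampled without replacement, by default with probability
    proportional to their distinct-patient support; edges are then sampled
    among candidate edges internal to the chosen nodes, weighted by
    succession support.
    """
    if not universe.nodes:
        raise ValueError("cannot initialize from an empty universe")
    rng = _as_rng(seed)
    cand_nodes = sorted(universe.nodes)
    n_max = min(constraints.max_nodes, len(cand_nodes))
    m = int(rng.integers(1, n_max + 1))
    if node_weighting == "support":
        w = np.array([universe.nodes[c].patients for c in cand_nodes], dtype=float)
    else:
        w = np.ones(len(cand_nodes))
    p = w / w.sum()
    chosen_idx = rng.choice(len(cand_nodes), size=m, replace=False, p=p)
    nodes = frozenset(cand_nodes[i] for i in chosen_idx)

    internal = sorted(e for e in universe.edges if e[0] in nodes and e[1] in nodes)
    edges: frozenset[tuple[str, str]] = frozenset()
    if internal and constraints.max_edges > 0:
        e_max = min(constraints.max_edges, len(internal))
        k = int(rng.integers(0, e_max + 1))
        if k:
            ew = np.array([universe.edges[e].events for e in internal], dtype=float)
            ep = ew / ew.sum()
            idx = rng.choice(len(internal), size=k, replace=False, p=ep)
            edges = frozenset(internal[i] for i in idx)
    return ProcessModel(nodes, edges)


# Moves are cheap descriptors materialized on demand:
#   ("add_node", c) ("remove_node", c) ("add_edge", (a, b))
#   ("remove_edge", (a, b)) ("swap_node", (out, in))
Move = tuple


def enumerate_moves(
    model: ProcessModel,
    universe: SuccessionUniverse,
    constraints: SizeConstraints,
) -> list[Move]:
    """All feasible single edits of ``model``, in deterministic order."""
    moves: list[Move] = []
    outside = sorted(set(universe.nodes) - model.nodes)
    if model.n_nodes < constraints.max_nodes:
        moves.extend(("add_node", c) for c in outside)
    moves.extend(("remove_node", c) for c in sorted(model.nodes))
    if model.n_edges < constraints.max_edges:
        moves.extend(
            ("add_edge", e)
            for e in sorted(universe.edges)
            if e[0] in model.nodes and e[1] in model.nodes and e not in model.edges
        )
    moves.extend(("remove_edge", e) for e in sorted(model.edges))
    moves.extend(
        ("swap_node", (out, inn)) for out in sorted(model.nodes) for inn in outside
    )
    return moves


def apply_move(
    model: ProcessModel,
    move: Move,
    universe: SuccessionUniverse,
    constraints: SizeConstraints,
) -> ProcessModel:
    kind, arg = move
    if kind == "add_node":
        nodes = model.nodes | {arg}
        return ProcessModel(nodes, _attach(set(model.edges), nodes, arg, universe, constraints))
    if kind == "remove_node":
        nodes = model.nodes - {arg}
        edges = frozenset(e for e in model.edges if arg not in e)
        return ProcessModel(nodes, edges)
    if kind == "add_edge":
        return ProcessModel(model.nodes, model.edges | {arg})
    if kind == "remove_edge":
        return ProcessModel(model.nodes, model.edges - {arg})
    if kind == "swap_node":
        out, inn = arg
        nodes = (model.nodes - {out}) | {inn}
        edges = set(e for e in model.edges if out not in e)
        return ProcessModel(nodes, _attach(edges, nodes, inn, universe, constraints))
    raise ValueError(f"unknown move kind {kind!r}")


def _attach(
    edges: set,
    nodes: frozenset[str],
    inn: str,
    universe: SuccessionUniverse,
    constraints: SizeConstraints,
) -> frozenset:
    """Wire a newly added node with its highest-support candidate edges.

    A bare node only hurts replay (its events project but their
    successions are missing), so the add/swap moves immediately attach the
    strongest observed successions incident to the incoming node, within
    the edge budget; at the budget they may evict strictly weaker edges
    not incident to the incoming node.
    """
    attach = [
        e
        for e in universe.edges
        if (e[0] == inn or e[1] == inn) and e[0] in nodes and e[1] in nodes and e not in edges
    ]
    attach.sort(key=lambda e: (-universe.edges[e].events, e))
    removable = sorted(
        (e for e in edges if inn not in e),
        key=lambda e: (universe.edges[e].events if e in universe.edges else 0, e),
    )
    for e in attach:
        if len(edges) < constraints.max_edges:
            edges.add(e)
            continue
        if not removable:
            break
        weakest = removable[0]
        weakest_support = universe.edges[weakest].events if weakest in universe.edges else 0
        if universe.edges[e].events <= weakest_support:
            break
        edges.remove(weakest)
        removable.pop(0)
        edges.add(e)
    return frozenset(edges)


def neighborhood(
    model: ProcessModel,
    universe: SuccessionUniverse,
    constraints: SizeConstraints,
) -> list[ProcessModel]:
    """The full deduplicated neighbor set of ``model`` (all moves applied)."""
    seen: dict[tuple, ProcessModel] = {}
    for move in enumerate_moves(model, universe, constraints):
        nb = apply_move(model, move, universe, constraints)
        sig = nb.signature()
        if sig != model.signature():
            seen.setdefault(sig, nb)
    return [seen[s] for s in sorted(seen)]


def _neighbor_key(score: float, model: ProcessModel) -> tuple:
    # Best score first; ties prefer smaller edge count, then node count,
    # then lexicographic signature, keeping runs reproducible.
    return (-score, model.n_edges, model.n_nodes, model.signature())


def tabu_search(
    log: EventLog,
    side: Side,
    universe: SuccessionUniverse | None,
    constraints: SizeConstraints,
    params: SearchParams | None = None,
) -> DiscoveryResult:
    """Run one tabu search on one side of the log."""
    params = params or SearchParams()
    if universe is None:
        universe = succession_universe(log, side)
    if not universe.nodes:
        empty = ProcessModel.empty()
        return DiscoveryResult(empty, 0.0, 0, 0, [(0.0, 0.0)], "budget")

    rng = _as_rng(params.seed)
    comp = compiled_side(log, side)
    exact = params.mc_sample_size is None or params.mc_sample_size >= comp.n_traces
    score_cache: dict[tuple, float] = {}

    def make_sampler() -> Optional[np.ndarray]:
        if exact:
            return None
        sel = np.zeros(comp.n_traces, dtype=bool)
        sel[rng.choice(comp.n_traces, size=params.mc_sample_size, replace=False)] = True
        return sel

    def evaluate(model: ProcessModel, sel: Optional[np.ndarray]) -> float:
        if exact:
            sig = model.signature()
            if sig not in score_cache:
                score_cache[sig] = comp.score(model).score
            return score_cache[sig]
        return comp.score(model, sel).score

    sel = make_sampler()
    current = initial_model(universe, constraints, rng, params.node_weighting)
    cur_score = evaluate(current, sel)
    best, best_score = current, cur_score
    tabu: dict[tuple, int] = {current.signature(): params.tabu_tenure}
    history: list[tuple[float, float]] = [(cur_score, best_score)]
    plateau = 0
    iterations = 0
    stop_reason: str = "budget"

    for it in range(1, params.max_iterations + 1):
        iterations = it
        sel = make_sampler()
        moves = enumerate_moves(current, universe, constraints)
        if not moves:
            stop_reason = "budget"
            break
        if len(moves) > params.neighbors_per_iteration:
            idx = rng.choice(len(moves), size=params.neighbors_per_iteration, replace=False)
            moves = [moves[i] for i in sorted(idx)]
        candidates: dict[tuple, ProcessModel] = {}
        for mv in moves:
            nb = apply_move(current, mv, universe, constraints)
            sig = nb.signature()
            if sig != current.signature():
                candidates.setdefault(sig, nb)
        if not candidates:
            plateau += 1
            history.append((cur_score, best_score))
            if plateau >= params.patience:
                stop_reason = "plateau"
                break
            continue
        scored = [(evaluate(nb, sel), nb) for nb in candidates.values()]
        allowed = [
            (s, nb)
            for s, nb in scored
            if tabu.get(nb.signature(), 0) < it or s > best_score  # aspiration
        ]
        if not allowed:
            allowed = scored
        allowed.sort(key=lambda pair: _neighbor_key(*pair))
        nb_score, nb_model = allowed[0]

        if params.hill_climb and nb_score <= cur_score:
            plateau += 1
            history.append((cur_score, best_score))
            if plateau >= params.patience:
                stop_reason = "plateau"
                break
            continue

        current, cur_score = nb_model, nb_score
        tabu[current.signature()] = it + params.tabu_tenure
        if cur_score > best_score:
            best, best_score = current, cur_score
            plateau = 0
        else:
            plateau += 1
        history.append((cur_score, best_score))
        if plateau >= params.patience:
            stop_reason = "plateau"
            break
    else:
        stop_reason = "budget"

    return DiscoveryResult(
        best_model=best,
        best_score=best_score,
        iterations_run=iterations,
        plateau_length_at_stop=plateau,
        score_history=history,
        stop_reason=stop_reason,  # type: ignore[arg-type]
    )


def _join_supports(log: EventLog, pre_model: ProcessModel, post_model: ProcessModel) -> dict:
    """Patient-supported edges joining each half to the index node.

    For each patient the entry edge is taken from the last pre-index event
    whose class was discovered (projection semantics, as in replay) and
    the exit edge from the first discovered post-index event.
    """
    joins: dict[tuple[str, str], int] = {}
    for trace in log.traces:
        last_pre = next(
            (c for c in reversed(trace.classes("pre")) if c in pre_model.nodes), None
        )
        if last_pre is not None:
            key = (last_pre, log.index_class)
            joins[key] = joins.get(key, 0) + 1
        first_post = next((c for c in trace.classes("post") if c in post_model.nodes), None)
        if first_post is not None:
            key = (log.index_class, first_post)
            joins[key] = joins.get(key, 0) + 1
    return joins


def discover_bowtie(
    log: EventLog,
    pre_constraints: SizeConstraints | tuple[int, int] = DEFAULT_PRE_CONSTRAINTS,
    post_constraints: SizeConstraints | tuple[int, int] = DEFAULT_POST_CONSTRAINTS,
    params: SearchParams | None = None,
) -> BowTieResult:
    """Discover the pre-index and post-index halves of the bow-tie.

    The two halves are optimized independently under their own size
    constraints; the index class itself sits outside both node budgets and
    is reconnected afterwards through patient-weighted join edges.
    """
    params = params or SearchParams()
    if isinstance(pre_constraints, tuple):
        pre_constraints = SizeConstraints(*pre_constraints)
    if isinstance(post_constraints, tuple):
        post_constraints = SizeConstraints(*post_constraints)
    # Distinct deterministic streams for the two halves.
    pre_params = params.model_copy(update={"seed": params.seed})
    post_params = params.model_copy(update={"seed": params.seed + 1_000_003})
    pre = tabu_search(log, "pre", None, pre_constraints, pre_params)
    post = tabu_search(log, "post", None, post_constraints, post_params)
    joins = _join_supports(log, pre.best_model, post.best_model)
    return BowTieResult(index_class=log.index_class, pre=pre, post=post, join_edges=joins)
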