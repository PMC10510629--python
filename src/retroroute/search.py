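"""Best-first multistep retrosynthesis tree search.

The search maintains an AND-OR structure over molecules: each non-building-
block molecule, once expanded, owns a list of validated single-step
retrosyntheses (OR choices); each step requires all of its starting
materials (AND).  A *route* selects exactly one step for every expanded
non-BB molecule it reaches; its leaves are building blocks, unexpanded
(open) molecules, or dead ends.  A route is solved when every leaf is a
building block.

Each iteration enumerates routes from the current tree, ranks them by
route penalty score, selects the top unsolved routes, and expands their
open leaves with the single-step loop.  Results are memoized per molecule,
so a molecule occurring in many routes is predicted once and the outcome is
shared wherever it appears.  The search stops once a minimum number of
solved routes is collected, the iteration budget is exhausted, or no
expandable leaf remains.  Cycles are suppressed during enumeration: a step
whose SM set contains an ancestor of its position is excluded from that
route, so no molecule repeats along a root-to-leaf path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from retroroute.centers import TagTemplate
from retroroute.loop import LoopConfig, SingleStepResult, run_ttl, with_iteration
from retroroute.predictors import ModelSuite
from retroroute.scoring import (
    BuildingBlockSet,
    ComplexityScorer,
    ScoreConfig,
    cscore,
    heuristic_complexity,
    rpscore,
)
from retroroute.smiles import Molecule, canonicalize, parse_tagged

log = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "MoleculeEntry",
    "SearchState",
    "Route",
    "SearchReport",
    "enumerate_routes",
    "rank_routes",
    "search",
    "report_to_json",
    "report_from_json",
]

BUILDING_BLOCK = "building_block"
OPEN = "open"
EXPANDED = "expanded"
DEAD = "dead"


@dataclass(frozen=True)
class SearchConfig:
    """Search budgets and widths.

    ``expansion_width``: how many top-ranked unsolved routes feed each
    expansion round.  ``min_solved`` / ``max_iterations``: stop criteria.
    ``route_cap``: enumeration bound guarding against combinatorial
    explosion.  ``per_molecule_cap``: validated steps kept per molecule.
    """

    expansion_width: int = 20
    min_solved: int = 10
    max_iterations: int = 10
    route_cap: int = 10000
    per_molecule_cap: int = 50


@dataclass
class MoleculeEntry:
    """Per-molecule node state shared across the whole tree (the memo)."""

    molecule: Molecule
    status: str
    steps: list[SingleStepResult] = field(default_factory=list)


@dataclass
class Route:
    """One resolved selection of steps rooted at the target."""

    steps: tuple[SingleStepResult, ...]
    leaves: tuple[str, ...]
    open_leaves: tuple[str, ...]
    dead: bool
    solved: bool
    rpscore: float = 1.0
    cscore: float = 1.0
    rank: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def key(self) -> tuple:
        return tuple(sorted(s.key for s in self.steps))


@dataclass
class SearchState:
    """The search tree: root molecule plus the per-molecule memo table."""

    root: Molecule
    entries: dict[str, MoleculeEntry]
    iteration: int = 0


def _leaf_route(mol: str, status: str) -> tuple:
    open_leaves = (mol,) if status == OPEN else ()
    dead = status == DEAD
    return ((), (mol,), open_leaves, dead)


def enumerate_routes(state: SearchState, cap: int = 10000) -> tuple[list[Route], bool]:
    """All distinct step-selection combinations, up to *cap* routes.

    Depth-first over per-molecule step choices (already confidence-ordered),
    excluding steps that would revisit an ancestor molecule.  An expanded
    molecule whose every step is excluded by the cycle rule becomes a dead
    leaf for that route.  Returns (routes, truncated).
    """
    entries = state.entries
    bb_set = {s for s, e in entries.items() if e.status == BUILDING_BLOCK}
    budget = [cap]

    def expand(mol: str, ancestors: frozenset[str]):
        entry = entries[mol]
        if entry.status in (BUILDING_BLOCK, OPEN, DEAD):
            yield _leaf_route(mol, entry.status)
            return
        usable = [
            s
            for s in entry.steps
            if not any(m.smiles in ancestors or m.smiles == mol for m in s.sm_set)
        ]
        if not usable:
            yield _leaf_route(mol, DEAD)
            return
        nxt = ancestors | {mol}
        for step in usable:
            for combo in _combine([m.smiles for m in step.sm_set], nxt):
                sub_steps, leaves, open_leaves, dead = combo
                yield ((step,) + sub_steps, leaves, open_leaves, dead)

    def _combine(mols: list[str], ancestors: frozenset[str]):
        if not mols:
            yield ((), (), (), False)
            return
        head, rest = mols[0], mols[1:]
        for h_steps, h_leaves, h_open, h_dead in expand(head, ancestors):
            for r_steps, r_leaves, r_open, r_dead in _combine(rest, ancestors):
                yield (
                    h_steps + r_steps,
                    h_leaves + r_leaves,
                    h_open + r_open,
                    h_dead or r_dead,
                )

    routes: list[Route] = []
    truncated = False
    for steps, leaves, open_leaves, dead in expand(state.root.smiles, frozenset()):
        if budget[0] <= 0:
            truncated = True
            break
        budget[0] -= 1
        solved = not dead and all(leaf in bb_set for leaf in leaves)
        routes.append(
            Route(
                steps=steps,
                leaves=leaves,
                open_leaves=open_leaves,
                dead=dead,
                solved=solved,
            )
        )
    return routes, truncated


def _score_route(
    route: Route,
    score_cfg: ScoreConfig,
    bb: BuildingBlockSet,
    scorer: ComplexityScorer,
) -> None:
    # a zero-step route (bare root) has nothing to penalize: neutral scores
    route.rpscore = rpscore(route.steps, score_cfg, bb, scorer) if route.steps else 1.0
    route.cscore = cscore(route.steps) if route.steps else 1.0


def rank_routes(
    routes: Sequence[Route],
    score_cfg: ScoreConfig = ScoreConfig(),
    bb: BuildingBlockSet = BuildingBlockSet(frozenset()),
    scorer: ComplexityScorer = heuristic_complexity,
) -> tuple[list[Route], list[Route]]:
    """Partition into (solved, unsolved), each sorted by descending RPScore,
    ties broken by fewer steps then lexicographic route key."""
    for route in routes:
        _score_route(route, score_cfg, bb, scorer)
    ordered = sorted(routes, key=lambda r: (-r.rpscore, r.n_steps, r.key))
    solved = [r for r in ordered if r.solved]
    unsolved = [r for r in ordered if not r.solved]
    for rank, r in enumerate(solved, 1):
        r.rank = rank
    for rank, r in enumerate(unsolved, 1):
        r.rank = rank
    return solved, unsolved


@dataclass
class SearchReport:
    """Outcome of one multistep search."""

    target: Molecule
    solved_routes: list[Route]
    unsolved_routes: list[Route]
    iterations: int
    ttl_calls: int
    exhausted: bool
    truncated: bool
    best_solved_trace: list[float | None]
    trivially_solved: bool = False  # target was itself a building block

    @property
    def solved(self) -> bool:
        return self.trivially_solved or bool(self.solved_routes)


def search(
    target: Molecule,
    models: ModelSuite,
    bb: BuildingBlockSet,
    cfg: SearchConfig = SearchConfig(),
    loop_cfg: LoopConfig = LoopConfig(),
    score_cfg: ScoreConfig = ScoreConfig(),
    scorer: ComplexityScorer = heuristic_complexity,
    templates: Sequence[TagTemplate] = (),
) -> SearchReport:
    """Run the full best-first multistep search for *target*.

    Budget exhaustion with zero solved routes is reported, not raised.
    """
    if target in bb:
        return SearchReport(
            target=target,
            solved_routes=[],
            unsolved_routes=[],
            iterations=0,
            ttl_calls=0,
            exhausted=False,
            truncated=False,
            best_solved_trace=[],
            trivially_solved=True,
        )

    state = SearchState(root=target, entries={target.smiles: MoleculeEntry(target, OPEN)})
    solved_ledger: dict[tuple, Route] = {}
    best_trace: list[float | None] = []
    ttl_calls = 0
    exhausted = False
    truncated = False
    unsolved_final: list[Route] = []
    iteration = 0

    def ledger_update() -> list[Route]:
        nonlocal truncated
        routes, trunc = enumerate_routes(state, cfg.route_cap)
        truncated = truncated or trunc
        solved, unsolved = rank_routes(routes, score_cfg, bb, scorer)
        for route in solved:
            solved_ledger.setdefault(route.key, route)
        # dead routes can never be solved: drop them from the unsolved ledger
        return [r for r in unsolved if not r.dead and r.open_leaves]

    while iteration < cfg.max_iterations:
        iteration += 1
        state.iteration = iteration
        viable = ledger_update()
        best_trace.append(
            max((r.rpscore for r in solved_ledger.values()), default=None)
        )
        if len(solved_ledger) >= cfg.min_solved:
            unsolved_final = viable
            break
        selected = viable[: cfg.expansion_width]
        frontier = sorted(
            {
                leaf
                for route in selected
                for leaf in route.open_leaves
                if state.entries[leaf].status == OPEN
            }
        )
        if not frontier:
            exhausted = True
            unsolved_final = viable
            break
        for smiles in frontier:
            entry = state.entries[smiles]
            results = run_ttl(entry.molecule, loop_cfg, models, templates)
            ttl_calls += 1
            kept = [
                with_iteration(r, iteration)
                for r in results[: cfg.per_molecule_cap]
            ]
            entry.steps = kept
            entry.status = EXPANDED if kept else DEAD
            for step in kept:
                for m in step.sm_set:
                    if m.smiles not in state.entries:
                        status = BUILDING_BLOCK if m in bb else OPEN
                        state.entries[m.smiles] = MoleculeEntry(m, status)
        log.info(
            "iteration %d: expanded %d molecules, %d solved routes so far",
            iteration,
            len(frontier),
            len(solved_ledger),
        )
    else:
        # budget spent: account for the final iteration's expansions
        unsolved_final = ledger_update()
        best_trace.append(
            max((r.rpscore for r in solved_ledger.values()), default=None)
        )

    solved_sorted, _ = rank_routes(
        list(solved_ledger.values()), score_cfg, bb, scorer
    )
    return SearchReport(
        target=target,
        solved_routes=solved_sorted,
        unsolved_routes=unsolved_final,
        iterations=iteration,
        ttl_calls=ttl_calls,
        exhausted=exhausted,
        truncated=truncated,
        best_solved_trace=best_trace,
    )


# --------------------------------------------------------------------------
# JSON round-trip


def _step_to_dict(step: SingleStepResult) -> dict:
    return {
        "product": step.product.smiles,
        "sm": [m.smiles for m in step.sm_set],
        "reagents": [m.smiles for m in step.reagent_set],
        "confidence": step.confidence,
        "site": step.site.serialized(),
        "provenance": sorted(step.provenance),
        "discovered_at_iteration": step.discovered_at_iteration,
    }


def _step_from_dict(d: dict) -> SingleStepResult:
    return SingleStepResult(
        product=canonicalize(d["product"]),
        sm_set=tuple(canonicalize(s) for s in d["sm"]),
        reagent_set=tuple(canonicalize(s) for s in d["reagents"]),
        confidence=d["confidence"],
        site=parse_tagged(d["site"]),
        provenance=frozenset(d["provenance"]),
        discovered_at_iteration=d["discovered_at_iteration"],
    )


def _route_to_dict(route: Route) -> dict:
    return {
        "rank": route.rank,
        "rpscore": route.rpscore,
        "cscore": route.cscore,
        "n_steps": route.n_steps,
        "solved": route.solved,
        "dead": route.dead,
        "leaves": list(route.leaves),
        "open_leaves": list(route.open_leaves),
        "steps": [_step_to_dict(s) for s in route.steps],
    }


def _route_from_dict(d: dict) -> Route:
    return Route(
        steps=tuple(_step_from_dict(s) for s in d["steps"]),
        leaves=tuple(d["leaves"]),
        open_leaves=tuple(d["open_leaves"]),
        dead=d["dead"],
        solved=d["solved"],
        rpscore=d["rpscore"],
        cscore=d["cscore"],
        rank=d["rank"],
    )


def report_to_json(report: SearchReport, path=None) -> str:
    payload = {
        "target": report.target.smiles,
        "solved": report.solved,
        "trivially_solved": report.trivially_solved,
        "iterations": report.iterations,
        "ttl_calls": report.ttl_calls,
        "exhausted": report.exhausted,
        "truncated": report.truncated,
        "best_solved_trace": report.best_solved_trace,
        "solved_routes": [_route_to_dict(r) for r in report.solved_routes],
        "unsolved_routes": [_route_to_dict(r) for r in report.unsolved_routes],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def report_from_json(text: str) -> SearchReport:
    d = json.loads(text)
    return SearchReport(
        target=canonicalize(d["target"]),
        solved_routes=[_route_from_dict(r) for r in d["solved_routes"]],
        unsolved_routes=[_route_from_dict(r) for r in d["unsolved_routes"]],
        iterations=d["iterations"],
        ttl_calls=d["ttl_calls"],
        exhausted=d["exhausted"],
        truncated=d["truncated"],
        best_solved_trace=d["best_solved_trace"],
        trivially_solved=d["trivially_solved"],
    )
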