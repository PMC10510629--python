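"""Multistep best-first tree search: enumeration, ranking, memoization."""

import itertools
import random

import pytest

import retroroute.search as search_mod
from retroroute.loop import SingleStepResult
from retroroute.scoring import BuildingBlockSet, ScoreConfig
from retroroute.search import (
    BUILDING_BLOCK,
    EXPANDED,
    OPEN,
    MoleculeEntry,
    Route,
    SearchConfig,
    SearchState,
    enumerate_routes,
    rank_routes,
    report_from_json,
    report_to_json,
    search,
)
from retroroute.smiles import TaggedMolecule, canonicalize
from retroroute.toyworld import WorldSpec, generate_world, mock_suite


def chain(i):
    """Distinct dummy molecules: linear alkanes of increasing length."""
    return canonicalize("C" * (i + 1))


def make_step(product, children, confidence=0.9):
    return SingleStepResult(
        product=product,
        sm_set=tuple(sorted(children)),
        reagent_set=(),
        confidence=confidence,
        site=TaggedMolecule.create(product, [0]),
        provenance=frozenset({"systematic"}),
    )


def build_state(n_mols, rng, p_bb=0.5):
    """A random acyclic AND-OR tree over *n_mols* dummy molecules.

    Children always have larger indices than their product, so the graph is
    a DAG by construction.
    """
    mols = [chain(i) for i in range(n_mols)]
    entries = {}
    for i, m in enumerate(mols):
        if i >= n_mols - 3 or rng.random() < 0.35:
            status = BUILDING_BLOCK if rng.random() < p_bb else OPEN
            entries[m.smiles] = MoleculeEntry(m, status)
        else:
            steps = []
            for _ in range(rng.randint(1, 3)):
                k = rng.randint(1, 2)
                children = rng.sample(range(i + 1, n_mols), k)
                steps.append(
                    make_step(m, [mols[c] for c in children],
                              confidence=round(rng.uniform(0.3, 1.0), 3))
                )
            # dedup on sm key as the loop would
            seen, kept = set(), []
            for s in steps:
                if s.sm_key not in seen:
                    seen.add(s.sm_key)
                    kept.append(s)
            entries[m.smiles] = MoleculeEntry(m, EXPANDED, kept)
    return SearchState(root=mols[0], entries=entries)


def brute_force_route_keys(state):
    """Independent oracle: exhaustive recursive enumeration of step choices."""
    entries = state.entries

    def expand(smiles):
        entry = entries[smiles]
        if entry.status != EXPANDED:
            return [()]
        out = []
        for step in entry.steps:
            child_choices = [expand(m.smiles) for m in step.sm_set]
            for combo in itertools.product(*child_choices):
                out.append((step.key,) + tuple(k for sub in combo for k in sub))
        return out

    return {tuple(sorted(keys)) for keys in expand(state.root.smiles)}


class TestEnumerateRoutes:
    def test_matches_brute_force_on_random_trees(self):
        rng = random.Random(123)
        for trial in range(12):
            state = build_state(rng.randint(5, 30), rng)
            routes, truncated = enumerate_routes(state, cap=100000)
            assert not truncated
            assert {r.key for r in routes} == brute_force_route_keys(state)

    def test_linear_tree_single_route(self):
        mols = [chain(i) for i in range(3)]
        entries = {
            mols[0].smiles: MoleculeEntry(mols[0], EXPANDED, [make_step(mols[0], [mols[1]])]),
            mols[1].smiles: MoleculeEntry(mols[1], EXPANDED, [make_step(mols[1], [mols[2]])]),
            mols[2].smiles: MoleculeEntry(mols[2], BUILDING_BLOCK),
        }
        routes, _ = enumerate_routes(SearchState(root=mols[0], entries=entries))
        assert len(routes) == 1
        assert routes[0].solved and routes[0].n_steps == 2

    def test_two_alternatives_give_two_routes(self):
        mols = [chain(i) for i in range(3)]
        entries = {
            mols[0].smiles: MoleculeEntry(
                mols[0],
                EXPANDED,
                [make_step(mols[0], [mols[1]]), make_step(mols[0], [mols[2]])],
            ),
            mols[1].smiles: MoleculeEntry(mols[1], BUILDING_BLOCK),
            mols[2].smiles: MoleculeEntry(mols[2], BUILDING_BLOCK),
        }
        routes, _ = enumerate_routes(SearchState(root=mols[0], entries=entries))
        assert len(routes) == 2
        assert all(r.solved for r in routes)

    def test_cap_truncates(self):
        rng = random.Random(7)
        state = build_state(25, rng)
        full, _ = enumerate_routes(state, cap=100000)
        if len(full) > 3:
            some, truncated = enumerate_routes(state, cap=3)
            assert truncated and len(some) == 3

    def test_cycle_suppression(self):
        a, b, c = chain(0), chain(1), chain(2)
        entries = {
            a.smiles: MoleculeEntry(a, EXPANDED, [make_step(a, [b])]),
            b.smiles: MoleculeEntry(b, EXPANDED,
                                    [make_step(b, [a]), make_step(b, [c])]),
            c.smiles: MoleculeEntry(c, BUILDING_BLOCK),
        }
        routes, _ = enumerate_routes(SearchState(root=a, entries=entries))
        # the b -> a step would revisit the root: excluded, one solved route
        assert len(routes) == 1
        assert routes[0].solved
        for route in routes:
            mols_on_path = [s.product.smiles for s in route.steps]
            assert len(mols_on_path) == len(set(mols_on_path))


class TestRankRoutes:
    def _route(self, steps):
        return Route(steps=tuple(steps), leaves=(), open_leaves=(),
                     dead=False, solved=True)

    def test_descending_rpscore(self):
        bb = BuildingBlockSet.from_smiles(["C", "CC", "CCC", "CCCC"])
        good = self._route([make_step(chain(3), [chain(0)], confidence=1.0)])
        bad = self._route([make_step(chain(3), [chain(1)], confidence=0.3)])
        solved, unsolved = rank_routes([bad, good], ScoreConfig(), bb)
        assert solved[0] is good and solved[0].rank == 1
        assert unsolved == []

    def test_tie_broken_by_fewer_steps(self):
        bb = BuildingBlockSet.from_smiles(["C", "CC", "CCC", "CCCC", "CCCCC"])
        cfg = ScoreConfig(step_penalty=1.0)
        two = self._route(
            [make_step(chain(4), [chain(0)], 0.6), make_step(chain(0), [chain(1)], 0.5)]
        )
        three = self._route(
            [make_step(chain(4), [chain(0)], 0.5),
             make_step(chain(0), [chain(1)], 0.6),
             make_step(chain(1), [chain(2)], 1.0)]
        )
        solved, _ = rank_routes([three, two], cfg, bb)
        assert solved[0].rpscore == pytest.approx(solved[1].rpscore)
        assert solved[0] is two

    def test_empty_input(self):
        assert rank_routes([]) == ([], [])


class TestSearch:
    def test_depth_two_target_solved_to_building_blocks(self, world, suite, bb):
        target = next(t for t, n in world.targets if n == 2)
        report = search(canonicalize(target), suite, bb,
                        SearchConfig(max_iterations=8, min_solved=4))
        assert report.solved
        best = report.solved_routes[0]
        assert best.n_steps == 2
        assert all(leaf in bb for leaf in best.leaves)

    def test_target_in_bb_is_trivially_solved(self, world, suite, bb):
        report = search(canonicalize(world.building_blocks[0]), suite, bb)
        assert report.trivially_solved and report.solved
        assert report.ttl_calls == 0

    def test_zero_iteration_budget(self, world, suite, bb):
        target = canonicalize(world.targets[0][0])
        report = search(target, suite, bb, SearchConfig(max_iterations=0))
        assert report.iterations == 0
        assert report.solved_routes == []
        assert len(report.unsolved_routes) == 1
        assert report.unsolved_routes[0].n_steps == 0

    def test_exhaustion_reported_not_raised(self, world, bb):
        # full forward noise: nothing ever validates, search dead-ends
        noisy = mock_suite(world, noise=1.0)
        target = canonicalize(world.targets[0][0])
        report = search(target, noisy, bb, SearchConfig(max_iterations=5))
        assert not report.solved
        assert report.exhausted or report.iterations == 5

    def test_memoization_one_ttl_call_per_molecule(self, world, suite, bb, monkeypatch):
        calls = []
        real = search_mod.run_ttl

        def counting(p, *args, **kwargs):
            calls.append(p.smiles)
            return real(p, *args, **kwargs)

        monkeypatch.setattr(search_mod, "run_ttl", counting)
        target = next(t for t, n in world.targets if n >= 2)
        report = search(canonicalize(target), suite, bb,
                        SearchConfig(max_iterations=8))
        assert len(calls) == len(set(calls)), "a molecule was expanded twice"
        assert report.ttl_calls == len(calls)

    def test_anytime_best_solved_rpscore_non_decreasing(self, world, suite, bb):
        target = next(t for t, n in world.targets if n >= 2)
        report = search(canonicalize(target), suite, bb,
                        SearchConfig(max_iterations=8, min_solved=50))
        seen = [x for x in report.best_solved_trace if x is not None]
        assert all(b >= a - 1e-12 for a, b in zip(seen, seen[1:]))

    def test_steps_carry_discovery_iteration(self, world, suite, bb):
        target = next(t for t, n in world.targets if n >= 2)
        report = search(canonicalize(target), suite, bb,
                        SearchConfig(max_iterations=8))
        for route in report.solved_routes:
            for step in route.steps:
                assert 1 <= step.discovered_at_iteration <= report.iterations

    def test_top_route_achieves_ground_truth_depth_on_seeded_worlds(self):
        hits = 0
        for seed in range(4):
            w = generate_world(WorldSpec(seed=100 + seed, n_building_blocks=12,
                                         max_depth=2, max_reactions_per_depth=50))
            suite = mock_suite(w)
            bbset = BuildingBlockSet.from_smiles(w.building_blocks)
            target, n_min = max(w.targets, key=lambda t: t[1])
            report = search(canonicalize(target), suite, bbset,
                            SearchConfig(max_iterations=10, min_solved=6))
            assert report.solved
            if report.solved_routes[0].n_steps == n_min:
                hits += 1
        assert hits >= 3


def test_report_json_round_trip(world, suite, bb):
    target = next(t for t, n in world.targets if n >= 2)
    report = search(canonicalize(target), suite, bb, SearchConfig(max_iterations=6))
    text = report_to_json(report)
    back = report_from_json(text)
    assert back.target == report.target
    assert back.solved_routes == report.solved_routes
    assert back.unsolved_routes == report.unsolved_routes
    assert back.best_solved_trace == report.best_solved_trace
    assert back.ttl_calls == report.ttl_calls
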