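"""Deterministic rule-based toy chemistry for end-to-end testing.

The generator builds a closed molecule universe: a set of small mono- and
bifunctional building blocks, a handful of coupling rules (amide, ester,
ether formation), and the reaction corpus obtained by exhaustively applying
the rules up to a depth limit.  Every generated product is therefore
reachable from building blocks, and the minimal number of steps to reach it
is known exactly — this ground truth is what the tree-search tests consume.

The same world powers mock implementations of the four predictor contracts:
the retro model inverts recorded reactions at the tagged site, the reagent
model returns the rule's reagent set, the forward model replays the rule
(optionally corrupted at a configurable noise rate to exercise validation
filtering), and the tagger proposes the recorded reaction centers.  All of
it is pure and seed-deterministic.

This is not chemistry: rules are graph edits over a small motif alphabet,
confidences are rule constants.  The package's orchestration and search are
what is under test, not reactivity learning.
"""

from __future__ import annotations

import functools
import hashlib
import json
import random
from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from retroroute.centers import tag_product
from retroroute.predictors import ScoredPrediction, ScoredTag
from retroroute.smiles import (
    MappedReaction,
    Molecule,
    TaggedMolecule,
    canonicalize,
    reaction_from_smiles,
    write_smiles_file,
)

__all__ = [
    "ToyRule",
    "ToyReaction",
    "WorldSpec",
    "World",
    "default_rules",
    "generate_world",
    "write_world",
    "random_molecules",
    "MockRetro",
    "MockReagent",
    "MockForward",
    "MockTagger",
    "mock_suite",
]


@dataclass(frozen=True)
class ToyRule:
    """A forward bond-formation rule between two functional-group motifs."""

    rule_id: str
    smarts: str  # mapped two-reactant forward reaction SMARTS
    reagents: tuple[str, ...]
    base_confidence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.base_confidence <= 1.0:
            raise ValueError("base_confidence must be in (0, 1]")


def default_rules() -> tuple[ToyRule, ...]:
    return (
        ToyRule(
            rule_id="amide",
            smarts="[C:1](=[O:2])[OX2H1].[NX3;H2;!$(N=*):3]>>[C:1](=[O:2])[N:3]",
            reagents=("CCN(CC)CC",),
            base_confidence=0.9,
        ),
        ToyRule(
            rule_id="ester",
            smarts="[C:1](=[O:2])[OX2H1].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]",
            reagents=("OS(=O)(=O)O",),
            base_confidence=0.8,
        ),
        ToyRule(
            rule_id="ether",
            smarts="[CX4:1][OX2H1:2].[Br][CX4:3]>>[C:1][O:2][C:3]",
            reagents=("O=C(O)O",),
            base_confidence=0.7,
        ),
    )


# candidate building blocks: alkyl/aryl scaffolds with acid, amine, alcohol
# or bromide heads; bifunctional entries let products react further
_BB_POOL = [
    "CC(=O)O", "CCC(=O)O", "CCCC(=O)O", "CC(C)C(=O)O", "O=C(O)c1ccccc1",
    "Cc1ccccc1C(=O)O", "OC(=O)CC(=O)O",
    "CN", "CCN", "CCCN", "CC(C)N", "Nc1ccccc1", "NCc1ccccc1",
    "CO", "CCO", "CCCO", "CC(C)O", "OCc1ccccc1", "C[C@H](O)CC",
    "CBr", "CCBr", "CCCBr", "BrCc1ccccc1",
    "NCCO", "NCCCO", "OCCO", "OCCCO", "OCCC(=O)O", "NCCC(=O)O",
    "OCC(C)O", "BrCCO", "BrCCCO", "NCCN", "OC[C@@H](N)C",
]


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a generated toy universe."""

    seed: int = 0
    n_building_blocks: int = 20
    rules: tuple[ToyRule, ...] = field(default_factory=default_rules)
    max_depth: int = 2
    max_reactions_per_depth: int = 120
    max_heavy_atoms: int = 30


@dataclass(frozen=True)
class ToyReaction:
    """One recorded forward application of a rule."""

    rule_id: str
    sm: tuple[str, ...]  # canonical, sorted
    reagents: tuple[str, ...]
    product: str  # canonical, map-free
    mapped_rsmi: str
    depth: int
    base_confidence: float

    @property
    def sm_key(self) -> tuple[str, ...]:
        return self.sm


def _map_product(
    rxn: AllChem.ChemicalReaction,
    product: Chem.Mol,
    reactants: Sequence[Chem.Mol],
    tmpl_map_to_reactant: dict[int, int],
) -> Chem.Mol | None:
    """Restore original reactant atom maps on a RunReactants product."""
    try:
        Chem.SanitizeMol(product)
    except Exception:  # noqa: BLE001 - invalid valence etc.: skip this outcome
        return None
    for atom in product.GetAtoms():
        if atom.HasProp("old_mapno"):
            tmpl_map = atom.GetIntProp("old_mapno")
            reactant = reactants[tmpl_map_to_reactant[tmpl_map]]
            orig = reactant.GetAtomWithIdx(atom.GetIntProp("react_atom_idx"))
            atom.SetAtomMapNum(orig.GetAtomMapNum())
    return product


@functools.lru_cache(maxsize=64)
def _compiled(smarts: str) -> AllChem.ChemicalReaction:
    return AllChem.ReactionFromSmarts(smarts)


def _apply_rule(rule: ToyRule, a: str, b: str) -> list[tuple[str, str]]:
    """Forward-apply *rule* to canonical SMILES (a, b).

    Returns (product canonical SMILES, mapped reaction SMILES) per distinct
    product, deterministic order.
    """
    rxn = _compiled(rule.smarts)
    mol_a = Chem.MolFromSmiles(a)
    mol_b = Chem.MolFromSmiles(b)
    if mol_a is None or mol_b is None:
        return []
    offset = 0
    for mol in (mol_a, mol_b):
        for atom in mol.GetAtoms():
            offset += 1
            atom.SetAtomMapNum(offset)
    tmpl_map_to_reactant = {}
    for ri in range(rxn.GetNumReactantTemplates()):
        for atom in rxn.GetReactantTemplate(ri).GetAtoms():
            if atom.GetAtomMapNum():
                tmpl_map_to_reactant[atom.GetAtomMapNum()] = ri
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for product_set in rxn.RunReactants((mol_a, mol_b)):
        if len(product_set) != 1:
            continue
        mapped = _map_product(rxn, product_set[0], (mol_a, mol_b), tmpl_map_to_reactant)
        if mapped is None:
            continue
        plain = canonicalize(Chem.MolToSmiles(mapped)).smiles
        if "." in plain or plain in seen:
            continue
        seen.add(plain)
        rsmi = (
            f"{Chem.MolToSmiles(mol_a)}.{Chem.MolToSmiles(mol_b)}"
            f">{'.'.join(rule.reagents)}>{Chem.MolToSmiles(mapped)}"
        )
        out.append((plain, rsmi))
    out.sort()
    return out


@dataclass
class World:
    """A generated toy universe with its reaction corpus and ground truth."""

    spec: WorldSpec
    building_blocks: list[str]
    reactions: list[ToyReaction]
    min_steps: dict[str, int]  # canonical SMILES -> minimal route length

    def __post_init__(self) -> None:
        self.by_product: dict[str, list[ToyReaction]] = {}
        self.by_sm_key: dict[tuple[str, ...], list[ToyReaction]] = {}
        for rxn in self.reactions:
            self.by_product.setdefault(rxn.product, []).append(rxn)
            self.by_sm_key.setdefault(rxn.sm_key, []).append(rxn)
        self._tagged: dict[str, list[tuple[TaggedMolecule, ToyReaction]]] = {}

    @property
    def targets(self) -> list[tuple[str, int]]:
        """Products outside the BB set with their minimal route length."""
        bb = set(self.building_blocks)
        return sorted(
            (s, n) for s, n in self.min_steps.items() if n > 0 and s not in bb
        )

    def corpus(self) -> list[MappedReaction]:
        return [
            reaction_from_smiles(r.mapped_rsmi, source_id=f"{r.rule_id}:{i}")
            for i, r in enumerate(self.reactions)
        ]

    def tagged_reactions(
        self, product: str
    ) -> list[tuple[TaggedMolecule, ToyReaction]]:
        """Recorded reactions for *product*, each with its tagged product."""
        if product not in self._tagged:
            entries = []
            for rxn in self.by_product.get(product, []):
                tagged = tag_product(
                    reaction_from_smiles(rxn.mapped_rsmi, source_id=rxn.rule_id)
                )
                if tagged is not None:
                    entries.append((tagged, rxn))
            self._tagged[product] = entries
        return self._tagged[product]


def generate_world(spec: WorldSpec) -> World:
    """Generate the closed toy universe for *spec*; deterministic per seed."""
    rng = random.Random(spec.seed)
    pool = sorted({canonicalize(s).smiles for s in _BB_POOL})
    n = min(spec.n_building_blocks, len(pool))
    bbs = sorted(rng.sample(pool, n))

    universe = list(bbs)
    frontier = list(bbs)
    reactions: list[ToyReaction] = []
    known_products: set[str] = set(bbs)

    def matches_template(smiles: str, rule: ToyRule, which: int) -> bool:
        mol = Chem.MolFromSmiles(smiles)
        tmpl = _compiled(rule.smarts).GetReactantTemplate(which)
        return mol is not None and mol.HasSubstructMatch(tmpl)

    for depth in range(1, spec.max_depth + 1):
        new_rxns: list[ToyReaction] = []
        frontier_set = set(frontier)
        for rule in spec.rules:
            side_a = [s for s in universe if matches_template(s, rule, 0)]
            side_b = [s for s in universe if matches_template(s, rule, 1)]
            for a in side_a:
                for b in side_b:
                    # at least one partner from the previous frontier, so each
                    # depth pass contributes genuinely new material
                    if a not in frontier_set and b not in frontier_set:
                        continue
                    for product, rsmi in _apply_rule(rule, a, b):
                        mol = Chem.MolFromSmiles(product)
                        if mol.GetNumAtoms() > spec.max_heavy_atoms:
                            continue
                        new_rxns.append(
                            ToyReaction(
                                rule_id=rule.rule_id,
                                sm=tuple(sorted((a, b))),
                                reagents=tuple(
                                    canonicalize(r).smiles for r in rule.reagents
                                ),
                                product=product,
                                mapped_rsmi=rsmi,
                                depth=depth,
                                base_confidence=rule.base_confidence,
                            )
                        )
        # one recorded outcome per SM-set key, so the forward lookup is a
        # function and round-trip validation is consistent by construction;
        # the most confident rule wins, deterministically
        new_rxns.sort(
            key=lambda r: (-r.base_confidence, r.rule_id, r.sm, r.product)
        )
        recorded = {x.sm for x in reactions}
        seen_keys: set[tuple] = set()
        deduped = []
        for rxn in new_rxns:
            if rxn.sm not in seen_keys and rxn.sm not in recorded:
                seen_keys.add(rxn.sm)
                deduped.append(rxn)
        deduped.sort(key=lambda r: (r.rule_id, r.sm, r.product))
        deduped = deduped[: spec.max_reactions_per_depth]
        reactions.extend(deduped)
        frontier = sorted(
            {r.product for r in deduped if r.product not in known_products}
        )
        known_products.update(frontier)
        universe = sorted(set(universe) | set(frontier))
        if not frontier:
            break
    if not reactions:
        raise ValueError("rule set generated no reactions from the building blocks")

    # minimal route length by relaxation over recorded reactions
    min_steps: dict[str, int] = {bb: 0 for bb in bbs}
    changed = True
    while changed:
        changed = False
        for rxn in reactions:
            if all(s in min_steps for s in rxn.sm):
                cost = 1 + sum(min_steps[s] for s in rxn.sm)
                if cost < min_steps.get(rxn.product, 10**9):
                    min_steps[rxn.product] = cost
                    changed = True
    return World(spec=spec, building_blocks=bbs, reactions=reactions, min_steps=min_steps)


def write_world(world: World, outdir) -> None:
    """Write bb.smi, corpus.rsmi, targets.smi and world.json into *outdir*."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_smiles_file(os.path.join(outdir, "bb.smi"), world.building_blocks)
    with open(os.path.join(outdir, "corpus.rsmi"), "w") as fh:
        for rxn in world.reactions:
            fh.write(rxn.mapped_rsmi + "\n")
    targets = world.targets
    write_smiles_file(
        os.path.join(outdir, "targets.smi"),
        [t for t, _ in targets],
        ids=[f"min_steps={n}" for _, n in targets],
    )
    meta = {
        "seed": world.spec.seed,
        "n_building_blocks": len(world.building_blocks),
        "max_depth": world.spec.max_depth,
        "rules": [r.rule_id for r in world.spec.rules],
        "n_reactions": len(world.reactions),
        "min_steps": world.min_steps,
    }
    with open(os.path.join(outdir, "world.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# mock predictor implementations


def _mols(smiles: Sequence[str]) -> tuple[Molecule, ...]:
    return tuple(canonicalize(s) for s in smiles)


class MockRetro:
    """Inverts recorded world reactions at the tagged site."""

    def __init__(self, world: World):
        self.world = world

    def predict(
        self, tagged_product: TaggedMolecule, beam: int
    ) -> list[ScoredPrediction]:
        hits = []
        for tagged, rxn in self.world.tagged_reactions(tagged_product.molecule.smiles):
            if tagged == tagged_product:
                hits.append(
                    ScoredPrediction(payload=_mols(rxn.sm), score=rxn.base_confidence)
                )
        hits.sort(key=lambda p: (-p.score, tuple(m.smiles for m in p.payload)))
        # same SM set may be recorded via several rules; keep the best
        out, seen = [], set()
        for p in hits:
            key = tuple(m.smiles for m in p.payload)
            if key not in seen:
                seen.add(key)
                out.append(p)
        return out[:beam]


class MockReagent:
    """Returns the recorded rule's reagent set; offers a lower-scored
    "no reagent" alternative when the beam allows, so reagent selection by
    forward confidence is exercised."""

    def __init__(self, world: World):
        self.world = world

    def predict(
        self, sm: Sequence[Molecule], product: Molecule, beam: int
    ) -> list[ScoredPrediction]:
        key = tuple(sorted(m.smiles for m in sm))
        out = []
        for rxn in self.world.by_sm_key.get(key, []):
            if rxn.product == product.smiles:
                out.append(
                    ScoredPrediction(
                        payload=_mols(rxn.reagents), score=rxn.base_confidence
                    )
                )
        out.sort(key=lambda p: (-p.score, tuple(m.smiles for m in p.payload)))
        if out and len(out) < beam:
            out.append(
                ScoredPrediction(payload=(), score=max(out[-1].score * 0.5, 1e-6))
            )
        return out[:beam]


class MockForward:
    """Replays recorded rules forward.

    A reagent set differing from the recorded one halves the confidence
    (the step still "works", less believably).  With ``noise`` > 0 a
    content-hash-seeded fraction of calls returns a corrupted top-1 product,
    emulating an unreliable forward model for filter testing.
    """

    WRONG = "C"  # methane: produced by no rule, so corruption never validates

    def __init__(self, world: World, noise: float = 0.0, noise_seed: int = 0):
        if not 0.0 <= noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        self.world = world
        self.noise = noise
        self.noise_seed = noise_seed

    def _corrupt(self, sm_key: tuple[str, ...], reagents: tuple[str, ...]) -> bool:
        if self.noise <= 0.0:
            return False
        if self.noise >= 1.0:
            return True
        text = f"{'.'.join(sm_key)}>{'.'.join(reagents)}|{self.noise_seed}"
        digest = hashlib.sha256(text.encode()).digest()
        return int.from_bytes(digest[:8], "big") / 2**64 < self.noise

    def predict(
        self, sm: Sequence[Molecule], reagents: Sequence[Molecule]
    ) -> list[ScoredPrediction]:
        key = tuple(sorted(m.smiles for m in sm))
        rset = tuple(sorted(m.smiles for m in reagents))
        scored = []
        for rxn in self.world.by_sm_key.get(key, []):
            score = rxn.base_confidence
            if tuple(sorted(rxn.reagents)) != rset:
                score *= 0.5
            scored.append(ScoredPrediction(payload=_mols([rxn.product]), score=score))
        scored.sort(key=lambda p: (-p.score, p.payload[0].smiles))
        if scored and self._corrupt(key, rset):
            scored[0] = ScoredPrediction(
                payload=_mols([self.WRONG]), score=scored[0].score
            )
        return scored


class MockTagger:
    """Proposes the recorded reaction centers of world products."""

    def __init__(self, world: World):
        self.world = world

    def predict(self, m: Molecule, beam: int) -> list[ScoredTag]:
        seen: set[str] = set()
        scored = []
        for tagged, rxn in self.world.tagged_reactions(m.smiles):
            s = tagged.serialized()
            if s not in seen:
                seen.add(s)
                scored.append(ScoredTag(tagged_smiles=s, score=rxn.base_confidence))
        scored.sort(key=lambda t: (-t.score, t.tagged_smiles))
        return scored[:beam]


def mock_suite(world: World, noise: float = 0.0, noise_seed: int = 0):
    """The full model bundle over one world."""
    from retroroute.predictors import ModelSuite

    return ModelSuite(
        retro=MockRetro(world),
        reagent=MockReagent(world),
        forward=MockForward(world, noise=noise, noise_seed=noise_seed),
        tagger=MockTagger(world),
    )


# --------------------------------------------------------------------------
# random molecule generation (for round-trip property tests)

_CURATED = [
    "c1ccccc1", "c1ccncc1", "Cc1ccc(O)cc1", "C[C@H](N)C(=O)O",
    "C[C@@H](O)[C@H](N)C", "C[N+](C)(C)C", "[13CH3]CO", "C1CC1C(=O)O",
    "FC(F)(F)c1ccccc1", "O=S(=O)(O)c1ccc2ccccc2c1", "C/C=C/C(=O)O",
]


def random_molecules(rng: random.Random, n: int) -> list[Molecule]:
    """*n* random small molecules: valence-respecting random trees over
    {C, N, O, S, F, Cl} plus a sprinkle of curated aromatic/stereo/charged
    cases.  Deterministic per RNG state."""
    max_valence = {6: 4, 7: 3, 8: 2, 16: 2, 9: 1, 17: 1}
    out: list[Molecule] = []
    while len(out) < n:
        if rng.random() < 0.15:
            out.append(canonicalize(rng.choice(_CURATED)))
            continue
        mol = Chem.RWMol()
        free: list[int] = []
        for i in range(rng.randint(1, 12)):
            z = rng.choice([6, 6, 6, 6, 7, 8, 6, 16, 9, 17])
            if i > 0 and not free:
                break
            idx = mol.AddAtom(Chem.Atom(z))
            if i > 0:
                partner = rng.choice(free)
                mol.AddBond(partner, idx, Chem.BondType.SINGLE)
            # recompute free-valence list
            free = [
                a.GetIdx()
                for a in mol.GetAtoms()
                if a.GetDegree() < max_valence[a.GetAtomicNum()]
            ]
        try:
            Chem.SanitizeMol(mol)
            out.append(canonicalize(Chem.MolToSmiles(mol)))
        except Exception:  # noqa: BLE001 - rare sanitization rejects; retry
            continue
    return out
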