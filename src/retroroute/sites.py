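"""Enumeration of candidate disconnection sites on a product molecule.

Three complementary strategies are combined: *systematic* tagging of all
single atoms, bonded pairs and connected triplets (chain or three-membered
ring); *template* tagging using patterns mined from a reaction corpus; and
*model* tagging via a learned tagger contract.  Candidates are merged and
deduplicated on the canonical serialized tagged string — topologically
equivalent sites count once — while per-strategy provenance flags are kept
for Venn-style diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from rdkit import Chem

from retroroute.centers import TagTemplate, apply_templates
from retroroute.predictors import TaggerModel
from retroroute.smiles import Molecule, SmilesError, TaggedMolecule, parse_tagged

log = logging.getLogger(__name__)

SYSTEMATIC = "systematic"
TEMPLATE = "template"
MODEL = "model"

__all__ = [
    "SYSTEMATIC",
    "TEMPLATE",
    "MODEL",
    "TaggingConfig",
    "SiteCandidate",
    "systematic_tags",
    "model_tags",
    "enumerate_sites",
]


@dataclass(frozen=True)
class TaggingConfig:
    """Which tagging strategies to combine, and their parameters.

    Defaults mirror the combination found to balance coverage and cost:
    systematic 1-3 atom tags, templates at conditional radius 2, and the
    learned tagger at beam 50.
    """

    systematic: bool = True
    template: bool = True
    template_radius: int = 2
    model: bool = True
    model_beam: int = 50


@dataclass(frozen=True)
class SiteCandidate:
    """A candidate disconnection site with strategy provenance."""

    tagged: TaggedMolecule
    provenance: frozenset[str]


def systematic_tags(m: Molecule) -> list[TaggedMolecule]:
    """All single-atom, bonded-pair and connected-triplet tag sets of *m*.

    A triplet qualifies when the three atoms induce a connected subgraph
    (a path or a triangle).  Symmetry-equivalent tag sets collapse.
    """
    mol = Chem.MolFromSmiles(m.smiles)
    n = mol.GetNumAtoms()
    adjacency = {
        i: {nbr.GetIdx() for nbr in mol.GetAtomWithIdx(i).GetNeighbors()}
        for i in range(n)
    }
    tag_sets: set[frozenset[int]] = {frozenset([i]) for i in range(n)}
    for bond in mol.GetBonds():
        tag_sets.add(frozenset([bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()]))
    for center in range(n):
        for a, b in combinations(sorted(adjacency[center]), 2):
            tag_sets.add(frozenset([a, center, b]))
    unique = {TaggedMolecule.create(m, ts) for ts in tag_sets}
    return sorted(unique, key=lambda t: (len(t.tagged_atoms), t.tagged_atoms))


def model_tags(
    m: Molecule,
    tagger: TaggerModel,
    beam: int,
    stats: dict | None = None,
) -> list[TaggedMolecule]:
    """Validated tagger suggestions for *m*.

    Suggestions whose tag-removal does not re-parse to *m* are dropped and
    counted (``stats['dropped']``).  Output is deduplicated, ordered by
    descending tagger score then lexicographically, at most *beam* long.
    """
    if stats is None:
        stats = {}
    stats.setdefault("dropped", 0)
    try:
        suggestions = tagger.predict(m, beam)
    except Exception:  # noqa: BLE001 - tagger is third-party pluggable code
        log.warning("tagger failed on %s; no model tags", m.smiles, exc_info=True)
        return []
    scored: list[tuple[float, TaggedMolecule]] = []
    seen: set[TaggedMolecule] = set()
    for suggestion in suggestions[:beam]:
        try:
            tm = parse_tagged(suggestion.tagged_smiles)
        except SmilesError:
            stats["dropped"] += 1
            continue
        if tm is None or tm.molecule != m:
            stats["dropped"] += 1
            continue
        if tm not in seen:
            seen.add(tm)
            scored.append((suggestion.score, tm))
    if stats["dropped"]:
        log.info("model tags: dropped %d invalid suggestions", stats["dropped"])
    scored.sort(key=lambda pair: (-pair[0], pair[1]))
    return [tm for _, tm in scored]


def enumerate_sites(
    m: Molecule,
    cfg: TaggingConfig = TaggingConfig(),
    templates: Sequence[TagTemplate] = (),
    tagger: TaggerModel | None = None,
) -> list[SiteCandidate]:
    """Union of the selected tagging strategies, deduplicated with provenance.

    Order is deterministic: systematic sites first, then template sites by
    template support, then model sites by score; a site found by several
    strategies appears once with all provenance flags.  Raises if the union
    is empty.
    """
    ordered: list[TaggedMolecule] = []
    provenance: dict[TaggedMolecule, set[str]] = {}

    def add(tags: Sequence[TaggedMolecule], flag: str) -> None:
        for tm in tags:
            if tm not in provenance:
                provenance[tm] = set()
                ordered.append(tm)
            provenance[tm].add(flag)

    if cfg.systematic:
        add(systematic_tags(m), SYSTEMATIC)
    if cfg.template and templates:
        add(apply_templates(m, templates), TEMPLATE)
    if cfg.model and tagger is not None:
        add(model_tags(m, tagger, cfg.model_beam), MODEL)
    if not ordered:
        raise ValueError(f"no candidate sites for {m.smiles!r}")
    return [
        SiteCandidate(tagged=tm, provenance=frozenset(provenance[tm]))
        for tm in ordered
    ]
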