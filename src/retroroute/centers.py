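"""Reaction-center identification and tagging-template mining.

Reacting atoms of an atom-mapped reaction are the product atoms whose local
environment differs between their starting-material occurrence and their
product occurrence.  "Environment" is operationalized as the triple (formal
charge, total hydrogen count, multiset of (neighbour atomic number, bond
order)); an atom whose map label is absent from the SM side is reacting by
definition.

Templates generalize observed reaction centers: the product substructure
induced by the reacting atoms plus their environment out to a conditional
radius (1-3 bonds), with the reacting atoms marked.  Applying a template to
a new molecule tags the matched images of those atoms.  Templates only TAG
atoms; they never rewrite structures.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem

from retroroute.smiles import (
    MappedReaction,
    Molecule,
    SmilesError,
    TaggedMolecule,
    maplabels_to_tags,
)

log = logging.getLogger(__name__)

__all__ = [
    "TagTemplate",
    "reacting_atoms",
    "tag_product",
    "template_for_reaction",
    "extract_templates",
    "apply_templates",
    "templates_to_frame",
    "templates_from_frame",
]

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _atom_environment(atom: Chem.Atom) -> tuple:
    nbrs = sorted(
        (b.GetOtherAtom(atom).GetAtomicNum(), b.GetBondTypeAsDouble())
        for b in atom.GetBonds()
    )
    return (atom.GetFormalCharge(), atom.GetTotalNumHs(), tuple(nbrs))


def reacting_atoms(rxn: MappedReaction) -> frozenset[int]:
    """Map labels of product atoms whose environment changed in the reaction.

    Labels missing from the SM side count as reacting.  Raises on a product
    with no map labels at all.
    """
    product = Chem.MolFromSmiles(rxn.product)
    if product is None:
        raise SmilesError(f"unparseable product: {rxn.product!r}")
    sm_env: dict[int, tuple] = {}
    for sm in rxn.starting_materials:
        mol = Chem.MolFromSmiles(sm)
        if mol is None:
            raise SmilesError(f"unparseable starting material: {sm!r}")
        for atom in mol.GetAtoms():
            label = atom.GetAtomMapNum()
            if label:
                sm_env[label] = _atom_environment(atom)
    changed: set[int] = set()
    n_labels = 0
    for atom in product.GetAtoms():
        label = atom.GetAtomMapNum()
        if not label:
            continue
        n_labels += 1
        if label not in sm_env or _atom_environment(atom) != sm_env[label]:
            changed.add(label)
    if n_labels == 0:
        raise SmilesError(
            f"reaction {rxn.source_id!r}: product carries no atom-map labels"
        )
    return frozenset(changed)


def tag_product(rxn: MappedReaction) -> TaggedMolecule | None:
    """Tagged product of *rxn*, or ``None`` if no atom changed (skipped)."""
    labels = reacting_atoms(rxn)
    if not labels:
        log.info("reaction %s skipped: no reacting atoms", rxn.source_id or "<anon>")
        return None
    return maplabels_to_tags(rxn.product, labels)


# --------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class TagTemplate:
    """A tagging template: substructure pattern with designated reactive atoms.

    ``pattern`` is a SMARTS string; reactive atoms carry atom map 1 inside it,
    and ``reactive_positions`` lists their indices in the pattern's atom
    order.  ``support`` counts occurrences in the mining corpus.
    """

    pattern: str
    reactive_positions: tuple[int, ...]
    radius: int
    support: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactive_positions) <= 10:
            raise ValueError(
                f"template must tag 1-10 atoms, got {len(self.reactive_positions)}"
            )


def _environment_atoms(mol: Chem.Mol, seeds: Iterable[int], radius: int) -> set[int]:
    """Atom indices within *radius* bonds of any seed atom (seeds included)."""
    seen = set(seeds)
    frontier = set(seeds)
    for _ in range(radius):
        nxt = {
            nbr.GetIdx()
            for idx in frontier
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors()
            if nbr.GetIdx() not in seen
        }
        seen |= nxt
        frontier = nxt
    return seen


def _atom_query(atom: Chem.Atom, reactive: bool) -> str:
    """SMARTS query recording element, aromaticity, ring membership, degree
    and charge; reactive atoms additionally carry atom map 1."""
    parts = [
        f"#{atom.GetAtomicNum()}",
        "a" if atom.GetIsAromatic() else "A",
        "R" if atom.IsInRing() else "!R",
        f"D{atom.GetDegree()}",
        f"{atom.GetFormalCharge():+d}",
    ]
    suffix = ":1" if reactive else ""
    return "[" + ";".join(parts) + suffix + "]"


def _pattern_for(mol: Chem.Mol, reacting: set[int], radius: int) -> str:
    atoms = sorted(_environment_atoms(mol, reacting, radius))
    atom_symbols = [
        _atom_query(a, a.GetIdx() in reacting) for a in mol.GetAtoms()
    ]
    bond_symbols = [_BOND_SYMBOL[b.GetBondType()] for b in mol.GetBonds()]
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=atoms,
        atomSymbols=atom_symbols,
        bondSymbols=bond_symbols,
        canonical=True,
        allBondsExplicit=True,
    )


def _reactive_positions(pattern: str) -> tuple[int, ...]:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise SmilesError(f"internal: unparseable template pattern {pattern!r}")
    return tuple(
        a.GetIdx() for a in query.GetAtoms() if a.GetAtomMapNum() == 1
    )


def reaction_pattern(rxn: MappedReaction, radius: int) -> str | None:
    """The tagging pattern one reaction contributes, or ``None`` if skipped."""
    labels = reacting_atoms(rxn)
    if not labels or len(labels) > 10:
        return None
    mol = Chem.MolFromSmiles(rxn.product)
    reacting = {a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in labels}
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return _pattern_for(mol, reacting, radius)


def template_for_reaction(rxn: MappedReaction, radius: int) -> TagTemplate | None:
    """The (support-1) template a single reaction induces, or ``None`` if the
    reaction is skipped (no reacting atoms, or more than ten)."""
    pattern = reaction_pattern(rxn, radius)
    if pattern is None:
        return None
    return TagTemplate(
        pattern=pattern,
        reactive_positions=_reactive_positions(pattern),
        radius=radius,
        support=1,
    )


def extract_templates(
    corpus: Sequence[MappedReaction],
    radius: int,
    min_support: int = 2,
    max_reactive_atoms: int = 10,
) -> list[TagTemplate]:
    """Mine tagging templates from an atom-mapped reaction corpus.

    Identical patterns (same typed substructure and reactive-atom layout)
    merge and accumulate support; only templates with support >=
    *min_support* and 1..*max_reactive_atoms* reactive atoms are kept.
    Result sorted by descending support, ties by pattern string.
    """
    if radius not in (1, 2, 3):
        raise ValueError(f"radius must be 1, 2 or 3, got {radius}")
    counts: Counter[str] = Counter()
    for rxn in corpus:
        labels = reacting_atoms(rxn)
        if not labels:
            log.info("template mining: %s skipped (no reacting atoms)", rxn.source_id)
            continue
        if len(labels) > max_reactive_atoms:
            continue
        pattern = reaction_pattern(rxn, radius)
        if pattern is not None:
            counts[pattern] += 1
    out = []
    for pattern, support in counts.items():
        if support < min_support:
            continue
        positions = _reactive_positions(pattern)
        if not 1 <= len(positions) <= max_reactive_atoms:
            continue
        out.append(
            TagTemplate(
                pattern=pattern,
                reactive_positions=positions,
                radius=radius,
                support=support,
            )
        )
    out.sort(key=lambda t: (-t.support, t.pattern))
    return out


def apply_templates(
    m: Molecule, templates: Sequence[TagTemplate], max_matches: int = 2000
) -> list[TaggedMolecule]:
    """Tag *m* at every distinct substructure match of every template.

    Symmetric matches yielding identical canonical tag sets collapse; output
    is deduplicated on the serialized tagged string, ordered by template
    then lexicographically within a template.
    """
    mol = Chem.MolFromSmiles(m.smiles)
    seen: set[TaggedMolecule] = set()
    out: list[TaggedMolecule] = []
    for template in templates:
        query = Chem.MolFromSmarts(template.pattern)
        matches = mol.GetSubstructMatches(
            query, uniquify=False, maxMatches=max_matches
        )
        hits = []
        for match in matches:
            positions = {match[i] for i in template.reactive_positions}
            hits.append(TaggedMolecule.create(m, positions))
        for tm in sorted(set(hits)):
            if tm not in seen:
                seen.add(tm)
                out.append(tm)
    return out


# --------------------------------------------------------------------------
# CSV round-trip


def templates_to_frame(templates: Sequence[TagTemplate]):
    import pandas as pd

    return pd.DataFrame(
        {
            "pattern": [t.pattern for t in templates],
            "reactive_positions": [
                " ".join(map(str, t.reactive_positions)) for t in templates
            ],
            "radius": [t.radius for t in templates],
            "support": [t.support for t in templates],
        }
    )


def templates_from_frame(frame) -> list[TagTemplate]:
    return [
        TagTemplate(
            pattern=row.pattern,
            reactive_positions=tuple(
                int(x) for x in str(row.reactive_positions).split()
            ),
            radius=int(row.radius),
            support=int(row.support),
        )
        for row in frame.itertuples()
    ]
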