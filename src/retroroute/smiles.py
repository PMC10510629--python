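"""Canonical SMILES handling and the "!"-token tagged-SMILES dialect.

A *tagged* SMILES marks candidate reacting atoms of a product by appending a
bare ``!`` token directly after the atom's SMILES token (after any ring-bond
digits belonging to that atom).  The tag never alters the atom token itself,
so token usage stays invariant to hydrogen count and stereochemistry of the
tagged atom.  Deleting every ``!`` from a tagged string recovers the plain
molecule exactly.

All molecules in the package are kept in a single canonical form (RDKit
canonical isomeric SMILES, atom-map labels stripped).  Tagged atom positions
are expressed as indices into the canonical SMILES atom order and are reduced
to a canonical representative under the molecule's automorphism group, so two
topologically equivalent tag sets compare equal as strings.
"""

from __future__ import annotations

import ast
import functools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

TAG_TOKEN = "!"

__all__ = [
    "TAG_TOKEN",
    "SmilesError",
    "Molecule",
    "TaggedMolecule",
    "MappedReaction",
    "canonicalize",
    "serialize_tagged",
    "parse_tagged",
    "maplabels_to_tags",
    "reaction_from_smiles",
    "reaction_to_smiles",
    "read_smiles_file",
    "write_smiles_file",
    "read_reaction_file",
]


class SmilesError(ValueError):
    """Raised for unparseable SMILES or invalid tagged-SMILES syntax."""


# --------------------------------------------------------------------------
# molecules


@dataclass(frozen=True, order=True)
class Molecule:
    """A molecule in the package's single canonical form.

    ``smiles`` is RDKit canonical isomeric SMILES with no atom-map labels;
    ``atom_count`` counts heavy atoms plus explicit bracket hydrogens, i.e.
    the atoms that own a token in the SMILES string.
    """

    smiles: str
    atom_count: int = field(compare=False)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> Molecule:
    """Return the canonical, map-label-free :class:`Molecule` for *smiles*.

    Deterministic and idempotent: ``canonicalize(m.smiles) == m``.
    Stereochemistry and isotopes are preserved.
    """
    mol = _mol_from_smiles(smiles)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    can = Chem.MolToSmiles(mol)
    return Molecule(smiles=can, atom_count=mol.GetNumAtoms())


@functools.lru_cache(maxsize=16384)
def _automorphisms(canonical_smiles: str) -> tuple[tuple[int, ...], ...]:
    """Self substructure matches = automorphisms of the molecular graph.

    Chirality is respected so stereo-distinct atoms never swap.  Capped at
    4096 matches; the cap is deterministic per molecule so canonical tag
    reduction stays stable.
    """
    mol = _mol_from_smiles(canonical_smiles)
    matches = mol.GetSubstructMatches(
        mol, uniquify=False, useChirality=True, maxMatches=4096
    )
    return tuple(tuple(m) for m in matches)


def _canonical_tag_positions(
    canonical_smiles: str, positions: Iterable[int]
) -> tuple[int, ...]:
    """Lexicographically smallest image of *positions* under automorphism."""
    base = tuple(sorted(set(positions)))
    best = base
    for perm in _automorphisms(canonical_smiles):
        cand = tuple(sorted(perm[i] for i in base))
        if cand < best:
            best = cand
    return best


@dataclass(frozen=True, order=True)
class TaggedMolecule:
    """A molecule with an ordered set of tagged (candidate reacting) atoms.

    ``tagged_atoms`` are indices into the canonical SMILES atom order,
    reduced to the canonical automorphism representative.  Construct via
    :meth:`create` (or :func:`parse_tagged` / :func:`maplabels_to_tags`),
    which performs that reduction.
    """

    molecule: Molecule
    tagged_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.tagged_atoms:
            raise SmilesError(f"empty tag set for {self.molecule.smiles!r}")
        if "." in self.molecule.smiles:
            raise SmilesError(
                f"multi-fragment tagged molecule rejected: {self.molecule.smiles!r}"
            )
        if any(i < 0 or i >= self.molecule.atom_count for i in self.tagged_atoms):
            raise SmilesError(
                f"tag index out of range for {self.molecule.smiles!r}: "
                f"{self.tagged_atoms}"
            )

    @classmethod
    def create(cls, molecule: Molecule, positions: Iterable[int]) -> "TaggedMolecule":
        pos = _canonical_tag_positions(molecule.smiles, positions)
        return cls(molecule=molecule, tagged_atoms=pos)

    def serialized(self) -> str:
        return serialize_tagged(self)


# --------------------------------------------------------------------------
# tokenizer

# order matters: bracket atoms, two-letter organics, then single letters
_ATOM_RE = re.compile(r"\[[^\]]*\]|Br|Cl|[BCNOPSFI]|[bcnops]")
_RING_RE = re.compile(r"[-=#:/\\~]?(?:%\d{2}|\d)")


def _tokenize(s: str) -> Iterator[tuple[str, str]]:
    """Yield (kind, text) with kind in {atom, ring, tag, other}.

    Ring-closure digits (optionally preceded by a bond symbol) directly after
    an atom are classed ``ring`` so the tag token can be placed after them.
    """
    i, n = 0, len(s)
    after_atom = False
    while i < n:
        m = _ATOM_RE.match(s, i)
        if m:
            yield "atom", m.group(0)
            i = m.end()
            after_atom = True
            continue
        if after_atom:
            m = _RING_RE.match(s, i)
            if m:
                yield "ring", m.group(0)
                i = m.end()
                continue
        if s[i] == TAG_TOKEN:
            yield "tag", TAG_TOKEN
            i += 1
            continue
        yield "other", s[i]
        i += 1
        after_atom = False


def serialize_tagged(tm: TaggedMolecule) -> str:
    """Emit tagged SMILES: each tagged atom's token followed by ``!``.

    The tag is placed after the atom's ring-bond digits; deleting every
    ``!`` from the output returns ``tm.molecule.smiles`` exactly.
    """
    tagged = set(tm.tagged_atoms)
    out: list[str] = []
    atom_idx = -1
    pending = False  # a tag owed for the most recent atom
    for kind, text in _tokenize(tm.molecule.smiles):
        if kind == "atom":
            if pending:
                out.append(TAG_TOKEN)
            atom_idx += 1
            pending = atom_idx in tagged
        elif kind != "ring" and pending:
            out.append(TAG_TOKEN)
            pending = False
        out.append(text)
    if pending:
        out.append(TAG_TOKEN)
    return "".join(out)


def _strip_tags(s: str) -> tuple[str, tuple[int, ...]]:
    """Remove ``!`` tokens, returning plain SMILES and tagged input-atom indices."""
    out: list[str] = []
    tags: list[int] = []
    atom_idx = -1
    taggable = False
    for kind, text in _tokenize(s):
        if kind == "atom":
            atom_idx += 1
            taggable = True
            out.append(text)
        elif kind == "ring":
            out.append(text)
        elif kind == "tag":
            if not taggable:
                raise SmilesError(
                    f"tag token not directly after an atom token in {s!r}"
                )
            if atom_idx in tags:
                raise SmilesError(f"duplicate tag on one atom in {s!r}")
            tags.append(atom_idx)
        else:
            taggable = False
            out.append(text)
    return "".join(out), tuple(tags)


def _output_order(mol: Chem.Mol) -> list[int]:
    """Atom output order recorded by the most recent MolToSmiles call."""
    return list(ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder")))


def _canonical_positions_from_input(
    mol: Chem.Mol, input_indices: Iterable[int]
) -> tuple[Molecule, tuple[int, ...]]:
    """Canonicalize *mol* and map atom indices to canonical SMILES positions."""
    can = Chem.MolToSmiles(mol)
    order = _output_order(mol)
    pos_of = {atom_idx: k for k, atom_idx in enumerate(order)}
    molecule = Molecule(smiles=can, atom_count=mol.GetNumAtoms())
    return molecule, tuple(pos_of[i] for i in input_indices)


def parse_tagged(s: str, allow_untagged: bool = False) -> TaggedMolecule | None:
    """Parse a tagged SMILES string into a :class:`TaggedMolecule`.

    Inverse of :func:`serialize_tagged` after canonicalization: tagged
    positions are carried through the canonicalization atom permutation.
    An untagged input raises unless ``allow_untagged``, in which case
    ``None`` is returned.
    """
    plain, input_tags = _strip_tags(s)
    if not input_tags:
        if allow_untagged:
            return None
        raise SmilesError(f"no tag token in tagged SMILES: {s!r}")
    mol = _mol_from_smiles(plain)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    molecule, positions = _canonical_positions_from_input(mol, input_tags)
    return TaggedMolecule.create(molecule, positions)


def maplabels_to_tags(
    mapped_product: str, reacting_labels: Iterable[int]
) -> TaggedMolecule:
    """Convert an atom-mapped product plus reacting map labels to tags.

    Atoms whose map label is in *reacting_labels* become tagged atoms; all
    map labels are stripped and positions follow canonical atom order.
    """
    labels = set(reacting_labels)
    if not labels:
        raise SmilesError(f"empty reacting-label set for {mapped_product!r}")
    mol = _mol_from_smiles(mapped_product)
    present = {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()}
    missing = labels - present
    if missing:
        raise SmilesError(
            f"reacting labels {sorted(missing)} absent from product {mapped_product!r}"
        )
    input_indices = [
        a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in labels
    ]
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    molecule, positions = _canonical_positions_from_input(mol, input_indices)
    return TaggedMolecule.create(molecule, positions)


# --------------------------------------------------------------------------
# mapped reactions


@dataclass(frozen=True)
class MappedReaction:
    """One atom-mapped reaction record ``SM1.SM2>R1.R2>P``.

    Starting materials carry atom-map labels, reagents carry none, and there
    is exactly one product molecule whose labels are unique on the product
    side.  Unmapped species listed on the SM side are moved to the reagents
    at construction (reagents are the unmapped species of a mapped reaction).
    """

    starting_materials: tuple[str, ...]
    reagents: tuple[str, ...]
    product: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if "." in self.product:
            raise SmilesError(
                f"reaction {self.source_id!r}: multi-fragment product rejected"
            )
        mol = _mol_from_smiles(self.product)
        labels = [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()]
        if len(labels) != len(set(labels)):
            raise SmilesError(
                f"reaction {self.source_id!r}: duplicate map label on product side"
            )


def _has_map(smiles: str) -> bool:
    mol = _mol_from_smiles(smiles)
    return any(a.GetAtomMapNum() for a in mol.GetAtoms())


def reaction_from_smiles(rsmi: str, source_id: str = "") -> MappedReaction:
    """Parse ``SM>R>P`` reaction SMILES, moving unmapped SM species to reagents."""
    parts = rsmi.strip().split(">")
    if len(parts) != 3:
        raise SmilesError(f"not a reaction SMILES (need two '>'): {rsmi!r}")
    left, middle, product = parts
    sms: list[str] = []
    reagents = [r for r in middle.split(".") if r]
    for species in filter(None, left.split(".")):
        (sms if _has_map(species) else reagents).append(species)
    return MappedReaction(
        starting_materials=tuple(sms),
        reagents=tuple(canonicalize(r).smiles for r in reagents),
        product=product,
        source_id=source_id,
    )


def reaction_to_smiles(rxn: MappedReaction) -> str:
    return ">".join(
        [".".join(rxn.starting_materials), ".".join(rxn.reagents), rxn.product]
    )


# --------------------------------------------------------------------------
# file round-trip (.smi / .rsmi)


def read_smiles_file(path) -> list[str]:
    """Read a .smi file: one SMILES per line, optional tab-separated id."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0].split()[0])
    return out


def write_smiles_file(path, smiles: Sequence[str], ids: Sequence[str] | None = None):
    with open(path, "w") as fh:
        for i, s in enumerate(smiles):
            fh.write(s if ids is None else f"{s}\t{ids[i]}")
            fh.write("\n")


def read_reaction_file(path) -> list[MappedReaction]:
    """Read a .rsmi file of reaction SMILES, one per line."""
    out = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(reaction_from_smiles(line, source_id=f"{path}:{k + 1}"))
    return out
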