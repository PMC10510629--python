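"""Molecular simplicity, building-block membership, and route-level scores.

The route penalty score of an N-step route is

    RPScore = SP^N * prod_i CS_i * prod_{m in U SM_i} Simplicity(m)

where SP in (0, 1] is the step penalty (default 0.8), CS_i the
forward-validation confidence of step i, and Simplicity maps a synthetic
complexity score c in [1, 5] linearly onto [0, 1] via 1 - (c - 1)/4, with
building-block members assigned 1 outright.  Reagents are excluded from the
simplicity product, and by default each molecule counts once per route even
if it appears in several SM sets.  The companion CScore is simply the
product of the per-step confidences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import FindMolChiralCenters

from retroroute.loop import SingleStepResult
from retroroute.smiles import Molecule, canonicalize, read_smiles_file

ComplexityScorer = Callable[[Molecule], float]

__all__ = [
    "BuildingBlockSet",
    "ScoreConfig",
    "heuristic_complexity",
    "simplicity",
    "rpscore",
    "cscore",
]


@dataclass(frozen=True)
class BuildingBlockSet:
    """Catalogue of purchasable compounds; membership is exact canonical
    string equality."""

    members: frozenset[str]
    source: str = ""

    @classmethod
    def from_smiles(cls, smiles: Iterable[str], source: str = "") -> "BuildingBlockSet":
        return cls(
            members=frozenset(canonicalize(s).smiles for s in smiles), source=source
        )

    @classmethod
    def from_file(cls, path) -> "BuildingBlockSet":
        return cls.from_smiles(read_smiles_file(path), source=str(path))

    def __contains__(self, m: Molecule | str) -> bool:
        smiles = m.smiles if isinstance(m, Molecule) else canonicalize(m).smiles
        return smiles in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ScoreConfig:
    """Route scoring knobs: the step penalty SP and how molecules repeat."""

    step_penalty: float = 0.8
    count_duplicates: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.step_penalty <= 1.0:
            raise ValueError(
                f"step_penalty must be in (0, 1], got {self.step_penalty}"
            )


def heuristic_complexity(m: Molecule) -> float:
    """Deterministic structural stand-in for a learned synthetic-complexity
    score: grows with heavy-atom count, ring count and stereocenters,
    clipped to the conventional [1, 5] range."""
    mol = Chem.MolFromSmiles(m.smiles)
    heavy = mol.GetNumHeavyAtoms()
    rings = mol.GetRingInfo().NumRings()
    stereo = len(FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False))
    return min(5.0, 1.0 + 0.1 * heavy + 0.4 * rings + 0.3 * stereo)


def simplicity(
    m: Molecule,
    bb: BuildingBlockSet,
    scorer: ComplexityScorer = heuristic_complexity,
) -> float:
    """Simplicity in [0, 1]: 1 for building blocks, else 1 - (c - 1)/4."""
    if m in bb:
        return 1.0
    try:
        c = scorer(m)
    except Exception as exc:
        raise RuntimeError(f"complexity scorer failed on {m.smiles!r}") from exc
    return min(1.0, max(0.0, 1.0 - (c - 1.0) / 4.0))


def _sm_molecules(
    steps: Sequence[SingleStepResult], count_duplicates: bool
) -> list[Molecule]:
    if count_duplicates:
        return [m for step in steps for m in step.sm_set]
    unique: dict[str, Molecule] = {}
    for step in steps:
        for m in step.sm_set:
            unique.setdefault(m.smiles, m)
    return list(unique.values())


def rpscore(
    steps: Sequence[SingleStepResult],
    cfg: ScoreConfig = ScoreConfig(),
    bb: BuildingBlockSet = BuildingBlockSet(frozenset()),
    scorer: ComplexityScorer = heuristic_complexity,
) -> float:
    """Route penalty score of a route given as its step list (N >= 1).

    Reagents are excluded from the simplicity product; the target itself
    never enters it (only SM-side molecules do).
    """
    if not steps:
        raise ValueError("rpscore requires at least one step")
    score = cfg.step_penalty ** len(steps)
    for step in steps:
        score *= step.confidence
    for m in _sm_molecules(steps, cfg.count_duplicates):
        score *= simplicity(m, bb, scorer)
    return score


def cscore(steps: Sequence[SingleStepResult]) -> float:
    """Product of per-step forward-validation confidences."""
    if not steps:
        raise ValueError("cscore requires at least one step")
    out = 1.0
    for step in steps:
        out *= step.confidence
    return out
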