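"""Predictor contracts for the single-step loop.

The loop needs three models — retro (tagged product -> starting materials),
reagent (SM + product -> reagents) and forward (SM + reagents -> product) —
plus an optional tagger proposing disconnection sites.  Each is a plain
structural contract so that rule-based mocks, or adapters around trained
sequence-to-sequence checkpoints, can be plugged in interchangeably.

Every implementation must be pure with respect to (input, seed): repeated
calls return identical lists.  Confidence scores are probabilities in
(0, 1] so that route scores, which multiply them, stay in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

from retroroute.smiles import Molecule, TaggedMolecule

__all__ = [
    "ScoredPrediction",
    "ScoredTag",
    "RetroModel",
    "ReagentModel",
    "ForwardModel",
    "TaggerModel",
    "ModelSuite",
]


@dataclass(frozen=True)
class ScoredPrediction:
    """A scored model output: a set of molecules plus a confidence in (0, 1].

    The payload meaning depends on the contract: SM set (retro), reagent set
    (reagent; may be empty meaning "no reagent"), or a single product
    (forward).
    """

    payload: tuple[Molecule, ...]
    score: float

    def __post_init__(self) -> None:
        if not 0.0 < self.score <= 1.0:
            raise ValueError(f"score must be in (0, 1], got {self.score}")


@dataclass(frozen=True)
class ScoredTag:
    """A tagger output: a tagged SMILES string plus a confidence."""

    tagged_smiles: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 < self.score <= 1.0:
            raise ValueError(f"score must be in (0, 1], got {self.score}")


@runtime_checkable
class RetroModel(Protocol):
    """Predict starting-material sets from a tagged product (descending score)."""

    def predict(
        self, tagged_product: TaggedMolecule, beam: int
    ) -> list[ScoredPrediction]: ...


@runtime_checkable
class ReagentModel(Protocol):
    """Predict reagent sets for a given SM -> product transformation."""

    def predict(
        self, sm: Sequence[Molecule], product: Molecule, beam: int
    ) -> list[ScoredPrediction]: ...


@runtime_checkable
class ForwardModel(Protocol):
    """Predict products from SM + reagents; top-1 is the model's best."""

    def predict(
        self, sm: Sequence[Molecule], reagents: Sequence[Molecule]
    ) -> list[ScoredPrediction]: ...


@runtime_checkable
class TaggerModel(Protocol):
    """Propose tagged variants of a molecule (learned disconnection sites)."""

    def predict(self, m: Molecule, beam: int) -> list[ScoredTag]: ...


@dataclass
class ModelSuite:
    """The bundle of models the single-step loop consumes."""

    retro: RetroModel
    reagent: ReagentModel
    forward: ForwardModel
    tagger: TaggerModel | None = None
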