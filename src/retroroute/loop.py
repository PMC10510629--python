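"""The triple-predictor single-step retrosynthesis loop.

For one product P: enumerate candidate disconnection sites, run the retro
model on each tagged variant (top-B starting-material sets), the reagent
model on each SM set (top-B' reagent sets), and the forward model on every
(SM, R) combination.  A prediction is kept only if the forward model's top-1
product equals P (canonical string equality, stereochemistry included); its
confidence is the forward model's score.  Among validated (SM, R) pairs that
share an SM set, the reagent set with the highest forward score wins; the
final results are deduplicated on the sorted SM-set key keeping the maximum
confidence, and sorted by descending confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from retroroute.centers import TagTemplate
from retroroute.predictors import ModelSuite
from retroroute.sites import SiteCandidate, TaggingConfig, enumerate_sites
from retroroute.smiles import Molecule, TaggedMolecule

log = logging.getLogger(__name__)

__all__ = ["LoopConfig", "SingleStepResult", "run_ttl", "tagging_efficiency"]


@dataclass(frozen=True)
class LoopConfig:
    """Beam sizes and filters of the single-step loop.

    ``retro_beam`` (B) and ``reagent_beam`` (B') bound how many SM sets per
    site and reagent sets per SM set are tried; ``min_confidence`` drops
    validated steps below a forward-confidence floor (default keeps all).
    """

    retro_beam: int = 3
    reagent_beam: int = 3
    min_confidence: float = 0.0
    tagging: TaggingConfig = field(default_factory=TaggingConfig)


@dataclass(frozen=True)
class SingleStepResult:
    """One validated single-step retrosynthesis of ``product``."""

    product: Molecule
    sm_set: tuple[Molecule, ...]  # canonically sorted: the route identity key
    reagent_set: tuple[Molecule, ...]
    confidence: float  # forward-validation score
    site: TaggedMolecule
    provenance: frozenset[str]
    discovered_at_iteration: int = 0

    def __post_init__(self) -> None:
        if not self.sm_set:
            raise ValueError("sm_set must be nonempty")
        if not 0.0 < self.confidence <= 1.0:
            raise ValueError(f"confidence must be in (0, 1], got {self.confidence}")

    @property
    def sm_key(self) -> tuple[str, ...]:
        return tuple(m.smiles for m in self.sm_set)

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        return (self.product.smiles, self.sm_key)


def run_ttl(
    p: Molecule,
    cfg: LoopConfig = LoopConfig(),
    models: ModelSuite | None = None,
    templates: Sequence[TagTemplate] = (),
    sites: Sequence[SiteCandidate] | None = None,
) -> list[SingleStepResult]:
    """Validated single-step retrosyntheses of *p*.

    Steps whose SM set contains *p* itself (no-op or identity steps) are
    rejected.  Returns an empty list when nothing validates; the caller
    decides what that means.  Pre-enumerated *sites* may be passed to skip
    site enumeration.
    """
    if models is None:
        raise ValueError("run_ttl requires a ModelSuite")
    if sites is None:
        sites = enumerate_sites(p, cfg.tagging, templates, models.tagger)

    # per SM set keep (confidence, result); validated best-reagent selection
    best: dict[tuple[str, ...], SingleStepResult] = {}
    for site in sites:
        try:
            retro_preds = models.retro.predict(site.tagged, cfg.retro_beam)
        except Exception as exc:
            raise RuntimeError(
                f"retro model failed at site {site.tagged.serialized()!r}"
            ) from exc
        for sm_pred in retro_preds[: cfg.retro_beam]:
            sm_set = tuple(sorted(sm_pred.payload))
            if any(m == p for m in sm_set):
                continue  # identity / no-op step
            reagent_preds = models.reagent.predict(sm_set, p, cfg.reagent_beam)
            for r_pred in reagent_preds[: cfg.reagent_beam]:
                forward = models.forward.predict(sm_set, r_pred.payload)
                if not forward or forward[0].payload[0] != p:
                    continue
                confidence = forward[0].score
                if confidence < cfg.min_confidence:
                    continue
                result = SingleStepResult(
                    product=p,
                    sm_set=sm_set,
                    reagent_set=tuple(sorted(r_pred.payload)),
                    confidence=confidence,
                    site=site.tagged,
                    provenance=site.provenance,
                )
                key = result.sm_key
                if key not in best or confidence > best[key].confidence:
                    best[key] = result
    out = sorted(best.values(), key=lambda r: (-r.confidence, r.sm_key))
    log.debug("single-step loop on %s: %d validated", p.smiles, len(out))
    return out


def tagging_efficiency(results: Sequence[SingleStepResult], n_sites: int) -> float:
    """Unique validated steps per candidate site (loop round)."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return len({r.key for r in results}) / n_sites


def with_iteration(result: SingleStepResult, iteration: int) -> SingleStepResult:
    """Copy of *result* stamped with the search iteration that found it."""
    return replace(result, discovered_at_iteration=iteration)
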