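# Methods

## The tagged-SMILES dialect

A tagged molecule `P*` is a product SMILES in which candidate reacting
atoms carry a bare `!` token immediately after the atom's token, after any
ring-bond digits belonging to that atom (`C1!CCCCC1` tags a cyclohexane
carbon).  The tag never modifies the atom token itself, so token usage is
invariant to the tagged atom's hydrogen count and stereochemistry, and
deleting every `!` recovers the plain SMILES exactly.  Multi-fragment
(dot-separated) tagged products are rejected; the pipeline assumes
single-product reactions throughout.

All molecules are held in one canonical form: RDKit canonical isomeric
SMILES with atom-map labels stripped.  Stereochemistry and isotopes are
preserved.  Tagged positions are indices into the canonical SMILES atom
order — but a canonical *string* fixes the atom correspondence only up to
the molecule's automorphism group, so the position set is additionally
reduced to its lexicographically smallest image under that group
(enumerated as chirality-aware self-substructure matches, capped at 4096
deterministically).  With this reduction, two topologically equivalent tag
sets serialize to the same string, equality of tagged molecules is string
comparison, and symmetric sites (all six CH positions of benzene) collapse
to one candidate.  The cost is a substructure self-match per molecule,
cached per canonical SMILES; at the molecule sizes this package targets it
is negligible.

## Reaction centers

For an atom-mapped reaction, a product atom is *reacting* when its local
environment differs between its starting-material occurrence and its
product occurrence.  Environment is operationalized as the triple (formal
charge, total hydrogen count, multiset of (neighbour atomic number, bond
order)); an atom whose map label never appears on the SM side is reacting
by definition.  This is a deliberately toolkit-independent, reproducible
definition; learned atom-mapping tools embody their own notion of
environmental change, and plugging one in upstream simply changes the maps
this definition consumes.  Unmapped species on the SM side are treated as
reagents and moved out of the starting materials before tagging.  Reactions
with an empty reacting set (identity records) are skipped and counted, not
errors.

## Tagging templates

A template generalizes one observed reaction center: the product
substructure induced by the reacting atoms plus every atom within a
conditional radius (1–3 bonds) of any of them, with the reacting atoms
marked.  Each atom is typed by element, aromaticity, ring membership,
degree and formal charge — the minimal typing that separates the radius
tiers without memorizing whole molecules — and bonds are written
explicitly.  Patterns are canonicalized (RDKit canonical fragment SMILES
over the typed atom queries) so identical environments merge and accumulate
support; mining keeps templates with support ≥ 2 and 1–10 reactive atoms,
which may form several disconnected groups within one pattern.  Merging
keys derive from the parent molecule's canonical ranking, so two fragments
with identical typed graphs embedded in different parents can, rarely, fail
to merge; this only splits support counts and absolute template counts are
not a quantity this package claims.  Applying a template tags the matched
images of its reactive atoms; templates only tag, they never rewrite
structures.

## Site enumeration

Three strategies are combined and deduplicated on the canonical serialized
tagged string, with per-strategy provenance retained: systematic tags (all
single atoms, bonded pairs, and connected triplets — paths and triangles),
template tags (default radius 2), and learned-tagger proposals (default
beam 50, validated so that tag removal re-parses to the input molecule;
invalid proposals are dropped and counted).  The defaults mirror the
combination that balances coverage against prediction cost.  Order is
deterministic: systematic, then template by support, then model by score.

## The single-step loop

For each tagged variant the retro model proposes up to B starting-material
sets; for each SM set the reagent model proposes up to B′ reagent sets; the
forward model then re-predicts the product for every (SM, R) combination.
A prediction is kept only when the forward top-1 equals the input product —
canonical string equality, stereochemistry included, the strictest reading
of forward validation.  Among validated pairs sharing an SM set the reagent
set with the highest forward score is kept; results are deduplicated on the
sorted SM-set key keeping maximal confidence.  Steps whose SM set contains
the product itself are rejected outright: they are no-ops that would seed
trivial loops.  Defaults B = B′ = 3 balance recall against the cubic cost
per site; `min_confidence` (default 0, i.e. keep everything) exposes the
optional confidence floor rather than guessing one.  The tagging-efficiency
diagnostic divides unique validated steps by the number of candidate sites.

## Route scoring

RPScore = SP^N · ∏ CSᵢ · ∏ Simplicity(m) over the union of SM-side
molecules of the route; reagents are excluded (their complexity rarely
reflects availability), and the target itself never enters.  SP defaults to
0.8; each extra step therefore costs at least a factor 0.8, which is what
drives the search toward short sequences and starves protect/deprotect
cycles.  Simplicity maps a synthetic-complexity score c ∈ [1, 5] linearly
to [0, 1] via 1 − (c − 1)/4 and is pinned to 1 for building-block members.
The complexity scorer is pluggable; the shipped default is a deterministic
structural heuristic, min(5, 1 + 0.1·heavy atoms + 0.4·rings +
0.3·stereocenters), chosen so the package runs without trained weights
while a trained complexity model can be dropped in behind the same
callable.  Molecules repeated across steps count once by default
(`count_duplicates` preserves the alternative reading).  CScore is the
plain product of step confidences; both are reported per route.

## Tree search

The tree is an AND-OR structure: each expanded non-building-block molecule
owns its validated steps (OR), each step requires all its starting
materials (AND), and per-molecule results are memoized, so one single-step
computation serves every tree position of that molecule.  Per iteration the
search enumerates routes, ranks unsolved ones by RPScore (ties: fewer
steps, then lexicographic route key), expands the open leaves of the top 20
(`expansion_width`), and stops on `min_solved` solved routes (default 10),
the iteration budget, or when no expandable leaf remains — budget
exhaustion is reported, never raised.  Cycles are suppressed during
enumeration: a step whose SM set contains an ancestor of its position is
excluded from that route, so no molecule repeats on a root-to-leaf path.
Molecules with zero validated steps are dead and prune every route through
them.  Route enumeration is confidence-ordered depth-first generation under
a cap (default 10 000 routes, truncation flagged) rather than a priority
queue over score bounds: at the problem sizes the package targets the cap
is not reached before exhaustive enumeration, and exhaustiveness is what
the correctness tests compare against a brute-force oracle.  Width control
comes from the per-molecule step cap (default 50, by confidence).  Solved
routes accumulate across iterations, so the best solved RPScore is
non-decreasing (anytime behaviour); each step records the iteration at
which it was first discovered.

## The toy universe

The synthetic world generates mono- and bifunctional building blocks
(alkyl/aryl scaffolds bearing acid, amine, alcohol, bromide heads) and
closes them under three coupling rules — amide (confidence 0.9), ester
(0.8), ether (0.7) — to a configurable depth (default 2, default 20
building blocks), recording every reaction as an atom-mapped reaction
SMILES with the rule's fixed reagent set.  Exactly one reaction is recorded
per starting-material set (the most confident rule wins deterministically),
which makes the mock forward model a function and round-trip validation
consistent by construction.  Minimal route lengths for every product are
computed by relaxation over the recorded corpus and shipped as ground truth.
Mock models are pure lookups over this record: retro inverts reactions at
the tagged site, the reagent model returns the recorded reagent set (plus a
half-scored "no reagent" alternative so best-reagent selection is
exercised), the forward model replays the rule and can corrupt its top-1
product for a content-hash-seeded fraction of calls (`noise`) to test the
validation filter, and the tagger proposes recorded reaction centers.

What this emulates — and does not.  The toy world reproduces the *shape* of
the problem: multi-site products, branching routes, reagent ambiguity,
unreliable forward prediction, known shortest routes.  It does not emulate
chemical reality: no competing selectivity, no failed-but-plausible
disconnections, no confidence spread within a rule, tiny building-block
sets.  Passing tests therefore certify the orchestration, scoring and
search machinery, not single-step chemical accuracy, which lives entirely
in whatever trained models are plugged into the predictor contracts.

## Problem sizes and numerical choices

Tests run on worlds of 12–20 building blocks, closure depth 1–2 (route
ground truth up to 3 steps via branching), corpora of 100–240 reactions;
the search correctness suite uses 20 seeded worlds.  These sizes were
chosen so the whole suite exercises every code path in well under a minute
of search time while keeping route enumeration exhaustive (cap never hit).
Ties are broken lexicographically on canonical strings everywhere;
deterministic ordering is enforced at every merge, sort and cap.  The only
stochastic components are the seeded world generator, the seeded random
molecule generator used by round-trip tests, and the content-hash forward
noise; the search itself is deterministic.

## Known limitations

- No adapters for trained sequence-to-sequence checkpoints are shipped;
  the contracts and configuration names reserve the slot.
- The automorphism reduction caps at 4096 self-matches; pathological
  highly symmetric molecules beyond the cap retain a deterministic but not
  provably minimal representative.
- Template merging can split support across different parent molecules
  with identical typed fragments (see above).
- The dataset-split reader verifies record counts of a local corpus copy;
  it does not download anything.
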