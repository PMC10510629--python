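# retroroute

Disconnection-aware multistep retrosynthesis: reaction-center tagging,
a triple-predictor single-step loop with forward validation, and a
route-penalty-score-guided best-first tree search down to commercial
building blocks.

## The problem

Computer-aided synthesis planning works backwards from a target molecule to
purchasable starting materials through known reaction types.  Two things
make it hard: a single-step model must propose *diverse, realistic*
disconnections rather than only the most common one, and the multistep
search must let *short* routes emerge from an exponentially growing tree.

`retroroute` addresses both:

1. **Where to disconnect.**  Candidate reaction centers of a product P are
   marked in a tagged SMILES dialect (`P*`): a bare `!` token directly after
   each candidate atom's token, e.g. `CC!O` tags the middle carbon of
   ethanol.  Candidates come from three complementary strategies —
   *systematic* (all single atoms, bonded pairs, connected triplets),
   *template-based* (substructure patterns with a conditional environment
   radius of 1–3 bonds, mined from an atom-mapped reaction corpus), and
   *model-based* (a pluggable learned tagger contract).
2. **Validated single steps.**  For each tagged variant, a retro model (T1)
   predicts starting-material sets SM, a reagent model (T2) predicts reagent
   sets R for SM → P, and a forward model (T3) re-predicts the product from
   SM + R.  A step survives only if T3's top-1 product equals P; its
   confidence CS is T3's score.
3. **Which routes to pursue.**  A best-first tree search ranks routes by the
   route penalty score

   ```
   RPScore = SP^N · ∏ᵢ CSᵢ · ∏_{m ∈ ∪ SMᵢ} Simplicity(m)
   ```

   with step penalty SP = 0.8 by default, and Simplicity ∈ [0, 1] derived
   linearly from a synthetic-complexity score in [1, 5] (building-block
   members score 1; reagents are excluded).  Each iteration expands the open
   leaves of the top-20 unsolved routes, memoizing single-step results per
   molecule.  A route is *solved* when every leaf is a building block.  The
   companion CScore is the plain product of step confidences.

Trained sequence models are not bundled: the three predictors and the tagger
are structural contracts (`retroroute.predictors`), and a deterministic
rule-based toy chemistry (`retroroute.toyworld`) provides consistent
implementations plus reaction corpora with exactly known shortest routes, so
every algorithmic component is testable end to end at desk scale.

## Worked example

Generate a toy universe, mine tagging templates, and plan a synthesis:

```sh
$ retroroute mockworld generate --seed 7 --n-building-blocks 12 --out world
world seed=7: 12 building blocks, 160 reactions, 148 targets -> world/

$ retroroute extract-templates world/corpus.rsmi --radius 2 --out templates.csv
13 templates from 160 reactions -> templates.csv

$ retroroute single-step "CC(=O)NCCC(=O)NCCC(=O)O" --world-seed 7 --world-size 12 \
      --template-file templates.csv
sm_set	reagents	confidence	site	provenance
CC(=O)NCCC(=O)O.NCCC(=O)O	CCN(CC)CC	0.9000	CC(=O)NCCC!(=O)N!CCC(=O)O	model,systematic,template
CC(=O)O.NCCC(=O)NCCC(=O)O	CCN(CC)CC	0.9000	CC!(=O)N!CCC(=O)NCCC(=O)O	model,systematic,template

$ retroroute run --target "CC(=O)NCCC(=O)NCCC(=O)O" --bb world/bb.smi \
      --world-seed 7 --world-size 12 --template-file templates.csv --out routes.json
target CC(=O)NCCC(=O)NCCC(=O)O: solved=True (2 routes, 3 iterations, 3 single-step calls) -> routes.json
```

The `single-step` table lists the two validated amide disconnections of the
target: each row is a starting-material set, the predicted reagent
(triethylamine), the forward-validation confidence, the tagged site that
produced it, and which tagging strategies found that site.  The best route
in `routes.json` is the two-step sequence

```
CC(=O)NCCC(=O)NCCC(=O)O  <-  CC(=O)NCCC(=O)O + NCCC(=O)O   (CS 0.9, iteration 1)
CC(=O)NCCC(=O)O          <-  CC(=O)O + NCCC(=O)O            (CS 0.9, iteration 2)
```

with RPScore 0.4018 = 0.8² · 0.9 · 0.9 · Simplicity(NCCC(=O)O, …) and
CScore 0.81 = 0.9 · 0.9; both leaves are building blocks, and two steps is
the exact minimum for this target (recorded in `world/targets.smi`).

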