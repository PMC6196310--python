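# invarel

Invariance-based linguistic pattern mining and smoothed partial tree kernel
(SPTK) classification for biomedical relation candidates (chemical–protein,
chemical–disease, protein–protein).

The pipeline:

1. **Candidate generation** — documents are segmented into sentences; each
   co-sentential heterogeneous entity pair yields a rewritten *candidate
   instance*: the focal pair is normalized to role tags, other mentions are
   genericized, and the proximal verb of interacting pairs becomes a
   relation tag. The parallel PoS sequence mirrors the rewrite.
2. **Pattern mining** — PoS context frames are extracted around the three
   referential anchors (entity1 / relation / entity2) for every window
   offset, scored against corpus-wide frame counts, consolidated into conic
   coefficients `(p20, p11, p02)`, and reduced to the rotation-invariant
   scalar `I = p20² + p11²/2 + p02²`. Instances with unit invariance ratio
   are clustered; each cluster is consolidated into a triple-context
   linguistic pattern by progressive global alignment (match +2,
   mismatch −2, gap −2).
3. **Tree construction** — dependency parses (CoNLL-U or a deterministic
   fallback parser) become grammatical-relation-centered trees
   (SYNT → POS → LEX layers); the best-matching pattern prunes uncovered
   subtrees and a class node decorates the root.
4. **Classification** — an SVM over a precomputed SPTK Gram matrix handles
   the binary interacting/non-interacting gate (cutoffs `>0` / `−0.3`, or
   the in-range `[0, 1]` rule for the protein–protein task) and a
   one-vs-all stage assigns the relation class by highest score.

A deterministic synthetic-corpus generator (`invarel.synthetic`) emits the
BioCreative-style three-file dialect with planted PoS templates,
configurable class imbalance and noise; it is the no-download test surface
for every module.

## CLI

```sh
invarel simulate --out-dir data/train --n-abstracts 50 --seed 1
invarel simulate --out-dir data/test  --n-abstracts 20 --seed 2

invarel learn-patterns --abstracts data/train/abstracts.tsv \
    --entities data/train/entities.tsv --relations data/train/relations.tsv \
    --out data/patterns.tsv

invarel train --abstracts data/train/abstracts.tsv \
    --entities data/train/entities.tsv --relations data/train/relations.tsv \
    --model data/model.json --seed 1

invarel predict --abstracts data/test/abstracts.tsv \
    --entities data/test/entities.tsv --relations data/test/relations.tsv \
    --model data/model.json --out data/predictions.tsv

invarel evaluate --predictions data/predictions.tsv \
    --abstracts data/test/abstracts.tsv --entities data/test/entities.tsv \
    --relations data/test/relations.tsv --out data/report.json
```

Other commands: `candidates` (instance dump as JSON lines) and `trees`
(bracketed pruned trees). Task presets: `--mode CPI` (frame size n=3,
cutoff rule), `--mode CDR` (n=5), `--mode PPI` (n=3, range rule). An INI
config file (`--config`) can override `[invariance]`, `[kernel]` and
`[classifier]` settings.

## Layout

- `src/invarel/corpus_io.py` — TSV corpora, CoNLL-U parses, predictions
- `src/invarel/tagging.py` — PoS tagger contract + deterministic fallback
- `src/invarel/candidates.py` — sentence segmentation, candidate instances
- `src/invarel/patterns.py` — frames, scores, invariants, clustering,
  alignment, pattern consolidation
- `src/invarel/grct.py` — tree construction, pattern matching, pruning,
  decoration, serialization
- `src/invarel/sptk.py` — smoothed partial tree kernel and Gram matrices
- `src/invarel/classification.py` — precomputed-kernel SVMs and metrics
- `src/invarel/synthetic.py` — synthetic corpus generator + recovery stats
- `src/invarel/pipeline.py`, `src/invarel/cli.py` — orchestration
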