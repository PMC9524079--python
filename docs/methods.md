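# Methods

## Problem and data model

The package extracts six preclinical PICO entity types — Species, Strain,
Induction (how the disease model was produced), Intervention, Comparator and
Outcome — from abstracts of in vivo animal studies. An annotated document is
a token sequence with 0-based, half-open character offsets; entity spans
never overlap, align to token boundaries, and convert losslessly to the
13-symbol BIO tag vocabulary (`O` plus `B-`/`I-` per type). `O` sits at tag
index 0 so tie-broken decoding of uninformative scores yields the outside
tag.

Annotated corpora travel as EntitiesTsv (`token<TAB>tag`, blank line
between sentences, one document per file). The format does not preserve
original spacing, so parsed documents use canonical single-space offsets;
these are authoritative for everything downstream. Stray `I-` tags in
third-party files are repaired to `B-` (the mention is kept) rather than
rejected.

The tokenizer splits on whitespace and peels flanking punctuation into
single-character tokens while keeping internal hyphens and slashes, so
strain and diet surface forms (`C57BL/6`, `high-fat`) survive as single
tokens. That rule is what makes character-level annotation and token-level
BIO tagging mutually consistent here.

## Stage 1: PICO sentence classification

A sentence is a PICO sentence iff it intersects at least one gold entity
span. The shipped encoder ("baseline") averages trainable word embeddings
(32-d), applies one tanh hidden layer (32 units) and a 2-way softmax. The
training contract — cross-entropy, AdamW, gradient clipping by global norm,
gradient accumulation, slanted-triangular or constant schedule, checkpoint
selection by validation F1 of the positive class — is independent of the
encoder, and the default hyperparameters (peak learning rate 5e-5, 10
epochs, clip norm 0.1, accumulation every 16 mini-batches) are the
fine-tuning regime reported for the transformer experiments. Those defaults
are kept verbatim for fidelity; since 5e-5 cannot train a randomly
initialised model, `ClassifierConfig.baseline_preset()` raises the rate to
0.1 and relaxes clipping to 1.0 for the from-scratch baseline. The decision
threshold is fixed at 0.5.

Splitting for training defaults to document level to avoid leakage between
sentences of the same abstract; sentence-level splitting (the published
protocol) is available via a flag.

Truncation removes non-PICO sentences, re-bases offsets, remaps contained
gold spans verbatim, and retains a provenance map from truncated to original
offsets. A gold span crossing a sentence boundary cannot be re-based safely
and is dropped with a warning (the validator flags such spans). If no
sentence survives, the result is an empty document with a `no_pico` flag.

## Stage 2: entity recognition

All learning components are NumPy implementations with analytic gradients
(gradient-checked against central finite differences in the test suite).
Encoders:

* **recurrent** — bidirectional tanh recurrent layer over word embeddings;
  full backpropagation through time;
* **transformer** — a compact single-head scaled-dot-product self-attention
  block with learned positional embeddings, residual connection and a tanh
  projection (it is a small attention encoder authored here, not a
  pretrained checkpoint);
* **transformer+recurrent** — attention feeding the recurrent layer.

Each pairs with a per-token softmax head or a linear-chain CRF head (the
`+crf` architectures). Word embeddings are a trainable lookup, randomly
initialised, 200-d by default, with a `freeze_embeddings` flag defaulting to
true (the published regime froze pretrained vectors); pretrained vectors can
be loaded from whitespace-separated text. Unknown words map to a shared
`<unk>` vector. Presets carry the published learning-rate/epoch regimes:
recurrent 1e-3/20, recurrent+crf 5e-3/20, transformer 1e-3/20,
transformer+crf 1e-4/30, transformer+recurrent+crf 1e-4/60. The hidden
dimension is restricted to [32, 512], the tuned range.

CRF inference is exact: partition by the log-space forward recursion,
decoding by Viterbi with ties broken toward the lowest tag index, marginals
by forward–backward. Training maximises sequence likelihood, with gradients
(model expectation minus empirical counts) read off the marginals. Decoding
applies hard BIO constraints (-inf on illegal transitions and illegal start
tags), which guarantees structurally valid output; transitions themselves
are learned unconstrained, since gold paths are always legal. Softmax heads
decode per-token argmax and rely on the `I-`→`B-` repair when converting to
spans. Per-token confidence is the posterior probability of the emitted tag
(softmax posterior, or the CRF marginal of the Viterbi tag).

One document is one training sequence; loss is computed only over real
tokens; checkpoint selection is by entity-level validation F1. Training is
bit-reproducible under a fixed seed.

## Evaluation

Entity-level, exact-boundary matching only; an optional overlap mode exists
for diagnostics but never produces headline numbers. Per-document metrics
are macro-averaged over documents (not pooled counts) — the test suite
includes a constructed case where macro and micro disagree to pin this
down. Zero conventions: empty prediction against non-empty gold scores 0;
a document with neither gold nor predicted entities is excluded from the
average; per-type averages skip documents where the type occurs in neither
set (a flag switches to counting them as zeros).

## Self-training

The loop scores each silver abstract by the arithmetic mean of its tokens'
posterior confidences and accepts strictly above the threshold (0.95 or
0.99). Accepted records keep the pseudo-labels from their acceptance round
and leave the pool permanently — re-predicting previously accepted records
is not part of the protocol here, which keeps runs auditable. Acceptances
are split 80/20 (validation share floored) into training/validation
additions; every round retrains from a fresh initialisation; the loop stops
at the first empty acceptance (recorded in the history as an empty round) or
after 15 rounds. Gold validation documents never enter training (enforced),
and the gold test set is evaluated once, for the best-across-rounds model
selected by gold-validation F1.

## Synthetic corpora

The generator reproduces the structure of the annotated 400-abstract
dataset: Poisson per-document counts around 11 sentences, 5 PICO sentences
and 17.5 entities, and the imbalanced type mix (Intervention 24.1 %,
Comparator 1.8 %, Outcome 40.6 %, Induction 10.6 %, Species 19.6 %,
Strain 3.3 %). (The source statistics are internally inconsistent by a
small margin — 6837 entities over 400 abstracts is 17.09 per abstract, not
17.5; the generator follows the per-abstract figure.) Entity phrases come
from small synthetic per-type lexicons, pairwise disjoint and disjoint from
the filler vocabulary; Intervention, Induction and Outcome phrases are
multi-word so `I-` tags are exercised. `cue_strength` < 1 replaces some
mentions with words from an ambiguous pool that also appears untagged in
filler text, producing genuinely uncertain posteriors.

What passing tests on this corpus do show: the data path is lossless, the
learners optimise what they claim to, the pipeline composes, and the
self-training control flow honours its discipline. What they do not show:
performance on real biomedical text, which has unseen vocabulary, ambiguous
boundaries, nested paraphrase and annotation noise — the published scores
on the real corpus (sentence F1 ≈ 0.85, entity F1 ≈ 0.70) are not
reproducible from synthetic data and are not claimed here.

## Numerical and design choices

* Enumeration oracles (all `K^n` paths) back the CRF tests at ≤6 tokens and
  ≤5 tags, tolerance 1e-8; marginal sums are checked to 1e-8.
* Splits floor the validation/test sizes and give the remainder to training
  (400 → 320/40/40); partitions are seeded and invariant to input order
  (items are sorted under a stable key before shuffling).
* Degenerate inputs: empty text tokenizes to nothing; empty documents
  predict empty outputs; zero-token training documents are skipped with a
  warning; an all-`-inf` decode raises.
* Benchmark problem sizes (200 abstracts for the closed-loop check, 30 gold
  / 12 silver for the self-training benchmark, hidden 64 / embedding 32)
  are chosen so the full suite runs in minutes on one CPU while leaving the
  learning checks comfortably away from their thresholds.

## Known limitations

* The attention encoder is one head and one layer; it exists to exercise
  the architecture space, not to rival pretrained transformers.
* The rule-based sentence splitter is an application-time convenience;
  training always uses stored sentence boundaries, so a better splitter can
  be plugged in without retraining.
* Document text reconstructed from EntitiesTsv has canonical spacing;
  original character offsets are unrecoverable from that format.
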