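# picoextract

Automated PICO extraction for abstracts of **preclinical animal studies**.

Systematic reviews of animal research screen thousands of abstracts for the
elements of the PICO framework. In preclinical work the *Population* splits
into the animal **Species**, the **Strain**, and the method of **Induction**
of the disease model, alongside the **Intervention**, the **Comparator**
(usually an untreated or vehicle control cohort) and the **Outcome**.
`picoextract` implements a two-stage extraction workflow for these six
entity types, aimed at people building evidence-synthesis tooling for
in vivo research:

1. **PICO sentence classification** — a binary classifier marks sentences
   that contain at least one PICO mention; the rest of the abstract
   (introduction, conclusions, background) is removed.
2. **PICO entity recognition** — a token tagger labels the remaining text
   over the 13-tag BIO vocabulary (`B-Type`/`I-Type` for each of the six
   types, plus `O`) and the tags are converted back to typed character
   spans in the original abstract.

The taggers combine a token encoder (bidirectional recurrent layer, or a
compact single-head self-attention encoder, or both) with either a per-token
softmax head or a **linear-chain CRF** head. The CRF scores a tag sequence
`y` as

```
score(y) = start[y_1] + Σ_t emission[t, y_t] + Σ_t transition[y_{t-1}, y_t] + end[y_n]
```

normalised over all sequences; decoding is Viterbi under hard BIO
constraints (no `I-Type` after anything but `B-Type`/`I-Type` of the same
type), so decoded output is structurally valid by construction. Per-token
confidences are exact posterior marginals from forward–backward.

Evaluation is **entity-level**: a prediction is correct only on an exact
(type, start, end) match; per-document precision/recall/F1

```
P_i = correct_i / predicted_i    R_i = correct_i / gold_i    F1_i = 2 P_i R_i / (P_i + R_i)
```

are macro-averaged across documents, overall and per type.

For the low-annotation regime the package includes **self-training**: the
recogniser pseudo-labels an unlabelled "silver" pool, abstracts whose mean
token posterior exceeds a threshold (0.95 or 0.99) are accepted with their
pseudo-labels, split 80/20 into training/validation additions, and a freshly
initialised model is retrained; the loop halts at the first empty acceptance
or after 15 rounds. Gold validation data is never trained on, and the gold
test set is evaluated exactly once.

A synthetic-corpus generator produces annotated abstracts with the structure
of the underlying annotated dataset (≈11 sentences and ≈17.5 entities per
abstract, ≈5 PICO sentences, the imbalanced six-type mix), so the entire
workflow is testable without any download.

## Worked example

```
picoextract simulate --n 200 --seed 1 --out corpus/
picoextract train-sentence --corpus corpus/ --out models/sent --seed 1
picoextract train-ner --corpus corpus/ --arch recurrent+crf --out models/ner --seed 1
```

Training prints the model-selection score, e.g.

```
best validation F1: 1.000
```

(on the fully cue-separable synthetic corpus both stages reach perfect
validation scores). Extraction from a raw abstract:

With `abstract.txt` containing
`the animals received low-dose velartinib therapy and assessed infarct
volume . we evaluated marmosets in each cohort .`:

```
$ picoextract predict --text-file abstract.txt \
      --sentence-model models/sent --ner-model models/ner
{
  "doc_id": "abstract",
  "kept_sentences": [0],
  "no_pico_sentences": false,
  "entities": [
    {"type": "Intervention", "start": 21, "end": 48,
     "text": "low-dose velartinib therapy", "confidence": 0.999825},
    {"type": "Outcome", "start": 62, "end": 76,
     "text": "infarct volume", "confidence": 0.999817},
    {"type": "Species", "start": 92, "end": 101,
     "text": "marmosets", "confidence": 0.999515}
  ],
  "text": "the animals received low-dose velartinib therapy and ..."
}
```

`kept_sentences` lists the sentences the first stage classified as PICO
sentences; entity offsets point into the *original* abstract text, and each
confidence is the mean posterior probability of the entity's token tags.
Other subcommands: `convert`, `validate`, `stats`, `evaluate`,
`self-train`.

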