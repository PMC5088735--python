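# Methods

`disner` implements a two-model disease named-entity recognition (DNER)
system with concept normalization: a feature-rich linear-chain CRF with
rule-based post-processing and a bidirectional RNN over word embeddings
are trained as independent base taggers, their per-token outputs are fused
by an SVM meta-classifier, and every recognized mention is linked to a
concept identifier by TF-IDF cosine ranking over synonym-expanded concept
documents. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic evaluation does and does not
show.

## Corpus model and preprocessing

A document is a title and abstract; all character offsets refer to
`title + " " + abstract` (0-based, half-open — the BC5CDR PubTator
convention). Sentence splitting is rule-based: a terminator followed by
whitespace and an uppercase letter/digit/bracket ends a sentence, except
inside parentheses or after a known abbreviation ("e.g.", "Fig.", ...);
the title is always its own sentence, and any boundary that would bisect a
gold mention is suppressed (logged). Tokenization is a regex over
alphabetic runs, digit runs, and single punctuation characters, so
hyphenated forms split ("ANCA-positive" → `ANCA`, `-`, `positive`).
Earlier descriptions of this architecture used external tools (a
sentence-boundary model and the GENIA tagger) for these steps; here both
sit behind pluggable callables with deterministic built-in defaults so the
whole pipeline is reproducible without binaries. POS and chunk tags come
from a bundled regex tagger with a closed 13-tag set; any callable
`tokens -> (pos, chunks)` can replace it.

Entity spans are projected to per-token B/I/O labels. A mention that does
not align with token boundaries is snapped outward to the smallest
covering token span and logged, never dropped. Decoding inverts this
(maximal `B I*` runs; an orphan `I` is repaired to `B`), so
`mentions_to_bio` and `bio_to_mentions` are mutually inverse on
boundary-aligned corpora — asserted corpus-wide in the tests.

## CRF base tagger

The CRF scores a label sequence by emission weights on active
`feature=value` indicators plus 3×3 transition weights. Feature families
per token: the word, POS, chunk, word shape (`U`/`L`/`D` per character,
extended with `S` for symbols), a coarse character-class type (closed
8-value set), 1–4-character prefixes/suffixes, and two dictionary
look-ups against the disease lexicon — a word-level Y/N flag and a greedy
longest-term BIO match. Each family is expanded over a context window of
radius n; the window radius is configurable per family (1–3) and defaults
to 2 for word/POS/chunk/shape/type and 1 for the affix and dictionary
families. "Longest common subsequence matching" for the dictionary BIO
feature is realized as greedy longest *contiguous* term matching over
normalized (lowercased, stemmed) tokens: gapped subsequence matches cannot
produce contiguous BIO spans.

Training minimizes the L2-penalized negative conditional log-likelihood,
`NLL + (c2/2)·||θ||²` with `c2 = 1.0` by default, via L-BFGS (iteration
cap 200 library-level, 100 in the pipeline default). Forward–backward and
Viterbi run in log space, batched across sentences with padding and
masking; the implementation is checked against exhaustive enumeration of
all `3^T` labelings for `T ≤ 6` and against central finite differences of
the objective. Viterbi ties break to the lexicographically smallest label
(B < I < O). The per-token confidence exported to the ensemble is the
posterior marginal of the assigned label (one reasonable realization of an
otherwise unspecified "confidence"; a per-sequence probability would be an
alternative).

### Post-processing

Two monotone recall boosters follow the CRF (they only add mentions, and
are idempotent):

* **Repeated-entity propagation.** A surface tagged at least `min_count`
  times in one document tags all its other case-insensitive,
  token-boundary occurrences. The threshold is 2: the description "more
  than twice" conflicts with the accompanying worked example (a surface
  tagged exactly twice triggers), and the example wins. Configurable.
* **Abbreviation resolution.** `<definition> (<abbreviation>)` patterns
  are detected with the Schwartz–Hearst right-to-left character alignment
  and its standard short-form validity constants (2–10 characters, ≤ 2
  words, contains a letter, first character alphanumeric, definition
  window ≤ min(|A|+5, 2|A|) words). If the definition is a lexicon term
  *or* is itself already tagged, every occurrence of the abbreviation is
  added. Consequently an undetected definition contributes nothing — the
  negative case is tested as well as the positive one.

## Bi-RNN base tagger

Two independent simple recurrences over the embedding sequence,

    h→_t = f(U_f x_t + W_f h→_{t−1} + b_f)
    h←_t = f(U_b x_t + W_b h←_{t+1} + b_b)
    y_t  = softmax(V [h→_t ; h←_t])

with f = tanh by default (logistic available; gated units are out of
scope). Both boundary states are zero vectors: the alternative of seeding
the backward recurrence with a "recursive copy" of a hidden state is
ambiguous, and zero initialization is standard and testable. The output
layer consumes the *concatenation* of the directional states rather than
their sum, because the ensemble explicitly consumes that 2H-dimensional
penultimate vector. Softmax is max-shifted; each y_t sums to 1 to 1e-9.

Training is per-sentence backpropagation through time with Adam
(lr 1e-3 library default, 3e-3 in the pipeline default; β₁ = 0.9,
β₂ = 0.999), inverted dropout of rate 0.25 on the input embedding
sequences only (training mode only), and a per-epoch validation
log-likelihood on a held-out fraction (default 10% of training
sentences) for convergence monitoring. Weights initialize uniformly in
±0.08 from a seeded generator; embedding rows, including a dedicated OOV
row, are trained with the network. Equal seeds give bit-identical
parameter trajectories. A NaN/inf loss aborts with diagnostics rather
than training through it. Gradients of the full parameter set (recurrent
matrices, output projection, embedding table) are verified against
central finite differences.

Desk-scale defaults are H = 32 hidden units per direction and D = 16
embedding dimensions, which keep the full pipeline around a minute on one
CPU; the publication-scale configuration (H = 500, D = 300) is reachable
through the same parameters. Pre-trained embeddings load from a
whitespace-delimited text table; a miniature skip-gram-with-negative-
sampling trainer is included for building corpus-local embeddings
(deterministic under seed), standing in for large-corpus word2vec
training. Random initialization over the training vocabulary is the
fallback.

## SVM fusion

Every token is one instance. The feature vector stacks: one-hot CRF label
(taken from the *post-processed* CRF output, matching the architecture
order in which post-processing precedes combination), one-hot Bi-RNN
label, both confidences, both base models' training error rates, a
one-hot POS tag, the dictionary flag and one-hot dictionary-BIO label,
and the Bi-RNN penultimate vector (2H values). Error rates are estimated
by document-level k-fold cross-validation rather than resubstitution — a
memorizing base model would otherwise report a degenerate near-zero rate.
The function default is k = 5; the pipeline default uses k = 3 folds with
reduced optimizer budgets inside folds, since a constant scalar feature
does not need fully converged fold models. "Weighted confidence" is
realized by including the error-rate block alongside the raw confidences
rather than pre-multiplying them; the weighting arithmetic is otherwise
undefined, and leaving the composition to the SVM is the more agnostic
choice.

The combiner is an RBF-kernel SVC (C = 1, gamma = 1/dim) on standardized
features with balanced class weights (O dominates). Its prediction is
BIO-repaired and decoded to mentions. Checkpoints store the scaler
parameters and the support-vector expansion in JSON together with a
feature-layout manifest, so a layout mismatch fails at load time; the
reloaded predictor reimplements one-vs-one RBF voting from the stored
arrays and is verified against the in-memory model.

## Normalization

Each concept's preferred name plus all synonyms form one document; a
mention is a query. Both sides are lowercased, tokenized on
non-alphanumerics, and Porter-stemmed (implemented in-package). Weights
are raw term frequency times idf = ln(N/df) with no smoothing (df ≥ 1
always since vocabulary comes from the documents); query terms outside
the vocabulary contribute 0. Candidates are ranked by cosine; a top score
of exactly 0 yields the sentinel "-1". Exact ties resolve to the smallest
concept ID — reproducibility outweighs fidelity to a random choice, and
a seeded-random tie mode is provided for strict emulation.

One consequence of this idf variant is worth noting: a term occurring in
*every* concept document has idf 0 and contributes nothing, so a lexicon
of exactly two identical documents scores 0 and returns "-1" rather than
exercising the tie rule; ties with positive scores require at least one
other concept in the index. The tests reflect this. Composite identifiers
for coordinated mentions ("vision and hearing loss") and word-sense
disambiguation are out of scope.

## Synthetic data

The generator emulates the structural properties each stage consumes,
at desk scale, fully deterministic under seed:

* concepts `T0001…` with 2–3-word names (1–2 modifiers + a head noun
  composed from onset+suffix morphemes, e.g. "chronic hepatemia"); heads
  are unique per concept, so every lexicon term retrieves its own concept
  at rank 1 by construction;
* synonym variants (bare head, suffix-swapped phrase, reordered form) and
  an initial-letter abbreviation, included as a synonym; when two
  concepts' initials collide, the later concept simply has no
  abbreviation, keeping all terms unique across concepts;
* abstracts of 4–7 template sentences; with probability 0.3 a document
  introduces a concept as `long form (ABBR)` and later mentions the bare
  abbreviation (exercising Schwartz–Hearst resolution); with probability
  0.4 a surface repeats within the abstract (exercising propagation);
  60% of sentences carry a mention;
* distractor sentences built from pseudo-words, plus two kinds of traps:
  modifier words ("acute", "chronic") used outside entities, and — in 25%
  of non-mention slots — a disease head-word of a concept *absent from
  the document* used in a non-entity context ("The cardosis screening
  assay…"). The second trap is what separates learning systems from the
  dictionary matcher: blind longest-match tagging mis-tags every trap
  (mention-level F1 ≈ 0.84 on the study corpus), while the CRF and
  Bi-RNN learn the contextual distinction.

What passing on this corpus shows: the machinery is correct end to end —
offsets, feature extraction, training, decoding, post-processing, fusion
and linking compose without loss, and context beats dictionary lookup
when gold annotation is context-dependent. What it does not show:
performance on real biomedical text. Template language has none of the
boundary ambiguity (modifier attachment), naming variation, nesting, or
annotation noise that dominate real DNER error profiles, and the
synthetic lexicon is unambiguous by construction. Scores near 1.0 here
are a correctness statement, not a performance claim.

The study configuration used by the acceptance script and the end-to-end
tests is 300 documents (200 train / 100 test), a 30-concept lexicon, and
the desk-scale network (H = 32, D = 16); at this size the full pipeline,
including cross-validated error-rate estimation, runs in roughly a minute
on one CPU. Byte-level determinism of checkpoints, tagged corpora and
reports under equal seeds is asserted on a smaller configuration of the
same pipeline.

## Known limitations

* Simple recurrences only — no LSTM/GRU cells, no stacked layers.
* No probability calibration of the SVM outputs; exactly two base models.
* Non-contiguous and overlapping mentions are rejected at parse time.
* The concept-level score uses per-document ID sets (union over
  mentions); mention-weighted concept scoring is not implemented.
* The dictionary-matching normalizer performs no disambiguation; an
  ambiguous real-world lexicon (same term under several concepts) will
  resolve ties lexicographically.
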