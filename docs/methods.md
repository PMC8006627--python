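# Methods

`deidtext` de-identifies Spanish-language medical free text in two stages:
a sequence tagger detects spans of protected information, and a randomizer
replaces each detected span with a synthetic surrogate of the same
category.  This note records the models, the synthetic study conditions,
the numerical choices, and what the test results do and do not establish.

## Entity schema

Seven token-level categories: `CAB` (section headers), `NAME` (person
names), `DIR` (full street addresses), `LOC` (populated places), `NUM`
(identifying numbers and alphanumeric codes), `FECHA` (dates), `INST`
(healthcare institutions).  `CAB` is annotated so headers can be *kept*:
they carry report structure, not identity.  Consequently the global
de-identification metric (below) counts only the other six as identifying.

## Tokenization and tagging scheme

Tokens are maximal non-whitespace runs with leading/trailing punctuation
peeled off as single-character tokens; characters interior to a chunk are
never split, so date surfaces (`14/03/2018`) and code surfaces (`1234-AB`)
stay single tokens — a deliberate choice, because surrogate substitution
replaces whole surfaces.  Offsets are 0-based half-open over Unicode code
points (the BRAT convention).  Tags use the BIO scheme over the seven
labels; invalid model output (a dangling `I-X`) is repaired to `B-X` before
span conversion, making decoding total.  The modeling sentence unit is the
report **line**: clinical reports carry signal in their line structure
(identifiers often sit alone on a line), and entities never cross lines.

## Sequence taggers

Three architectures share a word-level bidirectional LSTM whose outputs are
projected linearly to per-tag emission scores, decoded by a linear-chain
CRF; they differ in the character channel concatenated to the word
embedding:

* `lstm-crf` — none;
* `lstm-lstm-crf` — per-token character BiLSTM, final states concatenated;
* `conv-lstm-crf` — width-3 character convolution, ReLU, max-over-time.

Words are lowercased for the word channel; the character channel sees the
original case (capitalization is the key person-name cue and survives
there).  Digits are not normalized — numeric shape is the signal for `NUM`
and `FECHA`.  Word embeddings are randomly initialized (uniform ±0.05);
pretrained vectors in GloVe text format can overwrite rows but are never
required.

CRF scores include virtual START/STOP transitions; the partition function
is computed in log space and the training objective is the exact sequence
negative log-likelihood.  Viterbi ties break toward the lowest tag index,
making decoding deterministic.  The CRF carries no hard BIO transition
constraints; repairs are applied post hoc instead, keeping gradients
unconstrained.

Training uses Adam on minibatches of line sequences with global gradient-norm
clipping at 5, inverted dropout on the encoder input and output, and early
stopping on the validation global de-identification F1.  Optionally an
exponential moving average (EMA) of all weights — `shadow' = d·shadow +
(1−d)·current` after every optimizer step — is maintained and used for
validation and prediction; the raw gradient trajectory is unaffected.

Everything is implemented in NumPy (float64) on a small reverse-mode
autograd core; single-threaded with a fixed seed, training reproduces bit
for bit.  Hyperparameter defaults follow common BiLSTM-CRF practice:
word_dim 100, char_dim 25, char_hidden 25, word_hidden 100, dropout 0.5,
batch 16, learning rate 1e-3, patience 5, ema_decay 0.999.

## Gazetteers and pre-annotation

Gazetteers are weighted surface lists: person names weighted by frequency,
municipalities by population, plus hospital/outpatient indices and street
addresses.  The bundled miniature gazetteers (~200 name parts, 55
municipalities, 42 institutions, 50 addresses) are synthetic excerpts shaped
like the public Spanish registries; nothing is downloaded.  Weighted
sampling uses cumulative-weight inversion over the exclusion-filtered,
renormalized table.  Dictionary matching is case-insensitive but
accent-sensitive, token-boundary anchored, longest-match-first with a
left-to-right greedy tie-break; cross-category conflicts of equal length
resolve by fixed priority INST > DIR > LOC > NAME > NUM > FECHA (more
specific lists win).  Pre-annotation is context-blind by design; the
min-NAME-count document filter (default 2) is what removes
ambiguous-word-only documents afterwards.

## Synthetic corpus: what it emulates

Real de-identification corpora are restricted, so all experiments run on
generated reports with three structural profiles:

* **headered** — Spanish section headers, entities after headers, inside
  sentence templates, or occasionally alone on a line (orphan rate 0.15);
* **dept7** — the structurally divergent department: Valencian filler text
  and headers, metadata values detached from their headers by a line break,
  half of all entities alone on a context-free line, few headers overall;
  its documents carry department marker 7, all others a uniform draw over
  the remaining departments;
* **meddocan** — header-bound records where every value immediately follows
  its metadata descriptor, for structure-overfitting experiments.

Per-category annotated-token shares are steered by *greedy deficit
selection*: each new entity takes the category currently furthest below its
target share, so corpus shares converge within a fraction of a percentage
point by a few hundred documents.  The default target gives headers 21.37%,
names 35.34%, dates 17.79%, codes 12.47%, institutions 10.80%, addresses
1.38% and places 0.85% of annotated tokens; a second target for the
divergent department shifts mass toward addresses, places and institutions
and away from headers.  Dept7-only corpora keep a structural CAB floor of
roughly 13% (forced header lines), slightly above that target's 9.4%.

Date surfaces are valid calendar dates in three format families
(`dd/mm/yyyy`, `dd-mm-yyyy`, written Spanish); codes are 6–10 digits with
optional letter affixes and hyphen grouping, except that 30% are short bare
3–4 digit strings.  Filler comes from bundled phrase banks (Spanish and
Valencian) with numeric slots filled at generation time (measurements,
series/image numbers, clock times, including bare-number lines).  Two
deliberate ambiguity classes mirror real clinical text:

* **homograph names** — common clinical words that are also Spanish names
  (cabeza, campos, luz, alba, pilar, cuello, delgado, segura, sala) occur
  both lowercase in filler and as gazetteer name entries, so only context
  can disambiguate them;
* **short codes vs. series numbers** — a 3–4 digit code alone on a line is
  indistinguishable from a series or image number.

15% of generated name parts are out-of-gazetteer pseudo-words (no registry
covers every name).  Overall entity density defaults to 15% of tokens.

What the generator does **not** emulate: real clinical semantics, typos and
OCR noise, cross-document patient identity, Valencian full text beyond the
phrase bank, or the annotation disagreements of human corpora.  Passing
tests therefore certify the pipeline's mechanics and the qualitative
structure-sensitivity phenomenon, not expected performance on real reports.

## Corpus splitting

`split_corpus` holds one department out: the test set comes only from that
department, validation contains none of it, and the training set contains
exactly the requested number of its documents.  The held-out department
must therefore contain exactly `n_test + n_heldout_in_train` documents; any
other count raises a sizing error rather than silently violating one of the
three constraints.  Sizes come from largest-remainder apportionment of the
requested ratios; a single integer seed drives all sampling.

## Evaluation

All primary metrics are token-level with micro-averaged (pooled) counts.
Per category, a token is a true positive when gold and prediction agree on
the category (B/I prefixes ignored).  The **global de-identification
metric** is precision/recall/F1 over the binary distinction identifying
(NAME, DIR, LOC, NUM, FECHA, INST) vs. not (CAB, O): a gold NAME token
predicted FECHA is a category error but a binary true positive, because the
token still gets removed.  Zero-denominator cases return 0 with a
degenerate flag.  Report rows are ordered CAB, NAME, DIR, LOC, NUM, FECHA,
INST, global.

## Surrogate substitution

Rules per category: NAME → given-name + surname(s) combination matching the
original's word count (frequency-weighted); LOC → population-weighted
municipality; INST → hospital/clinic index entry; DIR → address entry;
FECHA → a fresh valid date in the original's format family; NUM → a random
string matching the original's character-class mask (digit→digit,
letter→letter preserving case, separators kept); CAB → unchanged.  Every
non-CAB surrogate is checked against the original and regenerated on
collision; if a gazetteer is exhausted by exclusion, a syllable-generated
pseudo-word stands in (flagged by construction: it is not a gazetteer
member).  Replacement proceeds right-to-left so character offsets stay
valid; text outside spans is byte-identical, line counts are preserved, and
the audit trail stores only categories and lengths, never original
surfaces.  Masks made entirely of separators admit no distinct surrogate
and are refused.  Cross-document surrogate consistency (same patient →
same pseudonym) and date-shift schemes are deliberately out of scope.

## The desk-scale reproduction experiment

`deidtext.experiments.run_structure_experiment` generates 250 documents
(72% headered, 28% dept7; dept7 documents use the shifted distribution
target), splits 140/60/50 with the divergent department as the whole test
set and 14% of training documents (matching the minority-department share
of the reference setting), and trains the reduced `lstm-lstm-crf` with EMA:
word_dim 50, word_hidden 50, char_dim/char_hidden 16, dropout 0.3, Adam at
3e-3, batch 8, 4 epochs, ema_decay 0.99.  These sizes were chosen once as
the package's desk-scale defaults; the run takes a few minutes on one CPU.

At the fixed experiment seed the validation split reaches global recall
0.999 while the held-out department scores 0.991 — the structure-
sensitivity effect, driven by exactly the mechanisms built into the
generator: context-free lines whose surface is a known non-identifying
word (homograph names, short bare codes) are tagged O, and such lines
concentrate in the divergent department.  The direction of the gap is
stable across seeds; its size varies with the few-token counts involved.

## Numerical choices and degenerate inputs

* All randomness flows from `numpy.random.Generator` instances seeded by a
  single integer; nothing reads global RNG state.
* CRF computations are log-space throughout; enumeration cross-checks agree
  to 1e-6 on random instances.
* Viterbi and argmax tie-breaks take the lowest index (first maximum).
* Empty documents tokenize to empty sequences and predict to empty span
  lists; empty token sequences are rejected by the encoder.
* Checkpoint loading recomputes the closed-form parameter count implied by
  config and vocabulary and refuses checkpoints that disagree.

## Known limitations

* The NumPy training loop is CPU-bound and single-threaded; it is sized for
  corpora of hundreds of documents, not tens of thousands.
* Binary recall on synthetic data saturates near 1 because filler
  vocabulary is finite; real-text recall will be lower and should be
  measured on real annotated data before any deployment.
* The randomizer guarantees surface inequality, not semantic unlinkability;
  formal re-identification-risk quantification is out of scope.
* MEDDOCAN-style official span-level scoring is not implemented; the
  entity-level strict-match mode here is token-derived and clearly labeled.
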