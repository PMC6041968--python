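# Methods

This note records the models, conventions and design choices behind
`crossner`, and what its synthetic-data experiments do and do not show about
real corpus collections.

## Corpus representation and formats

Annotated corpora are held as `Corpus → Document → Span` with 0-based,
half-open character offsets into the document text. BioC's
`offset`/`length` pairs are converted to `end = offset + length`; brat
standoff offsets are read in their native 0-based half-open convention;
CoNLL-style IOB input has no offsets, so they are synthesized by joining
tokens with single spaces. Text is normalized to `\n` line endings on read
*before* any offset handling, because mixed line endings are a common cause
of annotation index mismatches.

Offset repair is a shift search: for a span whose text slice does not equal
its recorded surface string, shifts are tried in order of increasing
magnitude (negative before positive at ties) up to `max_shift = 5`
characters; spans that still fail are dropped and counted. The repair is
surfaced in a `ValidationReport` rather than applied silently, alongside the
corpus exclusion rules (nested entities, declared subset corpora, declared
abbreviation corpora). The concrete shift-search algorithm is this
package's own design; only its outcome (repaired vs. unrepairable counts)
matters downstream.

Tokenization splits on whitespace and then at every letter↔digit transition,
with each non-alphanumeric symbol a token of its own ("p53" → "p", "53";
"V600E+" → "V", "600", "E", "+"). This keeps character-class features clean
and, combined with forced breaks at annotation boundaries during IOB
projection, removes partial token/span overlap entirely. IOB2 (B- on every
entity start) is used throughout because span reconstruction from it is
unambiguous; overlapping same-class spans are resolved leftmost-longest
before projection.

## Class remapping

Corpus-specific label names are mapped onto shared superclasses via an
explicit table (`corpus<TAB>label<TAB>class[,class...]`); a span may map to
several classes at once and is then replicated per class (an interleukin is
both a gene product and a chemical), and unmapped labels are dropped with a
logged count. The shipped default table is a reconstruction covering common
label names and is meant to be overridden. After remapping, a corpus is
split into single-class copies so each tagging problem is binary; classes
with fewer than 10 mentions are flagged as too sparse for representative
learning-curve analysis (exclusion is the caller's choice).

## The CRF tagger

A first-order linear-chain CRF over the three labels {O, B-class, I-class}.
Per-token features: word identity and lowercased form, character
prefixes/suffixes up to 4, collapsed word shape (caps→X, lower→x, digit→d,
symbols verbatim, runs collapsed), capitalization flags (InitCap, AllCaps,
MixedCase), digit flags, single-symbol identity, positioned neighbor words
within a window (default 2), and an unordered disjunction-of-words bag
within 4 tokens on each side. Label-history information enters through the
chain's transition weights; no part-of-speech tagging is used, which keeps
the tagger free of external models. No feature pruning is applied at this
scale.

Structurally invalid transitions (start→I, O→I) carry a −∞ mask added on
top of the (unused) corresponding parameters, so every decoded sequence is
well-formed IOB2 by construction and no post-hoc repair is needed.
Training minimizes the negative penalized log-likelihood with L-BFGS
(Gaussian prior, σ = 1.0 by default; tolerance 1e-6; 200 iterations max).
Weights start at zero and the objective is convex, so results are
reproducible; the seed only shuffles data order. The forward–backward pass
is vectorized over a padded batch of sequences in log space.

Viterbi decoding runs a backward dynamic program over suffix scores and a
greedy forward reconstruction; at each position the earliest label among
optimal continuations is chosen, which makes the decoded path the
lexicographically smallest maximizer under the label order O < B- < I-.
This tie rule matters only in degenerate score ties (e.g. repeated
identical tokens) but makes decoding fully deterministic and testable
against exhaustive enumeration.

## Evaluation

Strict (exact-match) mention-level scoring: a prediction is a true positive
only if an unconsumed gold mention with identical document, offsets and
class exists. 0/0 denominators evaluate to 0. Partial (overlap) matching
exists behind a flag for sensitivity analysis and is never the default.
Two cross-corpus aggregates are reported: the document-weighted mean
Σ F·n / Σ n and the equally-weighted mean of per-corpus F.

## Learning curves and power analysis

Corpora are split 80/20 at the manuscript-group level (all documents with
the same `group_id` land on one side). Three designs:

* **corpus-specific** — one model per source corpus, evaluated on every
  corpus's fixed test set (the within/cross F matrix);
* **merged** — training pools the union of all corpora; the `shuffled`
  scheme permutes the pool once per replicate, the `sequential` scheme
  concatenates corpora in the configured order one document at a time and
  records each corpus's cumulative boundary;
* **leave-corpus-out** — for each corpus, train on the shuffled union of
  all *other* corpora's training data, evaluate its test set. A hard
  assertion audits that no held-out document id ever enters the pool, and
  the pool ids are recorded on the curve for independent auditing.

The default x-grid is geometric (doubling, capped at the pool size);
per-document granularity is available but compute-heavy. Replicate points
at the same x are averaged before fitting.

The inverse power law `Yfs(x) = (1 − a) − b·x^c` is fitted by bounded
trust-region least squares (0 ≤ a ≤ 1, b ≥ 0, c ≤ 0), initialized at
a₀ = max(0, 1 − max y), b₀ = 0.2, c₀ = −0.1, with RMSE reported. A flat
curve is degenerate for this family (c → 0 absorbs b into the constant), so
flat inputs short-circuit to the unique interpretable solution b = 0 with
`c_identifiable = False`; the same flag is cleared whenever the fitted b or
|c| is numerically zero.

## Orthographic feature analysis

The 31-feature registry (7 case, 5 digit, 5 length, 14 symbol predicates)
is a frozen, data-driven table; the category structure (punctuation forms,
initial/end/all caps, digit counts, character counts) is fixed but the
registry can be swapped wholesale. Entity and null token samples are
balanced by down-sampling the larger side without replacement,
`floor(larger/smaller)` times (minimum 1). Within each repetition every
feature gets a two-sided Fisher exact test (scipy) on its 2×2
presence×class table and Benjamini–Hochberg correction across the 31
features; q-values are summarized as mean ± population sd across
repetitions (sd = 0 when there is a single repetition). A feature is
*characteristic* when mean q + sd < 0.05 and its percentage-point
difference (computed on the balanced sample, so comparable across corpora)
is positive. The BH scope — across features within a repetition — is the
natural reading of "correction for multiple testing" and is isolated behind
one function if a different scope is ever wanted.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structural* causes of cross-corpus divergence:

* **lexicon overlap** — shared lexicon fractions between corpus pairs are
  constructed exactly (shared forms first, remainder disjoint);
* **orthography/annotation standard** — per-class surface templates:
  gene-like (capitalized stems + digits), variant-like (letter-digit-letter
  with optional '+'), chemical-like (digit-hyphen-syllable chains), and
  natural-language "«gene» gene mutant" phrases standing in for corpora
  that annotate descriptive mentions instead of nomenclature;
* **entity density** — Poisson insertions per document into a null stream
  drawn from a fixed packaged vocabulary, with a 10% admixture of
  distractor tokens (capitalized words, numerals, abbreviations) so
  entities are not separable from context by orthography alone.

Default regime sizes: 100 documents per corpus, ~12 tokens per document,
density 2 mentions/document, lexicon size 40 — small enough that a full
multi-corpus experiment trains in seconds on one CPU, large enough that
F-scores are stable to a few points across seeds.

What the synthetic regimes do **not** capture: real linguistic context
(null tokens are i.i.d., so there is no syntax for contextual features to
exploit), annotation noise and inter-annotator disagreement, nested or
discontinuous entities, and realistic lexicon frequency distributions.
Passing the qualitative acceptance properties therefore shows that the
pipeline's machinery — training, transfer measurement, curve fitting,
feature testing — behaves correctly under known ground truth, not that any
particular real corpus pair will show a given gap. Absolute synthetic
F-scores are near-ceiling precisely because the generated task is clean;
the quantities of interest are the *differences* between regimes.

## Numerical and degenerate-input conventions

* Forbidden CRF transitions are −∞, not large negative constants; log-space
  forward–backward handles them exactly.
* Training with no positive (non-O) example raises; non-convergence at the
  iteration cap returns the model with `converged = False`.
* Fisher tests on all-zero tables return p = 1; balanced testing warns when
  the smaller token class has fewer than 20 tokens.
* Power-law fitting requires ≥ 3 distinct x values; extrapolation requires
  x ≥ 1.
* Stage seeds in the pipeline are `crc32(stage_name) XOR global_seed`, so
  adding a stage never perturbs another stage's random stream.

## Known limitations

* Single-class models only; joint multi-class tagging is out of scope by
  design (single-class copies are the unit of training).
* No gazetteer/dictionary features and no neural architectures.
* Sentence splitting, abbreviation expansion, discontinuous and nested
  spans are unsupported (nested-entity corpora are flagged and excluded).
* The learning-curve builders retrain from scratch at every grid point;
  at per-document granularity on large corpora this is O(pool²) work.
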