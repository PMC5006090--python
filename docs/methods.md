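# Methods

This note documents the models, the numerical choices, and the synthetic
data behind `scidisc`, in enough detail to reproduce or re-derive any
number the package prints.

## Discourse model

The unit of classification is the clause. Sentences are found by a
rule-based splitter that treats `[.!?]` as terminators unless the
preceding token is a listed abbreviation (*Fig.*, *et al.*, *e.g.*,
*i.e.*, *vs.*, …) or the following token is lowercase; newlines are hard
boundaries, so all-caps heading lines ("RESULTS") become single clauses
carrying the reserved `none` label and are excluded from training and
scoring — the classifiers are strictly seven-way. Clause boundaries within
a sentence come from a fixed delimiter set: `;`, `, which`, `, suggesting`,
`, indicating`, `whereas`, `while`, `because`, and `and`/`but` when a
finite clause precedes the conjunction and a finite verb occurs within the
next three tokens. The splitter is a deterministic approximation of
syntactic clause segmentation; the `splitter` argument of
`split_clauses`/`segment_document` accepts any replacement (e.g. a full
parser) that returns boundary offsets. Known failure modes: coordinated
verb phrases with an elided subject are split ("and bound DNA"), and
noun–noun coordinations whose right conjunct is followed by a verb are
not ("X and Y were compared" stays one clause by design, since the
conjunction joins subjects, not clauses).

Features per clause, all deterministic functions of (text, annotations,
lexicon):

* `pos:T` — counts of Penn-style tags from a pluggable tagger. The shipped
  `RuleTagger` combines a closed-class lexicon, a verb lexicon of ~60
  scientific-English stems with morphological inflection handling, and
  suffix rules. It is not a general tagger; its contract here is only that
  `VB*`/`RB*` decisions are reliable on the templates and prose the
  pipeline sees. Any callable with a `tag(tokens)` method can replace it.
* `lex:w` — binary indicators for tokens tagged `VB*` or `RB*`.
* `link:figure`, `link:citation` — binary flags when a figure-reference or
  citation annotation overlaps the clause span. Figure mentions are found
  by a grammar anchored on *Fig./Figs./Figure(s)* with conjunction
  expansion ("Figs. 2B, 2C and 2E" → three references; a bare letter
  inherits the current figure number), plus bare parenthesised lists
  ("(2B, 3A)") only in sentences that contain an anchor earlier on.
  Citations are numeric brackets/parens and author–year parentheticals;
  any candidate overlapping a figure reference is dropped, which makes the
  two span sets disjoint by construction.
* `cue:p` — case-insensitive substring hits of a 28-phrase cue lexicon
  (four high-precision attested cues — *possible* → hypothesis, *data not
  shown* → result, *demonstrate*/*suggest* → implication — plus ~24
  conservative extensions such as *we sought to* → goal, *it is known* →
  fact, *remains unclear* → problem). A user lexicon loaded from TSV
  overrides entries key-by-key. Larger lexicons were deliberately not
  pursued; the extension set is kept modest and configuration-visible.

**SVM baseline.** One-vs-all linear SVM (`LinearSVC`, C = 1.0, no class
reweighting by default; `TrainConfig.balanced` enables inverse-frequency
weights). Prediction is the argmax over the seven margins; exact ties
resolve by the fixed label order problem < fact < hypothesis < goal <
method < result < implication.

**Linear-chain CRF.** Score of a labeling `y` of a paragraph with feature
rows `x_t`:

    Σ_t W[y_t]·x_t + Σ_{t>1} T[y_{t-1}, y_t] + start[y_1] + end[y_n]

Training minimizes the exact L2-penalized negative conditional
log-likelihood (λ = 0.05 on every parameter) by L-BFGS (`ftol` 1e-7,
`gtol` 1e-6, ≤ 300 iterations) from zero initialisation, with gradients
from log-space forward–backward; sequences are bucketed by length so the
recursions vectorize across a bucket. The analytic gradient is verified
against central finite differences in the test suite. Decoding
is Viterbi; ties resolve to the lowest label index, i.e. the same fixed
label order as the SVM. The sequence unit is the paragraph
(blank-line-delimited block): that is the scale at which the narrative
ordering operates.

Models persist as a zip of metadata JSON + `npz` parameters. The feature
`schema_version` is stored and checked at predict and load time; a
mismatch is a hard error rather than a silent degradation.

## Experiment linking and typing

The linkage convention of curated interaction databases — one figure ≙ one
experiment, one lettered panel ≙ one sub-experiment — is adopted as-is.
Narrative linking is paragraph-grained: each Results paragraph citing at
least one figure becomes one passage linked to all subfigures it cites
(first-mention order, no merging across paragraphs; sub-paragraph
delineation is out of scope). Caption linking takes `(A) …` sentences; a
marker is accepted at the caption start or after whitespace, a permissive
rule that can oversplit captions containing parenthesised single letters
mid-sentence. Passages whose subfigures map to more than one distinct
curated code are discarded from classifier training; passages citing
uncurated subfigures are counted separately, so the partition conserves
the input. Category merging (PSI-MI leaves into vocabulary parents) is
data, not code: a TSV map, applied before frequency ranking, with ties in
frequency broken by code string order.

The type classifier is nearest-centroid over tf·idf vectors: lowercase
alphanumeric tokens of length ≥ 2, English stopwords removed, natural term
frequency, `idf = ln((1+N)/(1+df)) + 1`, L2 normalisation; class centroid
= mean of the class's training vectors, renormalised. Classification is
cosine argmax with ties broken by code string order; a passage with no
in-vocabulary tokens falls back to the most frequent training class and is
flagged. A top-m discriminative-term voting variant is available
(`FitConfig.mode="terms"`); nearest-centroid is the default because it is
deterministic and parameter-free. Cross-validation is stratified k-fold
(k = 5): per class, indices are shuffled with the seeded generator and
dealt cyclically, which degrades gracefully (with a logged warning) for
classes smaller than k. Out-of-fold predictions are pooled into a single
confusion matrix; the report therefore reflects one prediction per
passage, and mean per-fold accuracy is reported alongside.

## Evaluation conventions

Precision = diag/colsum and recall = diag/rowsum with the 0/0 convention
(a class never predicted, or absent from the gold, scores 0); F1 is the
harmonic mean, 0 when both parts are 0. Weighted F1 uses full-precision
per-class F1 values weighted by gold support. Rounding (half-up, two
decimals) happens only at presentation; tests compare rounded values to
printed references. The most-frequent-class baseline is the closed form
`p·2p/(1+p)` (majority precision `p`, recall 1, all other classes 0),
which the suite cross-checks against an explicit constant-predictor
confusion-matrix construction.

Two reference confusion matrices ship with the package (`scidisc/data/`):
a 7×7 discourse matrix over 445 clauses and a 5×5 caption experiment-type
matrix over 581 experiments with merged PSI-MI codes. All derived numbers
(per-class rows, weighted F1 0.63 and 0.71, baseline 0.42) are recomputed
from the raw counts at run time, never stored.

## Synthetic corpora

The generators exist because the annotated corpora behind the reference
matrices are not redistributable; they emulate the *statistical structure*
the models assume, not the prose. Templates are deliberately stylized
English; realism of wording is a non-goal.

**Discourse corpus.** Paragraph label sequences are drawn from a
first-order Markov chain over the seven labels plus an end state. The
default chain encodes the archetypal stage order with per-stage inclusion
probabilities `q_i` and self-loops `s_i` solved so that expected label
frequencies match the reference class priors (2, 53, 36, 30, 98, 182, 44
over 445) at mean paragraph length L = 8: the expected count of stage `i`
per paragraph is `m_i = L·π_i = q_i/(1−s_i)`, realised as `q_i = min(m_i,
0.95)` and `s_i = max(0, 1 − 0.95/m_i)`. Skipping uninvolved stages keeps
the process a valid Markov chain (`P(i→j) = (1−s_i)·q_j·Π_{i<k<j}(1−q_k)`),
and the start distribution conditions on a non-empty paragraph. Measured
frequencies at ~3600 clauses land within 2 percentage points of the
priors. Each clause is rendered from a label-specific template bank
(35% of the time from a shared, label-ambiguous generic bank — without
some per-clause ambiguity the ordering signal would be worthless and
sequence and non-sequence models would tie); a cue phrase for the label is
appended with probability `emission × (1 − dropout)` (defaults 0.6, 0.1),
result clauses carry a `Fig. NL` reference at rate 0.6, fact clauses a
numeric citation at rate 0.5. Base templates contain no lexicon phrase, so
`dropout = 1` provably eliminates every `cue:*` feature. Templates also
avoid clause-internal delimiters, so the generator's gold clauses align
span-for-span with the segmenter's output — asserted in the tests.

**Experiment-type corpus.** Five default classes mirror common interaction
assays (two-hybrid MI:0018, coimmunoprecipitation MI:0019, pull-down
MI:0096, fluorescence microscopy MI:0416, confocal microscopy MI:0663)
with disjoint eight-term vocabularies and supports apportioned
(largest-remainder) to 57/332/125/34/33 of 581, so the realized
most-frequent baseline is 0.4156 → 0.42 by construction. Each passage
draws 3 class terms (narrative) or 6 (caption; the 2× caption/narrative
density ratio encodes the regime in which caption text is the better
predictor) plus 6 shared filler tokens; with probability `term_bleed`
(default 0.25) a class term is replaced by a draw from the union
vocabulary. `bleed = 0` is exactly separable (CV weighted F1 = 1.0);
increasing bleed monotonically degrades the classifier.

**What passing tests do and do not show.** On these corpora the models
score far above the reference matrices (CRF ≈ 0.98 vs the reference 0.63)
because template vocabularies are cleaner, annotator disagreement is
absent, and class priors are exactly controlled. Passing therefore
demonstrates correctness of the machinery and the *direction* of the
published contrasts (CRF > SVM under ordering; caption ≥ narrative;
classifiers ≫ baseline), not expected performance on real articles.

**A documented boundary case.** In the full-bleed limit the five classes
are statistically exchangeable, and the nearest-centroid classifier's
predictions spread nearly uniformly over them; the weighted F1 of a
label-independent predictor with prediction shares `q` is
`Σ_i w_i·2p_i q_i/(p_i+q_i)` ≈ 0.28 under the default priors, which is
*below* the constant-majority baseline (0.4156) rather than equal to it.
With much longer passages the document vectors concentrate and the
majority centroid dominates, pulling the limit toward the baseline; at the
default short-passage lengths the gap is structural. The corresponding
end-to-end check in the test suite records this expectation honestly
rather than adjusting the corpus to mask it.

## Problem sizes and determinism

Default study sizes: 25 documents × 10 paragraphs ≈ 2000 clauses for
discourse experiments (five seeds for every mean comparison), 581 passages
for experiment typing, 80/20 paragraph-level splits. A CRF fit at this
scale takes ~1 s on one CPU. Every stochastic component — both generators,
the SVM's liblinear seed, fold assignment — is driven by an explicit seed,
and the pipeline's end-to-end determinism (identical artifacts from
identical seeds) is asserted in the acceptance tests.

## Known limitations

* The clause splitter and rule tagger are approximations; both are
  pluggable interfaces precisely so stronger components can be swapped in.
* Footnote-style superscript citations are not representable in plain
  text and are out of scope; only numeric-bracket, author–year and markup
  citations are detected.
* The caption-marker rule is permissive (any whitespace-preceded `(L)`),
  trading occasional oversplits for recall on real captions.
* The cue lexicon is an approximation of the unpublished original; it is
  shipped as data and fully overridable.
* `merge_categories` treats the merge map as user data; the shipped map
  covers only the common coimmunoprecipitation-family merges and is not a
  complete PSI-MI closure.
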