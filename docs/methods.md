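# Methods

This note documents the modeling and numerical choices behind `lingscreen`,
what the synthetic corpus generator does and does not emulate, and the known
limitations.

## Preprocessing and tokenization

Only participant speech is kept from interview transcripts (case-insensitive
exact speaker match, default label `participant`), so the model cannot learn
interviewer prompts or dialogue structure. Normalization lowercases, removes
every Unicode punctuation character plus the ASCII apostrophe, and collapses
whitespace; it is idempotent. Apostrophes are stripped rather than expanded
("don't" → "dont"): this avoids a contraction table at the cost of requiring
lexicon files to list apostrophe-free surface forms, which the bundled
lexicons do. All downstream tokenization is a whitespace split of the
normalized text — the only scheme consistent with punctuation-free text.

Dependency parses are consumed as CoNLL-U (multiword ranges and empty nodes
skipped) and validated: contiguous 1..n ids, heads in 0..n, at least one
root, no self-heads. The package deliberately contains no parser; parses of
the *raw* text are expected, and punctuation tokens are excluded from the
distance feature via `upos == PUNCT` so that parsed and normalized views
agree.

## Features

* `neg_words_r` — multiset proportion of tokens in the depression lexicon.
  A default ~50-word list ships with the package and is fully overridable;
  it is a stand-in for curated clinical lexicons, not a clinical instrument.
* `sent_neg` — a transparent valence-lexicon scorer: token valences in
  [−4, 4], a full sign flip when a negator occurs within the 3 preceding
  tokens, score = S⁻ / (S⁻ + S⁺ + N⁰) where S± are summed magnitudes of
  effectively negative/positive tokens and N⁰ counts neutral tokens
  (negators count as neutral). There are deliberately no intensifier,
  capitalization or punctuation rules: normalization has already destroyed
  those cues, and a closed-form scorer keeps the pipeline auditable. Numeric
  parity with general-purpose sentiment tools is not claimed.
* `avg_dep_dist` — token-level pooling across all sentences (not a mean of
  per-sentence means): "average distance between tokens and their heads"
  reads as a token-level average, and pooling makes the statistic
  insensitive to sentence segmentation.
* `emb_1` — dot product of the transcript embedding with one right singular
  vector of the training embedding matrix. The SVD is applied **without
  centering**: centering would turn the leading direction into a deviation
  axis and silently change the projection. Column signs are fixed by making
  each column's largest-magnitude entry positive; the pipeline additionally
  re-orients the selected component so that its training-split correlation
  with the labels is positive, giving the coefficient of `emb_1` a defined
  direction. Defaults: k = 8 components (small enough to audit, enough to
  cover the expected index), component index 2 fixed, with a
  point-biserial-correlation selector (`component_policy: correlate`) as the
  data-driven alternative.

The built-in embedding backend is a hashed bag-of-words projection: tokens
are MD5-hashed into 2¹⁸ buckets, each occupied bucket maps to a Gaussian
vector drawn from a counter-based RNG keyed on (seed, bucket), and rows are
L2-normalized. It is deterministic across processes and has no stored
weights. It captures lexical overlap only — none of the contextual semantics
a sentence-transformer provides — which is sufficient for testing the SVD /
projection machinery and for the synthetic corpus, whose semantic signal is
lexical by construction. A sentence-transformer adapter satisfying the same
contract is included as optional, untested plumbing.

## Classifier, calibration, threshold

The fit minimizes `C · Σ log(1 + exp(−ỹ(w·x + b))) + ‖w‖₁` with an
unpenalized intercept (inverse-regularization convention, so the default
grid 10⁻² … 10² in steps of 10⁰·² is interpretable and contains 0.6310, the
operating value published for the DAIC-WOZ model whose coefficients ship as
`PUBLISHED_COEFFICIENTS`). Solver: proximal
gradient with Nesterov acceleration and adaptive restart; step size 1/L with
L = C·σ²max([X 1])/4; convergence when the largest parameter change in one
proximal step is below 1e−7, cap 10,000 iterations. Soft-thresholding yields
exact zeros, so "retained features" is well defined. Features are z-scored
with training-set mean/sd before fitting (dev/test reuse training
statistics); this makes coefficient magnitudes comparable across features,
and is recorded as this package's assumption rather than a claim about any
external implementation.

C is selected by stratified 5-fold CV maximizing mean held-out AUC of raw
scores; exact ties break toward the smaller C (sparser model). AUC is
computed on raw scores because Platt calibration is a monotone transform and
cannot change it. Platt scaling maximizes the Bernoulli likelihood of
p = 1/(1 + exp(A·s + B)) against the standard smoothed targets
t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2) (BFGS with analytic gradient, initialized
at A = 0, B = log((N₋+1)/(N₊+1))). Calibration is fitted on the development
split by default (a training-split option exists): the threshold is chosen
there anyway, and holding calibration out of training keeps the probability
scale honest at the operating point.

The decision threshold is the **largest** candidate (the distinct dev
probabilities plus 0, inclusive ≥ rule) whose development-set sensitivity
meets the floor (default 0.92). Feasibility is total — the minimum positive
probability always achieves sensitivity 1 — and among equal-sensitivity
candidates the largest threshold maximizes specificity. Evaluation reports
Mann–Whitney AUC (ties half-credited; identical to trapezoidal ROC
integration) and the confusion-matrix rates at the fixed threshold.

## Synthetic corpus generator

The generator emulates exactly the structure the pipeline assumes, with
analytically controlled effect sizes:

* **Lexicon rate**: depression-lexicon tokens at per-token rates
  (0.02 control, 0.10 depressed) — transcript-level rates are then binomial
  means, so group gaps come with exact standard errors.
* **Valence**: valenced tokens at rate 0.10 with group mean valence
  (+0.8 control, −0.8 depressed), realized by mixing disjoint positive- and
  negative-valence word pools (pools are disjoint from the depression
  lexicon so each token category moves exactly one feature).
* **Syntax**: chain parse templates where token i attaches to the sentence
  root with probability q, giving E[mean distance] = 1 + q(m/2 − 1) at
  sentence length m = 8; q is solved per group from the targets
  (2.0 control, 1.3 depressed). Distances are controlled analytically, not
  by a real parser.
* **Semantics**: a label-independent "style" filler rate drawn per
  transcript from U(0.05, 0.35) creates the dominant bag-of-words variance
  axis, while group-specific theme vocabularies at rate 0.05·topic_signal
  (default topic_signal 0.8) carry the label on a *non-dominant* axis —
  the mechanism that makes a non-leading SVD component the informative one.
* Defaults: 150 transcripts per group (n = 300), 400 tokens per transcript;
  splits follow the 106/35/47 reference proportions. All randomness flows
  from one seed through counter-based substreams, so any transcript is
  reproducible in isolation.

What it does **not** emulate: real conversational English, interviewer
dynamics, questionnaire (PHQ-8) semantics, topic drift, disfluency
structure, or any age/cultural variation. Passing tests therefore
demonstrate that the pipeline recovers known statistical structure of the
kinds it models — not clinical validity on real interviews. With the default
effect sizes the corpus is strongly separable (AUC near 1), which is
intentional: the corpus-level tests check mechanism (directions, leakage,
thresholds), while weaker-signal regimes are probed at the abstract feature
layer (`generate_feature_dataset`) where effects (1.0, 0.6, 0.6, −0.4) give
test AUCs near 0.8.

## Degenerate inputs and numerical edges

Empty transcripts, single-class label vectors, parse-free transcripts and
non-finite features all raise typed errors (mapped to distinct CLI exit
codes: 2 config / 3 data / 4 degenerate labels). As C → 0⁺ the fit returns
exactly zero weights and the base-rate intercept log(n₁/n₀). A constant
feature column gets unit scale in the standardizer (centered only). Model
and projector JSON round-trip bit-exactly (floats serialized at full repr
precision).

## Problem sizes in tests

The default test suite and the acceptance script run entirely on generated
data: the full-size corpus (n = 300, 400 tokens) for the end-to-end
threshold check; an 80-transcript, 200-token corpus for shared pipeline
fixtures; 50–100 seed repetitions at n = 300 for the selection/recovery rate
checks. These sizes give the rate assertions comfortable binomial margins
while keeping the whole suite under a minute of compute.

## Known limitations

* The hashed backend's `emb_1` is a lexical-semantic proxy; conclusions
  about transformer-embedding components transfer only at the level of the
  SVD/selection machinery.
* The sentiment scorer ignores intensity modifiers, sarcasm and long-range
  negation scope.
* CV-selected C is noisy when the AUC-vs-C curve is flat; in such regimes
  the retained-feature count can vary by a few features across seeds even
  when the sign pattern is stable.
* The default lexicons are small research stand-ins, not validated clinical
  word lists.
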