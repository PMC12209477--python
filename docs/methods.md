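# Methods

## The model

The pipeline treats a stream of timestamped short posts as a longitudinal
corpus. Its unit of analysis is the pooled **document**: all of one user's
posts within one calendar quarter, merged into one token list. Pooling
reduces per-post noise and individual over-representation, and gives topic
models longer, better-conditioned documents; the cost is that every
document-level statistic is a *user-quarter* statistic, not a post-level
one.

Three quantities are extracted per quarter `t`:

* **counts** — documents and unique users;
* **sentiment presence** — for each dictionary category `c`, the percentage
  of documents containing at least one word of `c`. Presence (not word
  rate) is deliberately robust to document length, which varies by orders
  of magnitude after pooling;
* **topic prevalence** — the mean over documents of each dynamic topic's
  share of the document's topic distribution.

Trends in any of these are OLS fits `Y_t = β0 + β1·t + ε_t` with `t` the
0-based quarter ordinal, so `β1` is in units of Y per quarter. R² is
1 − SSE/SST; the p-value is the classical two-sided t test on `β1` with
n − 2 degrees of freedom. A constant series is a defined degenerate case
(`β1 = 0`, R² = 0, p = 1) rather than an error, because presence series of
empty categories legitimately occur. Associations are Pearson correlations
with the same t machinery; perfect correlations report a p at the machine
floor rather than exactly 0. No autocorrelation correction or multiple-
testing adjustment is applied — the trend test here is descriptive, and
consumers who need familywise control should apply it downstream.

## Two-layer NMF dynamic topics

Per quarter, the document–term matrix `A_t` (rows TF-IDF-weighted and
unit-L2-normalized; raw counts available via config) is factorized by NMF
into `k_w` **window topics**. The rows of every quarter's topic–term matrix
`H_t` are L2-normalized (scale folded into `W_t`) and stacked in
(quarter, topic) order into `B`; a second NMF of `B` into K **dynamic
topics** links window topics across quarters, each window topic being
assigned to its argmax dynamic topic (ties to the lowest index).

Both layers use the Frobenius objective with deterministic NNDSVD
initialization and coordinate descent (scikit-learn's solver), `max_iter`
400, `tol` 1e-4. Determinism matters more here than a marginally lower
objective: the whole pipeline is reproducible bit-for-bit given a seed.

`K` is selected by **TC-W2V coherence**: for each candidate K the mean,
over topics, of the mean pairwise cosine similarity among the topic's top
20 terms' embedding vectors. Terms missing from the embedding are dropped
(counts reported); a topic with fewer than two embedded terms is excluded
from the mean with a warning. Ties go to the smallest K. At desk scale the
candidate range is [2, 10]; at full corpus scale ranges like [25, 90] are
the norm and the range is a config parameter.

Document distributions over dynamic topics: a document's window-topic
weights (its `W_t` row normalized to sum 1) are pushed through the
sum-normalized `W₂` rows of its quarter's window topics and renormalized.
A document with an all-zero weight row (possible when all its tokens fell
out of the vocabulary) gets the uniform distribution, logged.

Reported topics pass two filters: overall mean proportion ≥ 3.5% of
documents, then trend R² > 0.1. Both stage outputs are kept, since the
"large but untrended" topics are themselves informative.

### Parameter defaults

| parameter | default | why |
|---|---|---|
| `min_rate` (vocabulary) | 0.001 | a term must appear in ≥ 0.1% of some quarter's documents; one global vocabulary |
| weighting | tfidf + unit rows | standard for NMF topic models; counts via config |
| `k_w` | 6 (desk scale) | a few more than the expected topics per window, leaving a factor for background/sentiment mass; at full scale ~10 |
| `t_top` | 20 | top terms per topic entering coherence |
| `k_range` | (2, 10) desk / config | candidate dynamic-topic counts |
| filters | 3.5%, R² > 0.1 | reporting thresholds for topic tables |

## The synthetic study conditions

`synthcorpus.default_spec` defines the desk-scale conditions used by the
tests, the analysis scripts and the acceptance script: T = 8 quarters,
Poisson(200) documents per quarter, K_true = 5 planted topics over disjoint
100-word blocks (near-uniform within-block distributions with a mild Zipf
tilt, exponent 0.25), a 100-word Zipf background receiving 20% of token
mass, document mixtures ~ Dirichlet(prevalence), document length ≈ 2 posts
× 20 tokens. Planted prevalence trajectories: one rising
(+2.5 points/quarter), one falling, one spiking at quarter 5 (the "event"
topic), two stable; rows renormalized to a simplex. Ten sentiment
categories mirror the affective-processes / negative-emotions / drives
subtree of a LIWC-style hierarchy; each injects ≥ 1 of its words per
document with probability `clip(baseline + slope·t + spikes, 0, 1)` —
anxiety spikes at the same quarter as the event topic so the
sentiment–topic correlation has a planted positive case. Embeddings are
unit vectors: topic words cluster around a per-topic random anchor
(Gaussian noise, sd 0.1, dim 50); background and sentiment words are
independent random directions.

What this emulates: the statistical shape the analysis assumes — pooled
documents, trended topic prevalence with event spikes, trended category
presence, embeddings under which true topics are coherent. What it does
not: natural-language morphology and segmentation (tokens are synthetic
strings; the whitespace tokenizer is exact), topic overlap in vocabulary,
user identity across quarters, reshare cascades, or embedding polysemy.
Passing recovery tests therefore demonstrates the pipeline's correctness
and identifiability under its own assumptions, not performance on real
text — on real corpora coherence values are far lower and topic separation
far weaker than here.

Scale was chosen so the full two-layer fit plus model selection runs in
seconds and the complete validation suite in well under a minute, while
keeping per-quarter binomial standard errors (~3.5 points at n = 200,
p = 0.5) small enough that trend signs and spikes are identifiable.

## Numerical and design choices

* "Occurrence rate < 0.1%" is read as per-quarter *document frequency*: a
  term survives if, in at least one quarter, it appears in ≥ 0.1% of that
  quarter's documents. This yields a single global vocabulary and makes
  the threshold independent of document length.
* Vocabulary order is lexicographic; top-term ranking breaks weight ties
  lexicographically — both so fixed seeds give byte-identical outputs.
* Quarters are calendar quarters in a single configured timezone; the
  study window must start on a quarter boundary.
* Emoji/symbol removal is defined by Unicode general categories
  (So/Sk/Sc/Sm, format and private-use codes) plus the supplementary
  pictograph blocks; full-width→half-width mapping is NFKC.
* Dictionary matching: exact entries plus trailing-wildcard stems, checked
  via a prefix map in O(token length); no infix patterns, no negation or
  context handling (word-based scoring is context-free by design).
* The fixture dictionary lists only the owning category per word (no
  ancestor roll-up), so each category's presence trajectory equals its own
  injection trajectory; hierarchy lives in the header's parent column and
  explicit roll-ups are the consumer's choice.
* Yearly aggregation for external rate tables is the mean of the four
  quarterly values; incomplete trailing years are dropped.
* The word2vec text reader/writer is local (~60 lines): the format is
  trivial and this keeps the dependency surface to numpy/scipy/pandas/
  scikit-learn/pyyaml.
* The analysis is exposed as numbered scripts over the library rather than
  a console entry point; each script is a thin driver that reads the
  previous stage's tables, so every reported number is recomputable from
  stage artifacts.

## Known limitations

* Plain OLS on autocorrelated quarterly series overstates significance;
  the p-values are descriptive.
* NMF is not identifiability-guaranteed for overlapping topic supports;
  the recovery guarantees shown here depend on the planted blocks being
  disjoint.
* Coherence-based selection can plateau above the true K when surplus
  topics split coherent blocks; in the validation runs the surplus factor
  instead absorbs incoherent background mass, which is what makes the
  criterion peak at K_true in ≥ 9 of 10 seeds.
* The morphological tokenizer contract is untested against a real
  analyzer in this repository (none is a dependency); only the whitespace
  default is exercised.
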