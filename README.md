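# discoursetrends

Longitudinal analysis of health-relevant discourse on social media: how do
public sentiment and discussion topics around a public-health issue (for
example, attitudes toward older drivers) change over years of short posts,
and how do those changes relate to each other and to external statistics?

The package implements the full pipeline for this kind of infodemiology
study, plus a synthetic corpus generator with planted ground truth so the
whole method can be validated end to end without access to platform data or
licensed dictionaries.

## Method

1. **Preprocessing** (`corpus`). Reshares are dropped and quoted/replied
   text is stripped; text is normalized (URLs, hashtags, emoji and symbols
   removed; lowercased; full-width mapped to half-width) and tokenized
   (whitespace by default, a morphological analyzer is a pluggable
   callable). All of one user's posts within one calendar quarter are
   merged into a single *document* — the unit of analysis. Terms kept in
   the vocabulary must appear in at least 0.1% of some quarter's documents.
2. **Sentiment** (`lexicon`). A hierarchical LIWC-format dictionary (exact
   words and trailing-wildcard stems) scores each document by *presence*:
   a category counts if at least one of its words occurs. The statistic is
   the per-quarter percentage of documents containing each category.
3. **Dynamic topics** (`dyntopics`). Two-layer NMF: each quarter's
   document–term matrix `A_t` (TF-IDF, unit-norm rows) is factorized into
   *window topics* `A_t ≈ W_t H_t`; the unit-normalized rows of all `H_t`
   are stacked into `B`, which a second NMF factorizes into *dynamic
   topics* `B ≈ W₂H₂` linking window topics across time. The number of
   dynamic topics K maximizes TC-W2V coherence — the mean pairwise cosine
   similarity among each topic's top-20 terms' word2vec vectors, averaged
   over topics. Document-level dynamic-topic distributions follow by
   pushing each document's window-topic weights through `W₂`. Topics are
   reported if they average ≥ 3.5% of documents and their quarterly series
   has trend R² > 0.1.
4. **Statistics** (`trendstats`). Trends are OLS fits of
   `Y_t = β₀ + β₁ X_t + ε_t` with `X_t` the quarter ordinal; associations
   are Pearson correlations; both with two-sided t tests (n − 2 df).
   Quarterly series can be aggregated to yearly means for comparison with
   yearly external rate tables.

`synthcorpus` generates corpora in which all of this structure is planted
and known: K topics over disjoint vocabulary blocks with linear prevalence
trends and quarter-localized event spikes, sentiment injection
probabilities with trends and spikes, topic-aligned embeddings, and a
fixture dictionary. `pipeline.run` orchestrates everything from a config.

## Worked example

```
python analysis/01_simulate.py --seed 1      # synthetic study inputs
python analysis/02_sentiment.py              # presence proportions + trends
python analysis/03_topics.py --seed 1        # two-layer NMF + selection
python analysis/04_correlations.py           # sentiment-topic correlations
```

The third step prints (seed 1):

```
coherence selected K=5 (TC-W2V=0.671 over K in (2, 10))
 topic_id  overall_mean_pct  beta1  r_squared     p  passes_mean_filter  passes_trend_filter
        0             18.51 -2.019      0.880 <.001                True                 True
        1             25.41  1.856      0.714  .008                True                 True
        2             20.60 -0.717      0.278  .179                True                 True
        3             14.98  0.708      0.074  .514                True                False
        4             20.49  0.172      0.032  .672                True                False

planted-topic recovery: matched cosines [0.929, 0.937, 0.937, 0.938, 0.935]
```

Reading: coherence-based selection found the five planted topics; the
recovered quarterly series show the planted rising (+1.86 points/quarter)
and falling (−2.02 points/quarter) trends with the stated significance;
all five recovered topic–term profiles match their planted blocks at
cosine ≈ 0.93. Step 2 prints the ten-category sentiment trend table in the
same form (slope in percentage points of documents per quarter), and step
4 the correlation table between sentiment and filtered topic series.

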