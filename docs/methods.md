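# Methods

`narralex` quantifies illness narratives along three axes — dictionary-based
linguistic features, between-group statistics, and word co-occurrence
networks — and ships a synthetic corpus generator so the whole pipeline can
be validated with known ground truth. This note documents the models,
parameters, numerical choices, and limitations.

## Corpus model

A corpus is a set of narratives, each either a first-person account (FPA,
written by a person with lived experience of psychosis) or a third-person
account (TPA, written by a family member, friend, or clinician). FPAs may
carry a human-coded binary flag for interpersonal difficulties (social
anxiety, no close friends, constricted affect). That flag is an *input*: it
comes from human coding, never from the text analysis itself.

Prolific authors publish several narratives, so all works by one author are
merged before analysis: texts concatenated in ascending publication order
(ties broken by narrative id), separated by a blank line so sentence
boundaries survive for the co-occurrence units. The merged
interpersonal-difficulties flag is the logical OR of the coded components —
a mention anywhere in an author's works marks the author. The merge is
idempotent and conserves characters up to the inserted separators.

Text is NFC-normalized at load; line endings are folded to `\n` and curly
apostrophes (U+2019) mapped to ASCII `'` so that `don’t` and `don't`
tokenize identically. Group splitting produces four subsets — FPA, TPA,
FPA_ID, FPA_noID — where the two ID subsets partition the coded FPAs;
uncoded FPAs stay in the FPA subset only and are logged.

## Linguistic features

**Tokenization.** A token is a maximal run of letters/digits with internal
apostrophes retained; hyphens split tokens. Sentences end at `.`, `!`, or
`?` followed by whitespace (closing quotes/brackets tolerated). All scoring
is on lowercase surface forms; there is no lemmatization.

**Category percentages.** Every category score is
`100 × matching tokens / total tokens`. A pattern is a literal word or a
stem ending in `*` (prefix match); a token may count toward several
categories, and tokens count with multiplicity. Tables round to two
decimals; full precision is kept internally.

**The packaged lexicon.** The proprietary dictionary used for this kind of
analysis cannot be shipped, so `narralex` packages a small open lexicon
(`data/default.dic`, percent-delimited dialect) covering the categories the
pipeline needs: `pos_tone`, `neg_tone`, `social`, `article`, `prep`,
`ppron`, `ipron`, `auxverb`, `conj`, `adverb`, `negations`, `exclusive`.
Any dictionary in the same dialect (or a two-column TSV) can be substituted.
Scores from the packaged lexicon are *not* comparable to proprietary
outputs; they are internally consistent percentages.

**Negation-adjusted tone.** A naive dictionary match scores "not good" as
positive. An emotion token is treated as negated when a negation token
(`not, no, never, none, cannot`, and n't contractions) occurs at most
*window* tokens before it in the same sentence; window defaults to 3, a
common scope convention, and is configurable. Negated occurrences are
removed from the tone numerator only — the denominator stays the total
token count — and their count is reported as `negation_case_count`
(token-level occurrences; exclusion is token-level, not sentence- or
narrative-level).

**Specific pronouns.** Five built-in classes (I, we, you, she/he, they),
each a fixed word list over subject/object/possessive/reflexive forms,
scored as percent of total tokens.

**Summary scores.** Analytic, Clout, and Authentic are *surrogate* linear
composites, clamped to [0, 100]:

- analytic = 30 + article + prep − ppron − ipron − auxverb − conj − adverb − negations
- clout = 50 + 4·we + 2·you − 3·I − 2·negations
- authentic = 40 + 4·I + 2·exclusive − 3·she_he

The directions follow the documented construct definitions (confidence
rises with collective/addressee pronouns and falls with self-reference and
hedging; authenticity rises with self-reference and exclusive words). The
exact proprietary regression weights are unpublished, so the coefficient
vectors here are configuration with the defaults above; every output is
labelled `"surrogate, not proprietary LIWC"` to prevent silent conflation.

## Group statistics

**Variance-gated t-tests.** Levene's test (classic form, centered on group
means; Brown–Forsythe available by passing medians upstream is out of scope)
gates the two-sample test: Levene p < .05 selects Welch's test with
Satterthwaite (possibly fractional) degrees of freedom, otherwise Student's
pooled test with df = n1 + n2 − 2. Cohen's d uses the pooled SD with n−1
weights; its sign matches t. When a variable is constant and equal in both
groups (e.g. a pronoun class no narrative uses), the battery reports t = 0,
p = 1 rather than aborting the family.

**Multiplicity.** Benjamini–Hochberg step-up adjustment, applied within
declared families. The default families mirror the two table blocks of the
analysis: {authentic, clout, analytic, pos_tone, neg_tone, social,
total_pronouns} and the five specific-pronoun classes, each adjusted
separately per contrast. The family partition is configurable.

**Covariate adjustment and partial correlation.** ANCOVA is the linear
model `y ~ group + covariate` (with one covariate and two groups the
coefficient t-test coincides with the Type-III F-test). Partial correlation
correlates the residuals of x and y on the control, with p from the
t transform on n − 3 df; residual norms below 1e−10 of the raw scale are
treated as degenerate.

**Inter-rater reliability.** Krippendorff's alpha (nominal) from the
coincidence matrix over all pairable values within items, with a percentile
bootstrap over items for the 95% CI (default 1000 replicates, seeded). The
CI method is a standard reproducible choice; the interval is clipped to
bracket the point estimate. Both contrasts are reported with and without
word count covaried out, rather than choosing one.

## Word networks

Per group subset, narratives are tokenized, stopwords (a fixed versioned
list packaged as `data/stopwords.txt`), configured non-meaningful words
(default `{things, one, will, much}`), and purely numeric tokens are
dropped. The co-occurrence unit defaults to the sentence — whole-narrative
units on long essays would yield near-complete graphs and destroy bridge
structure — with a sliding window (default width 10, never crossing
narrative boundaries) as the alternative. Within one unit every unordered
pair of distinct words co-occurs exactly once (set semantics, robust to
repetition); edge weight counts co-occurring units.

Betweenness centrality is computed on the **full** retained-vocabulary
graph with unweighted shortest paths (unnormalized, unordered-pair
convention); an inverse-weight distance mode (edge length 1/weight) is
available since heavier co-occurrence can be read as proximity. The top-k
(default 20) most frequent words control display only. The bridge ranking
sorts displayed words by betweenness descending, ties by frequency then
alphabetically. Edge styling highlights the heaviest 40% of edges (ties at
the threshold included). Graphs export as GraphML plus node/edge TSVs;
round-trips are exact.

Open choices resolved here: surface forms (no lemmas); frequency ranking
happens after exclusion-list pruning; display-oriented weights do not enter
the default shortest-path metric.

## Synthetic corpora

The generator emulates the statistical structure the analysis assumes, not
prose. Per narrative: length L from a log-normal (per-group mean/SD
defaults mirror the study-shaped word counts: 4064 ± 4581 tokens for coded
FPAs, 2022 ± 1171 uncoded, 2670 ± 1629 TPA); per-category emission rates
drawn around group means with a Gaussian narrative-level dispersion
(`rate_dispersion`, default 0.01 on the rate scale = 1 percentage point);
`round(rate × L)` tokens emitted per category from disjoint word pools that
match exactly one lexicon category each, the remainder from a closed list
of 500 neutral pseudo-words verified to match no category or stopword;
tokens shuffled into sentences of 8–15; finally a negation token is
inserted immediately before each emotion token with probability
`negation_rate` (default 0.05).

Because the narrative-level dispersion dominates the (deterministic,
rounded) within-narrative counts, a planted standardized effect d between
two groups is realized by shifting one group's mean rate by
d × `rate_dispersion`. Group mean rate defaults are informed by the
study-shaped group profiles (first-person accounts I-heavy and
social-light; third-person accounts she/he- and social-heavy; the coded
group more negative and less positive in tone).

Randomness uses one master seed with per-narrative substreams derived by
counter, so corpora are byte-stable under narrative-count changes and every
downstream artifact is reproducible from a single integer.

The bridge generator builds sentences from one of two disjoint word
clusters (never both, except with a configurable leak probability that
injects one opposite-cluster word), inserting the designated bridge word
into sentences of both clusters, so with zero leak every inter-cluster
shortest path passes through the bridge.

Rater codings: each simulated rater independently reports the true binary
label with a fixed accuracy in [0.5, 1].

**What passing tests do and do not show.** The generator has no grammar,
topics, or discourse structure; emission is exchangeable within a
narrative. Validation on it demonstrates that the *pipeline* is calibrated
(null rejection ≈ nominal), recovers planted effects and bridges, and is
deterministic — not that any linguistic claim holds on real narratives.

## Validation experiments and problem sizes

`narralex.experiments` runs each validation end to end (sizes chosen to
keep a full run around a minute): betweenness vs an exhaustive
shortest-path-enumeration oracle on 200 random graphs of ≤ 8 nodes; BH
step-up vs hand-computed vectors and an independent reference on 1000
random vectors; null calibration over 400 seeded corpora (60 narratives
per group, 7-variable family, log-normal lengths ~250 tokens — the
simulation's own problem size; narrative length only sets within-narrative
sampling noise); planted-effect recovery over 100 seeds (d = 0.5 estimate;
family-best detection at d = 1); bridge recovery over 100 seeds plus a
leak grid {0, 0.1, 0.3, 0.5} × 50 seeds; reliability under perfect,
chance, and graded accuracy; a fully negated corpus (adjusted tones must
be exactly zero); Welch/Student agreement under equal n and exactly equal
variances; and a study-shaped end-to-end replica (56 + 77 + 44, lengths
scaled to 10% to keep the dense filler-vocabulary networks light) run
twice to verify byte-identical outputs.

## Known limitations

- The packaged lexicon is small; its scores are internally consistent but
  not comparable across lexicons, and the summary composites are labelled
  surrogates.
- Negation handling is a fixed-window scope heuristic; it misses long-range
  negation and ignores intensifiers ("not very good").
- Percentages on short narratives are coarse; narratives under 25 tokens
  are flagged (never dropped) by the pipeline.
- t-tests on percentage variables rely on approximate normality; strongly
  skewed categories at small n inflate error rates mildly (the null
  calibration bounds this at the tested sizes).
- Inter-group network differences are descriptive: no inferential test is
  attached to centrality or ranking differences.
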