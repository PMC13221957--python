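# narralex

Quantitative analysis of illness narratives: dictionary-based linguistic
features with negation-aware emotional tone, between-group statistics with
false-discovery-rate control, inter-rater reliability, and word
co-occurrence networks with betweenness-centrality bridge ranking.

## The problem

First-person accounts (FPAs) of psychosis — essays written by people with
lived experience — carry information about social functioning that
structured interviews miss. Comparing them with third-person accounts
(TPAs, written by family or clinicians), and comparing FPAs coded for
interpersonal difficulties with those without, requires a reproducible
pipeline:

1. **Features.** For each narrative, the percentage of tokens matching each
   dictionary category, `100·k/N` — positive/negative tone, social words,
   pronoun classes (I, we, you, she/he, they) — plus surrogate Analytic /
   Clout / Authentic composites. Tone is negation-adjusted: an emotion token
   preceded by a negation within 3 tokens in the same sentence ("not good")
   is excluded from the tone numerator.
2. **Statistics.** Per variable, a Levene-gated two-sample t-test (Welch
   with Satterthwaite df when variances differ, pooled Student otherwise),
   Cohen's *d*, and Benjamini–Hochberg adjustment within declared variable
   families; ANCOVA with word count as covariate, partial correlation
   controlling word count, and Krippendorff's α (nominal, bootstrap CI) for
   the human codings.
3. **Networks.** Per group, an undirected word co-occurrence graph (nodes =
   retained words, edge weight = number of sentences in which a pair
   co-occurs). Betweenness centrality `g(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` is
   computed on the full graph; the top-20 most frequent words are displayed
   and ranked by betweenness, so the top-ranked word is the "bridge"
   between semantic clusters; the heaviest 40% of edges are highlighted.

Real journal essays cannot be redistributed, so the package includes a
synthetic corpus generator with controllable group rates, lengths, planted
effect sizes, negated-emotion insertions, planted bridge words, and rater
accuracies — every stage is validated against known ground truth. See
`docs/methods.md` for the full model description.

## Worked example

Generate a study-shaped synthetic corpus (133 FPAs, of which 56 coded with
interpersonal difficulties, plus 44 TPAs; lengths scaled to 10% here) and
run the full pipeline:

```python
import pandas as pd
from narralex.synthetic_corpus import SyntheticSpec, generate_corpus
from narralex.pipeline import RunConfig, run_full_pipeline

spec = SyntheticSpec(seed=7, length_distribution={
    g: (m * 0.1, s * 0.1)
    for g, (m, s) in SyntheticSpec().length_distribution.items()})
corpus, truth = generate_corpus(spec)
manifest = run_full_pipeline(RunConfig(output_dir="demo", seed=7), corpus=corpus)
print(manifest["group_sizes"])

t = pd.read_csv("demo/comparison_fpa_vs_tpa.csv")
cols = ["variable", "mean1", "mean2", "test_kind", "t", "df", "p_adj", "cohen_d"]
print(t[t.variable.isin(["pron_I", "social", "pos_tone"])][cols].round(3))
```

prints

```
{'FPA': 133, 'TPA': 44, 'FPA_ID': 56, 'FPA_noID': 77}
variable  mean1  mean2 test_kind       t    df  p_adj  cohen_d
pos_tone  2.477  2.422   student   0.301 175.0  0.764    0.052
  social  8.366 14.867   student -36.106 175.0  0.000   -6.279
  pron_I  8.459  4.152   student  20.094 175.0  0.000    3.495
```

Read: in this synthetic corpus first-person accounts use "I"-words far more
(8.46% vs 4.15% of tokens, *d* = 3.5) and social words far less than
third-person accounts, while positive tone does not differ (BH-adjusted
p = .76) — exactly the contrasts the generator planted. (Synthetic
narratives have far less within-group spread than real essays, hence the
outsized *d* values.) The output directory also contains
`comparison_fpa_id_vs_noid.csv`, four network bundles
(`network_<GROUP>.graphml`, node/edge TSVs, `*_bridge_ranking.txt` whose
first line is the most central word), and `manifest.json` with sha256
hashes of every output: rerunning with the same seed reproduces them
byte-for-byte.

The same steps are available from the shell:

```bash
narralex simulate --seed 7 --out corpus.tsv
narralex run --corpus-tsv corpus.tsv --out-dir demo --seed 7
narralex features --corpus-tsv corpus.tsv --out features.csv
narralex network --corpus-tsv corpus.tsv --group FPA_ID --out-prefix net_id
```

To analyze a real corpus, point `narralex features` / `narralex run` at a
metadata CSV (`narrative_id, author_id, file, account_type,
interpersonal_difficulties, publication_order`) plus a directory of UTF-8
`.txt` files; works by the same author are merged before analysis.

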