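# flsatopics

Fuzzy topic models for interpretable text classification.

Clinical free text (e.g. nursing and physician notes in an electronic health
record) can drive useful predictions — such as flagging patients at risk of
inpatient violence — but clinicians will not act on a score they cannot
interpret. One route to interpretability is to classify *through a topic
model*: represent each document by how strongly it expresses each of C
topics, feed those C numbers to a simple classifier, and read the topics'
top words to understand what the classifier saw. That raises two questions
this package is built to answer for a given corpus: **how interpretable are
a model's topics**, and **how well do its topic embeddings predict**?

## What is implemented

**Topic models.** A topic model returns two row-stochastic matrices:
P(W<sub>i</sub>|T<sub>k</sub>), the probability of word *i* given topic *k*
(C×M), and P(T<sub>k</sub>|D<sub>j</sub>), the probability of topic *k*
given document *j* (N×C). The package fits:

- **FLSA** — weight the document-term matrix **A** (tf-idf by default),
  take a truncated SVD **A** = **UΣV**ᵀ, fuzzily cluster the *document*
  projection **U**, read the memberships as P(T|D), and recover P(W|T) by
  Bayes' theorem with P(D) proportional to document lengths.
- **FLSA-W** — cluster the *word* projection **V** instead: topics are
  distributions over words, so clustering words targets them directly.
  Memberships are P(T|W); with P(W) proportional to corpus word counts,
  Bayes' theorem gives P(W|T) = P(T|W)P(W)/P(T) and
  P(T|D) = Σ<sub>i</sub> P(T|W<sub>i</sub>)P(W<sub>i</sub>|D).
- **FLSA-V** — replace the SVD projection by a stress-minimizing embedding
  of word co-occurrence (association-strength similarities), then proceed
  as FLSA-W.
- Baselines: **LSI** (top-C SVD factors read as topics) and **NMF**
  (multiplicative updates), plus fuzzy c-means (FCM) and Gustafson–Kessel
  (GK) clustering variants for each FLSA model.

**Interpretability.** Topic quality is scored by the product of

- **c_v coherence** — NPMI(w<sub>i</sub>, w<sub>j</sub>) =
  log[(P(w<sub>i</sub>,w<sub>j</sub>)+ε)/(P(w<sub>i</sub>)P(w<sub>j</sub>))]
  / (−log(P(w<sub>i</sub>,w<sub>j</sub>)+ε)), with probabilities from a
  boolean sliding window of 110 tokens, combined by indirect cosine
  confirmation and averaged over the top-20 words and over topics
  (range [0, 1]); and
- **topic diversity** — D = |W*|/(nC), the fraction of distinct words among
  all topics' top-n lists (1 = no sharing, 1/C = all topics identical).

**Classification.** Documents are embedded either as their full P(T|D) row
or as the aggregated P(w|T<sub>k</sub>) of top-20 topic words present in
the document, scored by logistic regression under stratified 10-fold
cross-validation, and evaluated by **AUC** and by **AUK** — the area under
the Cohen's-kappa-vs-FPR curve, which corrects for chance agreement and is
far more demanding than AUC under heavy class imbalance.

**Synthetic corpora.** A planted-topic generator (Dirichlet document
mixtures over C topic-word distributions, rare binary labels driven by
topic proportions) makes every stage testable against known ground truth.

## Worked example

```python
from flsatopics import (
    ClusteringConfig, apply_weighting, build_dtm, crossval_predict, embed_full,
    evaluate_model, fit_flsa_w, generate_corpus, generate_labels, kappa_curve_auk,
    roc_auc, top_n_words,
)

corpus, truth = generate_corpus(seed=0)          # 500 docs x 200 tokens, 5 planted topics
labels = generate_labels(truth, prevalence=0.10, seed=0)

dtm = apply_weighting(build_dtm(corpus), "tfidf")
model = fit_flsa_w(dtm, C=5, cfg=ClusteringConfig(method="fcm", seed=0), vocab=corpus.vocab)

for k, words in enumerate(top_n_words(model, n=5)):
    print(f"topic {k}:", " ".join(w for w, _ in words))

report = evaluate_model(model, corpus)
print(f"coherence={report.coherence:.3f} diversity={report.diversity:.3f} "
      f"interpretability={report.interpretability:.3f}")

scores = crossval_predict(embed_full(model), labels, folds=10, seed=0)
print(f"AUC={roc_auc(scores):.3f} AUK={kappa_curve_auk(scores).auk:.3f}")
```

Output:

```
topic 0: w295 w249 w232 w261 w209
topic 1: w177 w106 w152 w150 w159
topic 2: w394 w382 w386 w333 w356
topic 3: w402 w456 w415 w489 w460
topic 4: w009 w079 w091 w071 w010
coherence=0.991 diversity=1.000 interpretability=0.991
AUC=0.999 AUK=0.252
```

The five planted topics occupy disjoint 100-word vocabulary blocks, and the
fitted top words land in five different blocks: the topics were recovered
(diversity 1.000 — no word shared between topics — and near-perfect
coherence, since words from one block co-occur constantly). The labels mark
the 10% of documents richest in topic 1; the full-distribution embedding
separates them almost perfectly (AUC 0.999), while AUK (0.252) reminds us
that chance-corrected agreement is a much stricter yardstick at a 9:1 class
imbalance.

The same pipeline is available from the shell:

```bash
flsatopics simulate --n-docs 500 --out data/
flsatopics fit data/corpus.jsonl -k 5 --algorithm flsa_w_fcm --out model/
flsatopics evaluate data/corpus.jsonl model/
flsatopics classify data/corpus.jsonl model/ --embedding full
flsatopics grid data/corpus.jsonl --config grid.yaml --out results.csv
```

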