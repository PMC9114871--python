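# Methods

This note records the models implemented, the defaults chosen where the
methods literature leaves them open, and what the synthetic validation does
and does not establish.

## Preprocessing and encoding

Raw texts are lowercased, diacritics are reduced to base letters (Unicode
NFKD decomposition, combining marks dropped), punctuation is stripped,
tokens are split on whitespace, and stop words and single-character tokens
are removed. The stop-word list is an input, not baked in. Documents with
fewer than 101 tokens are discarded (strictly fewer: a 101-token document
is kept), the conventional floor for clinical-note modeling where very
short notes carry little signal. Counts are encoded as a sparse N×M
document-term matrix; the default weighting is raw tf × ln(N/df) —
unsmoothed, unnormalized tf-idf, so a word present in every document gets
weight zero. Other tf-idf variants can be substituted by weighting the
counts externally; the fitters only assume a non-negative weighted matrix.

## The FLSA family

All three fuzzy models share a skeleton: project, fuzzily cluster,
recombine by Bayes' theorem.

**Projection.** Truncated SVD of the weighted matrix, A ≈ U Σ Vᵀ, computed
by Lanczos iteration with a fixed start vector and a canonical sign
convention (the largest-magnitude V entry of each component is positive),
so factorizations are bit-reproducible and equivariant under row/column
permutations. The number of retained dimensions S defaults to C, one
dimension per requested topic — the common choice that removes a free
parameter; it is configurable. FLSA-V instead embeds words in a
`proj_dim`-dimensional space (default 2) by SMACOF stress majorization of
dissimilarities 1/(1+s), where s is the association strength
c<sub>ij</sub>/(c<sub>i</sub>c<sub>j</sub>) of document-level co-occurrence
counts — a frequency-normalized similarity, so common words are not pulled
together merely for being common. Components of the co-occurrence graph
that are disconnected carry no relative-placement information; they are
embedded independently and offset along the first axis, with a warning.

**Clustering.** FLSA clusters document projections (rows of U), FLSA-W and
FLSA-V cluster word projections (rows of V, or the stress embedding). For
the SVD-based models, rows are unit-normalized before clustering: in an LSA
space similarity is directional (cosine), while row magnitude mostly
encodes word frequency or document length, and clustering raw rows lets
high-frequency words split by radius rather than by topic. (Raw-row
clustering remains available via `normalize_projection=False`.)

Fuzzy c-means uses the standard updates — memberships
u<sub>xk</sub> = 1/Σ<sub>l</sub>(d<sub>xk</sub>/d<sub>xl</sub>)<sup>2/(m−1)</sup>,
centers v<sub>k</sub> = Σ u<sub>xk</sub><sup>m</sup>p<sub>x</sub> / Σ u<sub>xk</sub><sup>m</sup> —
with fuzzifier m = 2, tolerance 1e-6 on the maximum center shift, and an
iteration cap of 300. A point coinciding with a center receives membership
1 there (first such cluster on ties). Gustafson–Kessel replaces the
Euclidean distance by the volume-normalized Mahalanobis distance
d²<sub>xk</sub> = (p−v<sub>k</sub>)ᵀ det(F<sub>k</sub>)<sup>1/S</sup> F<sub>k</sub><sup>−1</sup> (p−v<sub>k</sub>)
with fuzzy covariances F<sub>k</sub>, regularized as
F<sub>k</sub> ← (1−ρ)F<sub>k</sub> + ρ·det(F₀)<sup>1/S</sup>·I (ρ = 1e-4,
F₀ the overall covariance) so degenerate geometry never produces a
singular norm. Centers are initialized k-means++-style from a seeded
generator; the selection runs over lexicographically sorted points so
initialization depends only on the point set. Both algorithms run
`n_init` = 4 independent starts and keep the partition with the lowest
objective: fuzzy clustering objectives have pronounced local minima — for
elongated clusters, the axis-aligned split — and the objective reliably
distinguishes them (the correct stripe partition scores several-fold lower
in our fixtures).

**Bayes recombination.** The fuzzy memberships are conditional topic
probabilities; the remaining factor comes from empirical frequencies.
For FLSA (memberships = P(T|D)): P(D) ∝ document token totals,
P(T) = Σ<sub>j</sub> P(T|D<sub>j</sub>)P(D<sub>j</sub>),
P(D|T) = P(T|D)P(D)/P(T), and
P(W|T) = Σ<sub>j</sub> P(W|D<sub>j</sub>)P(D<sub>j</sub>|T) with P(W|D) the
row-normalized counts. For FLSA-W/-V (memberships = P(T|W)): P(W) ∝ corpus
word totals, P(W|T) = P(T|W)P(W)/P(T), and
P(T|D) = Σ<sub>i</sub> P(T|W<sub>i</sub>)P(W<sub>i</sub>|D). The priors use
raw counts, not tf-idf weights: they are probabilities of observation, not
salience scores. Documents emptied by preprocessing carry zero prior mass;
any all-zero output row is set uniform so both matrices are always
row-stochastic (verified to 1e-8 for every algorithm and seed).

**Baselines.** LSI takes the top-C SVD factors and converts rows of U and
Vᵀ to probabilities by absolute-value normalization — a stated convention
for handling SVD's sign indeterminacy, not a probabilistic derivation. NMF
uses Lee–Seung multiplicative updates on the Frobenius loss (monotone
non-increasing, trace kept on the model); W columns are rescaled by H row
masses before normalization so P(T|D) reflects topic mass.

## Interpretability metrics

c_v coherence follows the four-stage recipe: (1) one-set segmentation of a
topic's top-n words (n = 20); (2) probabilities from a boolean sliding
window of 110 tokens — every contiguous 110-token span of a document is a
virtual document, a shorter document contributes one window, and windows
never cross document boundaries; (3) indirect confirmation: each word's
vector of NPMIs against all top words is compared by cosine with the
summed topic vector; (4) arithmetic means over words and topics. NPMI uses
ε = 1e-12 inside both logarithms and exponent γ = 1; when a marginal
product is zero it is floored at ε, so unseen words score 0 instead of
dividing by zero. Negative cosine confirmations are clipped to 0 so the
aggregate respects the [0, 1] coherence range; unclipped per-topic scores
are reported alongside. Diversity is |W*|/(nC) over the same top-n lists,
bounded by [1/C, 1]; interpretability is the exact product of the two.

## Classification

Embeddings: `full` uses the P(T|D) rows; `topn` sums, per topic, the
P(w|T<sub>k</sub>) of the distinct top-20 words present in the document
(type-based aggregation; a token-weighted variant is behind a flag, since
"aggregate" admits both readings). The classifier is ridge-penalized
logistic regression (penalty strength 1.0, max 1000 iterations, no tuning)
under stratified, seed-shuffled 10-fold cross-validation; stratification
matters because at 10% prevalence unstratified folds can end up with almost
no positives. Every document is scored once, out of fold. AUC is the
tie-aware rank statistic. AUK sweeps thresholds from +∞ down through every
distinct score, computes Cohen's kappa (p<sub>o</sub>−p<sub>e</sub>)/(1−p<sub>e</sub>)
and the false-positive rate at each, and integrates kappa over FPR by the
trapezoid rule; constant scores give a degenerate two-point curve with
AUK 0. Both metrics are invariant under monotone transformations of the
scores. Under a 9:1 imbalance a no-signal model keeps AUC near 0.5 but AUK
near 0 on an absolute scale where informative models score well above it —
the chance correction makes AUK the more conservative summary.

## Synthetic corpora

The generator emulates the *shape* of a clinical-notes outcome-prediction
dataset: long documents from a handful of latent themes and a rare binary
outcome tied to theme proportions. Each of C = 5 topics owns a disjoint
block of the M = 500-word vocabulary (an overlap fraction can blend
supports) with Dirichlet(1) word probabilities; each document draws its
topic mixture from a symmetric Dirichlet with concentration 0.1 — sparse,
few-themes-per-document mixtures typical of topical text — and 200 tokens
by topic-then-word sampling. The desk-scale default is N = 500 documents;
`full_shape()` provides the study-scale 4,280 documents of 1,481 tokens.
Labels mark the top 10% of documents by topic-1 share (plus optional
Gaussian noise), giving the ~9:1 imbalance of rare clinical outcomes.

What passing on this generator shows: the fitters recover planted word
groupings; the metrics and evaluators compute what they claim; signal
carried by topic proportions survives the whole pipeline. What it does not
show: performance on real clinical language — synthetic tokens have no
burstiness, no Zipfian tail, no near-synonymy, no label noise beyond the
injected Gaussian, and topic supports far cleaner than real themes. The
interpretability-vs-performance relationship on real notes is an empirical
question the grid tooling can ask of real data; it is not asserted here.

## Experiment grid

`enumerate_grid` expands (algorithm × topic count × repetition) with one
derived seed per run (CRC-32 of base seed, algorithm, k, repetition —
stable, independent, below 2³¹); algorithms that select their own topic
count sit outside the k sweep. The reference layout — 16 gridded
algorithms over k = 5, 10, …, 100 with 10 repetitions, plus 10 runs of a
self-sizing algorithm — enumerates 3,210 runs. `run_grid` executes
whichever algorithms this package implements (the fuzzy family and the two
baselines), records coherence, diversity, interpretability, and
AUC/AUK under both embeddings per run, and logs failures as NaN rows
rather than aborting a sweep. Dirichlet-based neural topic models (LDA and
its descendants) are out of scope; their names are accepted in grid
configurations so layouts can be enumerated faithfully, and they surface
as recorded errors if run.

## Known limitations

- The Bayes recombination is one explicit reading of "Bayes' theorem plus
  linear algebra"; other factorizations exist and would change P(W|T)
  for strongly non-uniform document lengths.
- FLSA-V's SMACOF embedding is a stress minimizer, not a replica of any
  specific mapping tool; with 2 projection dimensions, crowded vocabularies
  can fold distinct topics together.
- c_v is computed with ε = 1e-12 and γ = 1 and negative-confirmation
  clipping; coherence values are comparable within this package, not
  across implementations with other conventions.
- Acceptance-scale runs use the desk-scale corpus (N = 500, L = 200,
  M = 500); the generator's full-shape configuration exists for larger
  studies.
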