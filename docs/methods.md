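# Methods

## Task and data model

The pipeline analyzes single-label text classification: each document is an
ordered token sequence carrying exactly one class label, and class-frequency
distributions are long-tailed, with "rare" defined as prevalence ≤ 0.02%
(2 documents in 10,000; the threshold is inclusive). Corpora are consumed
pre-tokenized (JSONL with `id`/`label`/`tokens`, or 3-column TSV); word
segmentation for languages that need it is upstream of this package.
Classes with a single document are rejected at split time with an explicit
error rather than silently dropped or merged — the caller decides.

## Representations

**bow** — raw per-occurrence token counts over the training vocabulary
(first-appearance order, frozen at fit time; unseen test tokens are dropped),
weighted by tf·idf with idf = ln((1+N)/(1+df)) + 1 and L2 row normalization.
This smoothed-idf, non-sublinear dialect is a widely reproduced default; it
is implemented via scikit-learn's `TfidfTransformer` and cross-checked
against the closed-form formula in the tests. Test rows always reuse the
training idf.

**bow_exp** — chi-square selection plus synonym expansion:

- χ² is computed one-vs-rest per (token, class) on *document-level presence*,
  not term frequency, and defined as 0 whenever a 2×2 margin is zero.
- Each token is associated with the class maximizing p(c|w) =
  (docs of c containing w) / (docs containing w); ties resolve to the class
  earlier in corpus order. Ranking within a class is by χ² descending, then
  token lexicographic, so selection is fully deterministic. Defaults k = 2,
  t = 0.9 are the tuned operating point of the analysis this package
  reproduces.
- Expansion is applied **per token occurrence**: a synonym occurring three
  times adds three counts to the matched feature. Self-matches count
  (cos(w,w) = 1 ≥ t), deliberately emphasizing selected features that are
  literally present. Expansion inspects *all* document tokens, including
  tokens outside the training vocabulary — that is the mechanism by which an
  unseen test-time synonym activates a selected feature. Tokens or features
  without embeddings are skipped (counted and logged, never an error), since
  real vocabularies always exceed embedding coverage.
- Document frequencies for the idf are computed *after* expansion, because
  expansion happens before the TF-IDF transformation.
- A numerical slack of 1e-12 is applied to the cosine threshold so that exact
  self-matches survive floating-point rounding even at t = 1.

**bow_exp_kg / cbow_kg** differ from their base variants only in the
embedding table supplied; no knowledge-graph code exists here — refined
vectors are consumed as an input table in word2vec text format.

**cbow** — the per-occurrence mean of the document's token embedding vectors.
A document with no embedded token is an error for the single-document
operation, but in batch transforms it maps to the zero vector (with a
warning) so that prediction over arbitrary test documents stays total.

## Classifier

All representations feed an L2-regularized linear SVM (scikit-learn
`LinearSVC`), C = 1 by default with the grid {0.001, 0.01, 0.1, 1, 10, 100}
available for tuning. The multi-class scheme is one-vs-rest with argmax over
decision values; labels are encoded as integers in corpus class order before
fitting so that ties resolve toward the earlier class deterministically.
Documents sharing no feature with the training data score as the all-zeros
vector and receive the argmax of the intercepts — a deterministic, valid
training label. The train/predict-over-corpus surface doubles as a plug-in
protocol so external sequence models can join the harness. Model persistence
is a single joblib bundle (representation state, weights, class order);
round-trip loading reproduces decision values exactly.

## Evaluation protocol

Per run: a stratified per-class split (train gets ⌈(1−f)·n_c⌉ documents,
both sides forced ≥ 1, so every class appears in training *and* test), then
one seeded shuffle per class from which nested subsets are taken at the
proportion grid (10%…100% by default; subset sizes ⌈p·n_c⌉, min 1). Nesting
makes curves monotone in expectation and runs comparable across proportions.
Each model is trained on a subset and scored by macro-F1 on the full test
side. Ten independent resplits are averaged by default.

Rare-class ("scope") curves restrict only the set of classes averaged in
macro-F1 — never the training data and never the predictions. Classes in the
scope but absent from a test fold cannot occur, because the split guarantees
per-class presence.

Seeding: all randomness descends from one master seed through
`numpy.random.SeedSequence` spawn keys — per run, per purpose (split /
subsample / model), and per class index within a split — so adding a class or
a method perturbs nothing else, and two methods evaluated under the same plan
see byte-identical partitions (asserted via split fingerprints). This paired
design is what licenses the paired significance test.

**ALC** is the uniform mean of macro-F1 over the proportion grid, averaged
over runs — the normalized rectangle rule on an equally spaced grid. A
trapezoid alternative is available behind the `rule` argument; on an equally
spaced grid the two differ only in the half-weighting of the endpoints.

**Significance**: one-sided paired sign-flip randomization test of
mean(a − b) > 0 on per-run ALC (or any per-run paired statistic). For n ≤ 20
pairs the 2^n sign assignments are enumerated exactly
(p = #{null ≥ observed}/2^n, with a 1e-12 tolerance on the comparison so
all-zero differences give p = 1); beyond that, sampled sign vectors with the
add-one estimator p = (#{null ≥ observed}+1)/(n_perm+1).

## Synthetic data generator

The generator emulates the statistical structure the analysis depends on:

- **Class frequencies**: expected shares ∝ rank^(−zipf_exponent), realized
  multinomially with every class forced to ≥ 2 documents (so it can be
  split). The long-tail fixture (10,000 documents, 150 classes, exponent 2)
  leaves tail classes at exactly their forced 2 documents — prevalence
  0.0002, the rare regime. At exponent 1 a 10,000-document corpus's tail is
  not that rare; the steeper fixture exponent is the deliberate default for
  rare-class studies.
- **Documents**: length ~ max(1, Poisson(27)) — the few-dozen-token scale of
  patient descriptions; each token is, with probability π = 0.35, a uniform
  draw from one of the class's signature synonym clusters (3 clusters/class,
  3 variants/cluster by default), else a Zipf(1)-distributed background token
  (400 types by default).
- **Embeddings**: each synonym cluster receives a random unit centroid;
  members sit within half the cluster's angular budget of it, guaranteeing
  intra-cluster pairwise cosine ≥ 0.95 (> t = 0.9, so expansion fires).
  Centroids and background vectors are rejection-resampled until all
  off-cluster cosines stay below 0.8 (< t, so expansion never fires across
  clusters); an embedding dimension too small to separate the vocabulary
  fails after bounded retries rather than silently degrading.
- **Synonym-split scenario**: training documents emit only variant 0 of each
  signature cluster, test documents only the remaining variants. Surface
  bag-of-words then has zero lexical overlap on class-indicative tokens
  between train and test, isolating the expansion mechanism.

What the generator does *not* model: real morphology or clinical language,
polysemy (clusters are cleanly separated, real embedding neighborhoods are
not), annotator noise, document length/label correlations, and
embedding-coverage gaps. Passing tests therefore demonstrate that the
machinery is correct and that the expansion mechanism works where its
assumptions hold — not that it attains any particular score on real corpora.

## Problem sizes

The default fixture corpus is 600 documents over 12 classes (256-dimensional
embeddings); the mechanism analysis averages 10 generator seeds at the 10%
training proportion; the rare-class analysis uses the 10,000-document
long-tail fixture with 2 resplits over a 3-point proportion grid. These sizes
give stable signs and tight dispersion for every quantity reported while
keeping a full run in seconds on one CPU; the acceptance script's curve study
uses 5 resplits over the full 10-point grid.

## Known limitations

- The exact ALC normalization in the literature varies (active-learning
  variants use log-scaled budgets); the uniform mean here is the simplest
  defensible choice and is stated wherever reported.
- χ² selection assumes document-level presence is the informative unit;
  corpora with heavy within-document repetition may prefer frequency-based
  selection metrics (not implemented: information gain, bi-normal
  separation).
- `LinearSVC` decision values are not calibrated probabilities; only argmax
  predictions are consumed.
- The randomization test is one-sided by construction; two-sided use requires
  calling it twice or negating the pairing.
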