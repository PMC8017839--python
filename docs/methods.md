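# Methods

## Problem and model

The package treats lncRNA–disease association prediction as supervised link
prediction on a bipartite network. The observed network is a binary matrix
`A` with `A[l, d] = 1` when lncRNA `l` is known to be involved in disease
`d`. Known associations are positives; the zero cells are a mixture of true
negatives and undiscovered associations, and the goal is to rank them.

The working assumption is *guilt by association*: diseases with similar
ontology placement or similar interaction profiles involve similar lncRNAs.
All information available to the classifier is therefore channelled through
two similarity matrices, one over diseases and one over lncRNAs.

### Disease semantic similarity

Two models operate on the disease ontology DAG (a `child → parent` edge
list; any DAG with these semantics works, e.g. a MeSH-derived hierarchy).

**Decay model.** `DAG(D)` is disease `D` plus all its ancestors. `D`
contributes 1 to itself; a term `i` above it contributes
`C_D(i) = max{ Δ·C_D(i′) }` over its children `i′` inside `DAG(D)`. Children
outside the closure carry nothing. With uniform `Δ` this equals
`Δ^(shortest hop distance from D to i)`; the test suite checks the recursion
against an exhaustive-path oracle. The semantic value is
`G(D) = Σ_{i∈DAG(D)} C_D(i)` and similarity is the ratio of shared
contribution mass to total mass, so `sim(D, D) = 1` identically and two
siblings under a common parent score `Δ/(1+Δ)`.

- `Δ` (attenuation per generation, dimensionless in [0, 1], default 0.5):
  the customary value in this model family; smaller values concentrate
  similarity on near ancestors.

**Information-content model.** The variant replaces `C_D(i)` with
`IC(t) = −log(n_t/N)`, where `n_t` counts corpus diseases whose closure
contains `t`, combined by the same ratio form. A term carried by every
disease (e.g. the root) has zero information. This corpus-frequency
concretisation is our design choice: only the existence of a second model is
fixed by the method family, not its formula, so it is flagged prominently
here. The diagonal is pinned to 1, covering the degenerate corpus in which a
disease's entire closure is shared by all diseases (zero total information).

By default the two models are averaged element-wise; `model1_only` /
`model2_only` are available where one model is preferred.

### Gaussian interaction profile kernels

A disease's interaction profile is its column of `A`, a lncRNA's its row.
The kernel `K(x,y) = exp(−k‖x−y‖²)` uses the bandwidth
`k = count / Σ‖profile‖²`, i.e. the inverse mean squared profile norm along
that axis, so the scale adapts to network density. An all-zero matrix has no
defined bandwidth and is rejected; callers must filter empty profiles. The
exponent's bandwidth is taken positive — a negative width would make the
kernel explode with distance and contradicts the normalisation.

Integration: disease similarity is the mean of semantic and GIP values where
both diseases have semantic scores, GIP alone otherwise (graceful
degradation when the ontology misses diseases); lncRNA similarity is GIP
alone unless a user-supplied functional similarity matrix is given, in which
case the mean is used. Means of matrices with unit diagonal and entries in
[0, 1] stay in [0, 1].

### Pair features and negative sampling

Every known association is a positive sample; `⌈neg_ratio × positives⌉`
negatives are drawn uniformly without replacement from the zero cells
(default `neg_ratio = 1`, the usual balance for this protocol). The feature
vector of `(l, d)` concatenates the lncRNA similarity row of `l` and the
disease similarity row of `d` (width `n_lnc + n_dis`) — the minimal
construction that exposes both similarity spaces to the classifier.

Known caveat: similarity matrices are computed once from the full `A`.
Held-out fold labels therefore leak weakly into the features through the GIP
profiles (transductive bias common to this method family); the
masking-recovery experiment, which recomputes all similarities from the
masked matrix, is the leakage-free check.

### Dimensionality reduction

A one-shot compression of the feature covariance: centre the samples
(columns = features), form the covariance `C` with `1/(rows−1)`
normalisation, keep the `k` columns of `C` with largest ℓ₂ norm (ties to the
smaller index), orthonormalise them by QR into `Q`, SVD the compressed
covariance `C1 = QᵀCQ`, and project with `basis = Q·U[:, :n_components]`.
High-norm covariance columns belong to the features most correlated with
the rest, so their span approximates the dominant eigenspace; at `k = p`
the procedure reproduces exact PCA (principal angles < 1e−8 in the tests).
Despite the "incremental" name sometimes attached to this family, the
decomposition is one-shot; no minibatch updates.

Numerical choices: defaults `n_components = min(64, p)`,
`k = min(2·n_components, p)`; each basis column's largest-magnitude entry is
made positive so results are bit-reproducible; if the compressed covariance
has lower rank than requested the trailing components carry zero variance
and a warning is logged; constant input yields zero projections.

### Classifier and evaluation

A random forest (scikit-learn back-end) on the reduced features; the
probability of the positive class is the ranking score. Defaults:
`n_estimators = 1500` (the grid-search optimum at full scale; tests and the
desk-scale benchmark use 100 for speed), all other tree options at library
defaults, overridable via a passthrough map. One integer seed controls
sampling and tree construction; bit-level identity across library versions
is not promised, only statistical agreement.

Evaluation uses stratified 10-fold cross-validation at pair level (the
common reading; folds over lncRNAs would test cold-start generalisation
instead). Per fold, the centring mean, the reduction basis and the forest
are fitted on the training split only — instrumented tests assert that no
test row reaches a fit call. Metrics from the confusion counts: accuracy,
precision, recall, FPR; F1 defaults to the harmonic mean of precision and
recall, with `variant="printed"` using accuracy in place of precision for
comparability with an alternative definition seen in the applied
literature. Undefined ratios (e.g. precision with no positive predictions)
return NaN and are skipped with a warning in fold aggregates, rather than
aborting a whole cross-validation. ROC curves enumerate all distinct score
thresholds; AUC is the trapezoid area and equals Mann–Whitney concordance
(asserted against a brute-force oracle).

Grid search over `n_estimators ∈ {100, 500, 1000, 1500, 2000, 2500}` by
inner k-fold mean AUC (5 inner folds by default); ties go to the smallest
forest for speed.

Candidate ranking for a disease scores every lncRNA with `A[l, d] = 0`,
sorts descending, ties broken lexicographically for determinism.

## Synthetic benchmark

The generator emulates the pipeline's two inputs with a planted-block
model. Defaults: 80 lncRNAs × 40 diseases in 4 blocks, within-block
association probability (signal) 0.6, background (noise) 0.05, a 60-term
rooted DAG of depth ≤ 4 in which block-mate diseases hang under the same
depth-1 branch, seed 42. Block structure is exactly the "similar diseases,
similar lncRNAs" premise, so the blocks are a tunable ground truth:
cross-validated AUC rises with the signal − noise gap and collapses to ~0.5
under label permutation.

What it does not emulate: the heavy-tailed degree distribution of curated
association databases, correlated annotation noise, and ontology depth
heterogeneity. Passing the benchmark shows the machinery recovers planted
block signal end-to-end; it does not certify performance on any real
database.

A consequence of the stated background rate worth knowing: at noise 0.05
roughly a fifth of generated positives fall outside every block. These
pairs carry no recoverable structure — they bound the achievable
cross-validated AUC on the benchmark near 0.89 and likewise cap how often a
masked association can be re-ranked into the top of its candidate list.
The masking-recovery experiment therefore tests the directional property
(hidden positives outscore random unassociated pairs; one-sided Wilcoxon
across 25 seeded repetitions), which is robust to that unlearnable
fraction.

## Running on real data

1. Export the association list as TSV with columns
   `LncRNA name, Disease name[, Dysfunction type]` (the dysfunction column
   is read and preserved but unused). Names are trimmed, internal whitespace
   collapsed and lower-cased by default (`lowercase=False` to disable);
   matching across sources is the user's responsibility.
2. Provide the disease ontology as a `child<TAB>parent` edge list (an OBO
   import is a documented extension point, deliberately not a dependency),
   plus a `disease<TAB>term` mapping when database disease names differ from
   ontology term ids.
3. Optionally provide a precomputed disease similarity matrix (e.g. a
   text-mining derived one such as MimMiner's) as labelled TSV via
   `disease_similarity`; it then replaces the ontology route, and diseases
   missing from it fall back to GIP similarity. A lncRNA functional
   similarity matrix can be supplied the same way.
4. Run `ipcarf run --config run.yaml` with `folds: 10`,
   `grid: [100, 500, 1000, 1500, 2000, 2500]` to reproduce the full
   protocol, then `rank_diseases` for the diseases of interest.

## Known limitations

- Negative sampling treats zero cells as negatives; undiscovered true
  associations contaminate the negative class (inherent to the protocol).
- The transductive GIP bias above makes cross-validated metrics optimistic
  relative to truly prospective prediction.
- Semantic model 2 is a corpus-frequency interpretation (see above).
- Similarity matrices are dense; the implementation targets
  database-download scale (thousands of entities), not genome-scale inputs.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the benchmark at its default
scale (≈1200 sampled pairs, 120 features), the grid search on a 30×20
instance with 3 inner folds, and masking recovery over 25 seeded
repetitions — sizes chosen so the whole verification runs comfortably on a
single CPU while keeping every statistical check well-powered.
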