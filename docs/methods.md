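# Methods notes

## Scope and data model

The package implements a diagnostic-marker pipeline for a two-class
(normal vs disease) bulk-transcriptomic design measured in two cohorts on a
shared platform, with an independent validation cohort. The carrier is a
genes × samples matrix of log2 intensities with a sample sheet
(sample id, group, batch). All stages operate on gene-symbol-keyed
matrices; probe-level annotation is out of scope, as are enrichment,
immune-deconvolution and drug-signature analyses.

## Preprocessing

Duplicate gene symbols are collapsed by the element-wise mean (median
available). A matrix whose maximum exceeds 50 is treated as raw-scale and
log2(x+1)-transformed: log2 microarray data rarely exceeds ~20, so the
threshold cleanly separates the two scales; the decision is logged and the
caller can transform explicitly instead. Cohorts merge on the intersection
of gene symbols in first-cohort order; values are never altered by the
merge.

Batch correction defaults to per-gene mean-centering (each batch shifted to
the grand mean). This removes exactly the additive per-gene batch offset
that the merged-cohort design introduces, is idempotent, and preserves
per-gene grand means to machine precision. An `eb_shrink` mode additionally
rescales each batch's residual spread toward the pooled spread with
location/scale factors shrunk halfway toward their across-gene averages — a
parametric empirical-Bayes-style adjustment for users who want a closer
analogue of full location/scale batch correction. Zero-variance genes
receive location correction only. No downstream quantity in this package
depends on the difference between the two modes.

## Moderated t

Per gene, the pooled two-sample variance s²_g on d = n₁+n₂−2 degrees of
freedom is shrunk toward a prior: s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d). The
prior is fit by method of moments on z = log s²_g: Var(z) in excess of
trigamma(d/2) determines d₀ through the inverse trigamma (Newton
iteration), and the adjusted mean of z determines s₀². When the observed
spread is at or below the sampling floor, d₀ → ∞ and every gene uses s₀²
(t is then referred to the normal distribution). d₀ = 0 recovers the
ordinary pooled t exactly, which the tests exploit as an oracle. A Welch
mode is provided for tiny gene sets (< 10 genes) where the prior fit is
unstable.

Selection is deliberately strict and uncorrected by default — p < 0.05 and
|log2FC| > 0.585, both strict inequalities — matching the convention of the
study design this mirrors; Benjamini–Hochberg adjustment is available
through `correction="bh"`.

## Marker selection

*Random forest.* 500 trees; mtry tuned over {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋} (≥ 1,
capped at p) by out-of-bag error, ties to the smaller value. Importance is
the mean decrease in Gini impurity on the count-weighted scale (impurity
decreases weighted by absolute node sample counts, averaged over trees).
scikit-learn's `feature_importances_` normalizes to sum 1, which would make
a fixed threshold meaningless, so importances are rebuilt from the fitted
tree structures. The selection threshold (> 2, strict) is only meaningful
on this unnormalized scale. Genes are sorted lexicographically before
fitting so importances do not depend on input order.

*SVM-RFE.* Features standardized; linear SVM with C = 1; one feature
eliminated per iteration by smallest squared weight, giving a full ranking.
The selected set is the ranking prefix minimizing stratified 5-fold
cross-validated error. Among tied prefix sizes the **largest** is kept:
with a handful of strong, partially redundant markers the error minimum is
reached already at one or two genes, and a smallest-tie rule would prune
true markers that carry signal; keeping every feature that does not hurt
generalization matches the generous marker sets recursive elimination is
typically used to produce, and makes the panel the RF∩SVM intersection is
built from stable. Determinism across gene orderings comes from the
lexicographic pre-sort.

The marker panel is the order-stable intersection (RF order); an empty
intersection is a logged warning for the selectors and an error for the
full pipeline.

## Gene score and network

Each marker is binarized against its median across **all** samples of the
cohort being scored (groups pooled): up markers score 1 strictly above the
median, down markers score 1 at or below it, so 1 always encodes
"disease-like". Ties therefore go to 0 for up markers and 1 for down
markers. Validation cohorts are re-binarized against their own medians.

The classifier is markers → H=5 hidden (ReLU) → 2 output (softmax), fit by
summed cross-entropy. Optimization is Rprop+ with the algorithm's canonical
constants (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δmin = 1e−6, Δmax = 50) and weight
backtracking: a parameter whose partial derivative changes sign has its
last step reverted, its step size halved, and its stored gradient zeroed so
the following update is neutral. Initial weights are uniform(−0.5, 0.5)
from the seed; training stops when the largest absolute partial derivative
falls below 0.01 (or at 100 000 steps). Given a seed, training is
bit-reproducible.

On the shipped 35-sample worked-example score table, nine samples share the
all-zero pattern (8 normal, 1 disease), so no deterministic function of the
scores can exceed 34/35 training accuracy; a converged cross-entropy fit
assigns that pattern the majority (normal) label and a disease probability
near its empirical frequency 1/9. Every tested seed reaches exactly 34/35.
The training AUC depends on how the remaining unique normal patterns are
ordered relative to the shared pattern: at the global pattern-frequency
optimum the AUC is 296/300 = 0.987, which about half of random
initializations reach exactly, the rest stopping at nearby local optima
within about 0.01–0.03 of it. Tightening the gradient threshold does not
change this — the spread reflects genuine local optima of the nonconvex
fit, not under-convergence — hence the worked-example retraining is
summarized by the majority 3-decimal value over 10 seeds.

Gene weights are the per-marker maxima over the five input→hidden weights
only — hidden biases and the output layer are excluded. They feed the
per-sample linear score Σ score × weight, reported alongside the softmax
output-node values; the two live on different scales (the linear score is
unbounded, the output nodes sum to 1) and both are preserved in the
diagnostic output.

## Evaluation

AUC uses the Mann–Whitney midrank form, identical to pair counting with
half credit for ties (the brute-force pair count is kept as a test oracle).
Youden's J is maximized over midpoints of adjacent distinct scores with a
"score > threshold ⇒ disease" rule; tied J resolves to the lower threshold.
Confidence intervals are stratified percentile bootstrap (2000 replicates
by default; smaller inside the pipeline summary where the CI is
informational), resampling within class so no replicate loses a class. The
bootstrap method is a package choice — reported CIs are method-dependent
and not comparable across implementations. Per-marker AUCs are computed on
raw expression without sign-flipping down markers; an `oriented_up` flag
marks markers discriminating in the expected direction.

## Synthetic cohorts

The generator plants known up/down markers in a Gaussian log2-intensity
model: per-gene baselines ~ N(8, 1.5²), disease shift ±δ on planted
markers, residual noise N(0, σ²), and a per-gene N(0, τ²) offset added to
the second training batch. Defaults: 2000 genes, 48 up + 27 down planted
markers, δ = 1.0, σ = 0.5, τ = 0.5, batches 10+10 and 5+10, validation 8+9
— the sample layout and differential-expression scale of the study design
it emulates (a 21 654-gene matrix is a flag away but unnecessary for
correctness testing). The tests use δ = 1.5 with five planted markers for
end-to-end recovery runs, and reduced gene counts (200–1000) where only
per-gene behaviour is probed.

What the generator does **not** emulate: probe-level effects, correlated
gene modules, heavy-tailed intensity noise, intensity-dependent variance,
or class imbalance beyond the fixed design. Passing end-to-end tests
therefore demonstrate internal correctness and recoverability under an
idealized additive Gaussian design, not performance on real microarray
data.

## Problem sizes and determinism

The default test and analysis runs use 1000–2000 genes, 35 training and 17
validation samples, 20-replicate property checks, and 50–500 bootstrap
replicates — sizes chosen so a full desk run of suite plus analysis chain
completes in a few minutes while keeping Monte-Carlo margins comfortable.
All randomness flows through explicit integer seeds (NumPy `default_rng`;
scikit-learn `random_state`); identical seeds give byte-identical
artifacts.

## Known limitations

- The mean-center batch mode assumes additive per-gene batch effects; scale
  differences between batches survive it (use `eb_shrink`).
- The moderated-t prior assumes a single variance prior shared across all
  genes; strongly bimodal variance structure would be shrunk toward one
  pool.
- SVM-RFE retrains one SVM per elimination step and one CV sweep per prefix
  size: fine for DEG-sized inputs (tens to hundreds of genes), quadratic
  and slow if applied to whole transcriptomes.
- The network is intentionally tiny and unregularized; it is a scoring
  device over 5 binary inputs, not a general classifier.
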