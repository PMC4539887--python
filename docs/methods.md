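# Methods

This note documents the models, estimators and numerical choices behind the
package, in the order the pipeline runs them, plus what the synthetic
benchmark does and does not emulate.

## Data model

A dataset is a list of views — real matrices with features in rows and
patients in columns — sharing one patient axis, plus an optional class
label per patient.  Loading accepts TSV (default) or CSV (autodetected from
the header line), decimal points only.  Missing cells are rejected by
default; per-feature median imputation can be enabled.  When views cover
different patient sets, `align_dataset` restricts everything to the
intersection and orders patients lexicographically — a deterministic
canonical order so identical inputs give identical runs on any platform.
Aligning is idempotent.

## Stage 1 — prototype extraction

**Variance filter.** The `⌈keep_fraction·F⌉` features with largest sample
variance (ddof=1) are kept, original order preserved; ties at the boundary
go to the lower feature index.  Default `keep_fraction = 0.5`.

**Feature clustering geometry.** Features are clustered using patients as
coordinates in `1 − r` Pearson distance.  Ward uses that distance matrix
directly; k-means runs on row-standardized features (squared Euclidean on
z-scored rows is proportional to correlation distance, so the geometry is
consistent); PAM is a hand-rolled deterministic k-medoids (greedy BUILD
initialization, then alternating assignment / within-cluster medoid
updates, ties to the lowest index); spectral clustering uses the
`(1+r)/2` affinity.  All backends take an explicit seed; k-means uses 10
restarts.

**VAL index.**  A clustering with K clusters of N features scores

```
VAL = ¼ ( (IC+1)/2 + 1 − (EC+1)/2 + (1 − S) + CG )
```

* `IC` — mean over clusters of size ≥ 2 of the *minimum* pairwise
  correlation within the cluster ("complete diameter" in similarity space).
  Singletons are excluded from the average; if every cluster is a
  singleton, IC is set to 0 with a warning.
* `EC` — mean over cluster pairs of the minimum cross-cluster correlation
  ("complete linkage").
* `S = #singletons / (K−1)`.  S can exceed 1 when singletons outnumber
  K−1; VAL is then allowed below 0 rather than clamped, so the identity
  above holds exactly for every emitted score (it is asserted in tests to
  1e−12).
* `CG = 1 − K/N`.

"Least similar" is read as the minimum pairwise correlation; with the
`(IC+1)/2` rescaling this keeps every term in [0, 1] for S ≤ 1.  The
definition is isolated in `val_components` so an alternative similarity
currency can be swapped in one place.

**k tuning.**  For every (algorithm, k) on a grid (default: 10 log-spaced
values in `[2, min(F/2, 100)]`) VAL is computed; the per-k score is the
mean VAL across algorithms, the best k is its argmax with ties to the
smaller k (favoring compression), and the two algorithms with the highest
VAL at that k are the candidates; failed cells are logged and excluded
from the mean.

**Prototype selection.**  Per cluster, the member maximizing the mean
correlation to the other members; ties to the lexicographically smallest
feature id; singletons represent themselves.

## Stage 2 — feature ranking

**CAT-scores.**  Per one-vs-rest contrast, a pooled-variance t-statistic is
computed with the residual variance shrunk toward the median variance
(analytic intensity from the variance of the per-feature variance
estimates).  The vector of t-scores is decorrelated by `R^{−1/2}`, where
`R` is the Schäfer–Strimmer shrinkage correlation of the within-class
residuals (off-diagonals shrunk toward 0 with
`λ* = Σ V̂ar(r_ij) / Σ r_ij²`, clipped to [0, 1]); the inverse square root
comes from an eigendecomposition with eigenvalues floored at 1e−10.
Shrinkage matters because the number of prototypes can approach or exceed
the number of patients.  A feature's score is the sum of its squared
CAT-scores over contrasts; with an identity correlation this reduces
exactly to ordinary t-scores.  Ties in the final ordering break
lexicographically.

**Random-forest importance.**  A forest (default 300 trees in the pipeline,
1000 standalone) is fit on a stratified 70 % split and permutation
importance (mean decrease in accuracy, 10 repeats) is measured on the
held-out 30 %; negative importances are floored at 0.  Held-out rather than
in-bag measurement keeps null features at zero importance.  Fully seeded.

**Cumulative cuts.**  The shortest ranking prefix reaching 60/70/80/90 % of
the total score mass (a 1e−12 slack guards float round-off).  Selections at
increasing fractions are nested by construction.  A ranker whose scores are
all zero is dropped for that view.

## Stage 3 — per-view patient clustering

Patients are clustered on the selected prototypes (z-scored, Euclidean
geometry) with the same four backends, with K equal to the number of known
classes by default (overridable).  Each candidate in the grid
(algorithm × ranking method × cut) is scored by **impurity** — the fraction
of patients whose class differs from their cluster's majority class, the
single shared error notion across the package — and the argmin is kept.
Error ties follow the precedence kmeans > pam > ward > spectral, then
CAT before RF, then the smaller cut.  Without labels the fallback score is
the negative silhouette in `1 − r` distance.  Views with fewer than 10
prototypes skip ranking and cluster on all features.

## Stage 4 — late integration

**MF.**  The transposed memberships are stacked into `X` (l × n, column
sums = number of views).  For each k in the range, `X ≈ PH` is fit by
multiplicative updates minimizing `‖X − PH‖²_F` (denominator guard 1e−12),
10 seeded restarts, keeping the best objective; updates stop when the
per-iteration improvement falls below `1e−9·max(obj₀, 1)` or at 500
iterations (then the best iterate is returned with `converged=False`).
The Frobenius objective is recorded every iteration and is non-increasing —
asserted in tests.  Across k, the factorization with the sharpest patient
memberships wins: sharpness is the mean over patients of the largest
column-normalized entry of H (a crisp partition scores 1); ties go to the
smaller k.  This model-selection rule uses only the factor values, is
reproducible, and needs no external information.  Patients are assigned by
column argmax of H; empty meta-clusters are dropped and `k_effective`
reported.

**GLI.**  With `M = Xᵀ` (n × l), minimize `GI(M‖BP) = Σ (M log(M/Y) − M +
Y)`, `Y = BP`, over `B ≥ 0` with unit row sums and `P ≥ 0`.  The printed
divergence uses the standard generalized KL form; `0·log 0 = 0` and an
ε = 1e−12 floor appears inside logs and denominators only, never in the
data.  Standard KL multiplicative updates alternate with a row
normalization of B; because the normalization can locally raise the
objective, the best iterate seen is kept and its best-so-far trajectory
(non-increasing by construction) is reported.  Convergence is declared
after 5 consecutive iterations without material improvement.

**Contribution matrix.**  Each row of P (one single-view cluster) is
normalized to a distribution over meta-clusters — its *dedication*.  View
h's raw contribution to meta-cluster f is the dedication of its
best-aligned cluster, `max_r P_norm[r, f]`; columns are then normalized to
sum to 1.  A meta-cluster that only one view's clustering isolates is
attributed (close to) 100 % to that view, while a view whose clusters
merely scatter across the meta-cluster contributes little.  Summing a
view's dedications instead of taking the maximum turns out to be
uninformative: when a view has about as many clusters as there are
meta-clusters, its total dedication mass is ≈ 1 regardless of alignment,
pinning every contribution at 1/#views.  Before computing T the MF factors
are gauge-fixed by scaling each H row to peak at 1 (indicator
factorizations are untouched and `X = PH` is preserved); GLI's gauge is
already fixed by B's row-stochasticity.

**Semi-supervised mode** appends the exact class-indicator membership as
one extra view (weight 1 by default, configurable multiplier) before
stacking.  The prior anchors meta-clusters to the known classes, which on
the synthetic benchmark cuts meta-cluster impurity by an order of
magnitude (recomputed by `scripts/acceptance.py`, not quoted from
anywhere).

## Subclass calling

Per non-empty meta-cluster: the majority class (ties to the
lexicographically smallest label, logged), and a one-sided Fisher's exact
test on the 2×2 table {in cluster / out} × {majority class / other} via the
hypergeometric survival function — one-sided because the question is
over-representation of the majority class.  Raw p-values are primary; a
Benjamini–Hochberg column is provided but not used for filtering.

## Validation

* **NMI** between partitions: mutual information normalized by the
  geometric mean of the entropies (selectable: sqrt / max / mean).
* **Leave-one-out stability**: stages 2–4 are rerun once per left-out
  patient with the stage-1 prototypes held fixed (prototype stability is a
  separate question from the joint stability of the downstream stages);
  entry (i, j) of the N×N matrix is the NMI of runs i and j on their N−2
  shared patients; the stability index is the mean of the full matrix
  (diagonal included).  Failing runs are excluded and logged.
* **Borda count**: a feature at position p of a length-L list earns L − p
  points, absent features earn 0; ties break lexicographically.

## Synthetic benchmark

The generator plants a two-level grouping (classes split into subclasses;
sizes as even as possible, exactly reproducible from the seed) and builds
each view from Gaussian noise plus correlated feature blocks constructed
with a shared latent factor, `x = √ρ·z + √(1−ρ)·ε`, giving exact population
within-block correlation ρ.  A block *informative* for a subclass is
mean-shifted by `effect_size` in that subclass's patients, and each view
can be restricted to drive a chosen subset of subclasses — so the
contribution matrix has a known target.  Default conditions: 200 patients,
2 classes × 2 subclasses, two views of 100 features with four 10-feature
blocks (ρ = 0.5, effect 2.0, noise sd 1.0).  The benchmark experiments in
the tests and the acceptance script use 60–200 patients and effects
1.5–3.0, chosen so that single-view clustering is good but imperfect —
integration then has something to add.

What the generator does **not** emulate: count-valued RNA-seq marginals,
heavy tails, batch effects, missingness, or feature-feature structure
beyond single-factor blocks.  Passing tests therefore demonstrate the
correctness and internal consistency of the machinery under a controlled
Gaussian regime, not performance on any real cohort.

## Known limitations and open choices

* The per-view K defaults to the class count; finer per-view structure is
  only surfaced by the integration step (or by overriding K).
* MF model selection by membership sharpness is one defensible rule among
  several; it is deliberately minimal and depends only on the factors.
* GLI's monotonicity is guaranteed only for the best-so-far trajectory
  because of the row-normalization interleaved with the KL updates.
* PAM is a deterministic greedy variant, not the full original SWAP search;
  on the problem sizes here the difference has not been observable.
* SOM and Pvclust feature-clustering backends are not provided; the
  backend set is fixed to ward/kmeans/pam/spectral behind one dispatch
  function where additional backends could be registered.
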