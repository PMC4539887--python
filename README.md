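# mvda — multi-view late-integration clustering for patient subtyping

`mvda` discovers patient subtypes from several omics layers (*views*: mRNA,
miRNA, protein, CNV, ...) measured on the same patients.  Instead of
concatenating heterogeneous matrices, it clusters each view separately and
integrates only the **clustering results** — a *late integration* strategy
that lets each data type keep its own best-suited algorithm, and that can
quantify how much each view contributed to every discovered subgroup.

It is aimed at computational biologists analysing multi-omics cohorts
(e.g. TCGA-style breast, ovarian or glioblastoma panels) who want
statistically supported subclasses *within* known clinical classes.

## The method

Given view matrices `M_i ∈ R^{F_i×P}` and a class label per patient, four
stages run per dataset:

1. **Prototype extraction.**  Low-variance features are dropped, the rest
   are clustered in `1 − r` (Pearson) distance with ward / k-means / PAM /
   spectral backends, and each cluster is represented by its *prototype* —
   the member most correlated with the others.  Candidate clusterings are
   scored by the validity index

   `VAL = ¼ · ( (IC+1)/2 + 1 − (EC+1)/2 + (1 − S) + CG )`

   with IC the complete diameter (mean minimum within-cluster correlation),
   EC the complete linkage (mean minimum cross-cluster correlation),
   `S = #singletons/(K−1)` and compression gain `CG = 1 − K/N`.  The K with
   the best mean VAL across algorithms wins.

2. **Feature ranking.**  Prototypes are ranked by class separability with
   correlation-adjusted t-scores (CAT, `R^{-1/2} t` with shrinkage
   estimates) and random-forest permutation importance; nested selections
   keep 60/70/80/90 % of the cumulative score mass.

3. **Per-view patient clustering.**  Patients are clustered on the selected
   prototypes with K = number of classes; the (algorithm × ranker × cut)
   combination minimizing confusion-matrix impurity is kept per view.

4. **Late integration.**  The per-view membership matrices are stacked into
   `X` (clusters × patients) and combined either by non-negative matrix
   factorization `X ≈ PH` (Frobenius multiplicative updates, model selection
   over k) or by the consensus model `min GI(M‖BP)` under the generalized
   Kullback–Leibler divergence with row-stochastic `B`.  The projection `P`
   yields the view × meta-cluster **contribution matrix T** (columns sum
   to 1).  Semi-supervised mode adds the class-indicator matrix as one extra
   prior view.

Each meta-cluster is labeled with its majority class and tested for
enrichment with a one-sided Fisher's exact test; robustness is measured by
leave-one-out stability (mean pairwise NMI over reruns) and feature lists
are aggregated across reruns by Borda count.

## Worked example

```sh
python examples/01_full_pipeline.py
```

runs the whole pipeline on a generated two-view cohort (120 patients,
2 classes × 2 planted subclasses) and prints:

```
meta-clusters found: 4 (MF)
impurity vs classes: 0.083
NMI vs planted subclasses: 0.636

 cluster  size majority_class  majority_count      p_value     p_adj_bh  contrib_view1  contrib_view2
       0    31             C2              27 9.470867e-07 9.470867e-07       0.504451       0.495549
       1    33             C2              30 1.164405e-08 2.328809e-08       0.510154       0.489846
       2    28             C1              27 3.052233e-09 1.220893e-08       0.494489       0.505511
       3    28             C1              26 7.317781e-08 9.757042e-08       0.495270       0.504730
```

Four meta-clusters emerge, two nested in each known class; every one is
significantly enriched for a single class (Fisher p ≪ 0.01), and the
contribution columns show both views mattered roughly equally — by design
in this simulation.  `examples/03_integration_and_contributions.py` shows
the asymmetric case where one subclass is attributable ~75 % to a single
view, and `examples/02_prototype_extraction.py` and
`examples/04_stability_and_borda.py` demonstrate the VAL-based dimension
reduction and the stability/Borda machinery.

The same pipeline is scriptable from a shell:

```sh
mvda synth --out data --seed 3
mvda run --config cfg.yaml        # views, labels, params in YAML
```

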