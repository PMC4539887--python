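"""Full multi-view subtyping run on a synthetic two-omics dataset.

Generates 120 patients with 2 known classes each hiding 2 subclasses,
measured in two views, then runs all four stages and prints the subclass
report: each meta-cluster's majority class, its Fisher enrichment p-value,
and how much each view contributed to defining it.
"""

import mvda

spec = mvda.SyntheticSpec(
    n_patients=120,
    n_classes=2,
    subclasses_per_class=(2, 2),
    views=tuple(
        mvda.SyntheticViewSpec(
            n_features=60, n_informative_blocks=4, block_size=10,
            within_block_correlation=0.3, effect_size=2.0,
        )
        for _ in range(2)
    ),
    seed=7,
)
dataset, truth = mvda.generate(spec)

config = mvda.MVDAConfig(seed=0, rf_trees=100, patient_k=4, meta_k_range=(4,))
result = mvda.run_pipeline(dataset, config)

print(f"meta-clusters found: {result.meta.k_effective} ({result.meta.method})")
print(f"impurity vs classes: {result.metrics['impurity']:.3f}")
print(f"NMI vs planted subclasses: "
      f"{mvda.nmi(result.meta.partition, truth.subclass_codes):.3f}")
print()
print(result.report.to_string(index=False))
# Low impurity means meta-clusters respect the known classes; a small
# p_value marks a meta-cluster significantly enriched for one class — a
# candidate subclass — and the contrib_* columns say which omics layer
# defined it.
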