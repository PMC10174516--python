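# Headline run preset: 100 repetitions, 50-epoch optimizer budget, pop size 30,
# positions searched in [-1, 1].  lsa_epoch is an opaque passthrough.
runs: 100
seed_base: 0
domain_range: [-1, 1]
epochs: 50
pop_sizes: [30]
models: [knn, rf, c45, ann, svm, rf_svm]
with_hgso: [true, false]
optimizer_strategy: hgso
lambda_weight: 0.99
fitness_classifier: knn
split_fraction: 0.8
lsa_epoch: 100
data_source:
  generator:
    class_counts: [800, 700, 850, 650]
    n_informative: 12
    n_noise: 25
    effect_size: 2.0
    seed: 0
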