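# Default two-view semi-supervised benchmark: the dataset and training
# settings used by the regime comparison (feature / fusion / co-training).
dataset:
  n_labeled: 20          # 10 per class
  n_unlabeled: 400       # ~200 per class
  class_separation: 2.0  # class-mean distance per view, in noise sd units
  view_correlation: 0.3
  seed: 11
training:
  kernel: linear
  penalty: 1.0
  k_per_round: 2
  max_rounds: 30
  confidence_min: 0.0
evaluation:
  n_seeds: 20
  n_test: 200
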