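# Desk-scale synthetic 3-class cluster task (600 train / 200 valid)
architecture: [10, 20, 3]
n_iter_free: 20
n_iter_nudged: 4
epsilon: 0.5
beta: 1.0
learning_rates: [0.1, 0.05]
minibatch_size: 20
n_epochs: 25
seed: 0
random_beta_sign: true
persistent_particles: true
activation: hard_sigmoid
l2_penalty: 0.0
data:
  kind: clusters
  n_classes: 3
  n_per_class: [267, 267, 266]
  n_features: 10
  spread: 0.05
  valid_fraction: 0.25
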