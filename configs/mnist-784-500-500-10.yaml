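# Two hidden layers of 500 units; edit the IDX paths to your local MNIST copy.
architecture: [784, 500, 500, 10]
n_iter_free: 100
n_iter_nudged: 6
epsilon: 0.5
beta: 1.0
learning_rates: [0.4, 0.1, 0.01]
minibatch_size: 20
n_epochs: 60
seed: 0
random_beta_sign: true
persistent_particles: true
activation: hard_sigmoid
l2_penalty: 0.0
data:
  kind: idx
  images: data/train-images-idx3-ubyte
  labels: data/train-labels-idx1-ubyte
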