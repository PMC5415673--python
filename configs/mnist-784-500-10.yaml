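# One hidden layer of 500 units; edit the IDX paths to your local MNIST copy.
architecture: [784, 500, 10]
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
  kind: idx
  images: data/train-images-idx3-ubyte
  labels: data/train-labels-idx1-ubyte
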