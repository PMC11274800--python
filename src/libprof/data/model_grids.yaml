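# Default hyperparameter grids for the classification model search.
# Deliberately small: only the hyperparameters that matter most per
# algorithm, fully user-overridable.
KNN:
  n_neighbors: [1, 3, 5]
RF:
  n_estimators: [100]
GBT:
  n_estimators: [50]
  learning_rate: [0.1]
SVM:
  C: [1.0, 10.0]
FFNN:
  hidden_layer_sizes: [[32]]
  alpha: [0.0001]
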