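# Default comparative-benchmark configuration: the eight regressor
# families, their (deliberately small, desk-scale) hyperparameter grids,
# and the per-family dimensionality-reduction assignment.
suite:
  - linear
  - random_forest
  - svr
  - xgboost
  - gradient_boosting
  - gp
  - knn
  - lightgbm

reduction_policy:
  linear: tsvdh
  svr: tsvdh
  knn: tsvdh
  xgboost: tsvdh
  gp: tsvdh
  random_forest: none
  gradient_boosting: none
  lightgbm: none

variance_threshold: 0.95

cv:
  scheme: shuffle_split
  n_splits: 10
  validation_fraction: 0.1

grids:
  linear: {}
  random_forest:
    n_estimators: [100, 300]
    max_depth: [null, 8]
  svr:
    C: [0.1, 1.0, 10.0]
    epsilon: [0.05, 0.1]
  xgboost:
    n_estimators: [100, 300]
    max_depth: [3, 6]
    learning_rate: [0.05, 0.1]
  gradient_boosting:
    n_estimators: [100, 300]
    learning_rate: [0.05, 0.1]
  gp:
    n_restarts: [5]
  knn:
    n_neighbors: [3, 5, 9]
    weights: [uniform, distance]
  lightgbm:
    n_estimators: [100, 300]
    num_leaves: [15, 31]
    learning_rate: [0.05, 0.1]
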