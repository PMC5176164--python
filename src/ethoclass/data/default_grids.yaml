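# Default hyperparameter grids for the four model families.
#
# Each family's grid brackets the best parameters found for the captive
# otariid dataset (e.g. SVM polynomial: degree 4, gamma 0.01, coef0 4,
# cost 1), so a search over these grids includes those points. The
# penalised-logistic pair is read as (mixing, strength) of an elastic-net
# penalty; an L1-only or L2-only model is the mixing = 1 or 0 edge.
#
# These grids are sized for a full-scale dataset; ethoclass.model_suite
# exposes fast_grids() for small synthetic cohorts.
families:
  gbm:
    - {learning_rate: 0.01, max_depth: 4, n_rounds: 5000, subsample: 0.8}
    - {learning_rate: 0.01, max_depth: 5, n_rounds: 5000, subsample: 0.7}
    - {learning_rate: 0.05, max_depth: 4, n_rounds: 1000, subsample: 0.8}
  random_forest:
    - {n_trees: 1000, vars_per_split: 12, min_node_size: 3}
    - {n_trees: 1400, vars_per_split: 10, min_node_size: 1}
    - {n_trees: 500, vars_per_split: 7, min_node_size: 1}
  penalised_logistic:
    - {mixing: 0.10, strength: 0.0018}
    - {mixing: 0.81, strength: 0.0012}
    - {mixing: 0.50, strength: 0.0010}
  "svm:linear":
    - {cost: 1}
    - {cost: 10}
    - {cost: 100}
  "svm:polynomial":
    - {degree: 4, gamma: 0.01, coef0: 4, cost: 1}
    - {degree: 4, gamma: 0.01, coef0: 4, cost: 0.1}
    - {degree: 3, gamma: 0.01, coef0: 1, cost: 10}
  "svm:radial":
    - {gamma: 0.001, cost: 100000}
    - {gamma: 0.001, cost: 10000}
    - {gamma: 0.01, cost: 100}
  "svm:sigmoid":
    - {gamma: 0.0001, coef0: 0, cost: 100}
    - {gamma: 0.0001, coef0: 0, cost: 10}
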