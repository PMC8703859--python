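# Hyper-parameter search grids, one block per classifier family.
# Invalid solver/penalty/loss combinations are skipped by the search.
lsvm:
  C: [0.1, 1, 5, 10]
  loss: [hinge, squared_hinge]
  penalty: [l1, l2]
lr:
  penalty: [l1, l2, elasticnet]
  C: [0.1, 1, 5, 10]
  solver: [newton-cg, lbfgs, liblinear, sag, saga]
pagg:
  C: [0.1, 1, 5, 10]
  n_iter_no_change: [1, 5, 10]
rbfsvm:
  C: [0.1, 1, 5, 10]
  kernel: [rbf, poly, sigmoid]
  degree: [2, 3, 4, 5, 6]
  gamma: [scale, auto]
  coef0: [0.0, 0.01, 0.1, 1, 5, 10, 50, 100]
gnb: {}
rf:
  max_features: [sqrt, log2]
  n_estimators: [50, 100, 200, 500, 1000]
  criterion: [gini, entropy]
  bootstrap: [true, false]
  min_samples_split: [2, 5, 10]
xgb:
  booster: [gbtree, gblinear, dart]
  learning_rate: [0.001, 0.01, 0.1, 0.3, 0.5, 1]
  gamma: [0, 0.1, 0.5, 1, 1.5, 2, 5, 20, 50, 100]
  min_child_weight: [0.1, 0.5, 1, 5, 10]
  colsample_bytree: [0.6, 0.8, 1.0]
  reg_lambda: [0, 0.001, 0.5, 1, 10]
  reg_alpha: [0, 0.001, 0.5, 1, 10]
nn:
  hidden_layer_sizes: [[150, 100, 50], [100, 50, 25], [100]]
  activation: [tanh, relu, logistic]
  solver: [lbfgs, sgd, adam]
  alpha: [0.0001, 0.001, 0.01, 0.05, 0.1, 0.5]
  learning_rate: [constant, adaptive]
  beta_1: [0, 0.001, 0.01, 0.1, 0.3, 0.5, 0.9]
  beta_2: [0, 0.001, 0.01, 0.1, 0.3, 0.5, 0.9]
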