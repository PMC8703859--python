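# Frozen per-classifier parameters for re-split evaluation runs.
lsvm: {penalty: l2, loss: hinge, C: 1}
pagg: {n_iter_no_change: 5, C: 0.1}
lr: {solver: newton-cg, penalty: null, C: 0.1}
xgb: {reg_lambda: 0.001, reg_alpha: 0, min_child_weight: 10, learning_rate: 1,
      gamma: 0.1, colsample_bytree: 0.6, booster: gblinear}
gnb: {}
rbfsvm: {kernel: poly, gamma: scale, degree: 3, coef0: 5, C: 0.1}
rf: {n_estimators: 50, min_samples_split: 2, min_samples_leaf: 0.1,
     max_features: sqrt, criterion: entropy, bootstrap: false}
nn: {solver: adam, learning_rate: adaptive, hidden_layer_sizes: [100],
     beta_2: 0.5, beta_1: 0.5, alpha: 0.0001, activation: logistic}
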