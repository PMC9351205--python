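built 400 graphs in 130s
train 31s best_val_auc=0.763 epoch=0
test AUC: 0.654
permuted test AUC: 0.51 gap: 0.143
lr history head/tail: [0.01, 0.01, 0.01] [1e-05, 1e-05, 1e-05]
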