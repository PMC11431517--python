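# Reduced demonstration grid: 3 probabilities x 2 lengths x 2 strategies
# x 2 amplification settings = 24 cells, a few seconds on one CPU.
p_cat_values: [0.0, 0.1, 0.5]
lengths: [6, 10]
strategies: [uniform-no-reuse, weighted-reuse]
amplification: [false, true]
n_samples: 500
seed: 42
include_root_in_k: true
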