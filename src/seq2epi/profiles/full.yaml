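# Full-scale profile: 128-kb windows, 1000 tokens of width 968.
profile: full
model:
  input_length: 128000
  bin_size: 128
  seq_channels: 256
  n_tf_padded: 712
  n_heads: 8
  n_layers: 12
  n_signals: 8
  head_type: regression
  pool_factors: [2, 2, 2, 4, 4]
train:
  learning_rate: 5.0e-5
  batch_size: 10
  alpha: 2.0
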