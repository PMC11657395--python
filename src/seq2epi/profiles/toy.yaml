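# Desk-scale profile used by the synthetic recovery experiments.
profile: toy
model:
  input_length: 4096
  bin_size: 128
  seq_channels: 16
  n_tf_padded: 8
  n_heads: 4
  n_layers: 2
  n_signals: 8
  head_type: regression
  pool_factors: [2, 2, 2, 4, 4]
  conv_kernel: 5
train:
  learning_rate: 1.0e-3
  batch_size: 4
  steps: 1000
  warmup_steps: 50
  cosine_decay: true
  alpha: 2.0
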