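# Hyperparameters for attaching a real DPO/QLoRA training backend to the
# exported preference dataset. The package itself performs no training.
dpo:
  beta: 0.1
optimizer:
  name: paged_adamw_32bit
  learning_rate: 5.0e-5
training:
  max_steps: 200
  batch_size: 8
lora:
  rank: 2
  alpha: 4
  dropout: 0.05
  target_modules: [q_proj, k_proj, v_proj, o_proj, gate_proj, up_proj, down_proj]
quantization:
  bits: 4
  compute_dtype: float16
tokenizer:
  padding_side: left
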