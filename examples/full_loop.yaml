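# Full closed loop: the simulated chemist (persona) reviews each batch, the
# reward function and preference model update, and the toy generator samples
# the next batch in proportion to the updated reward.
liability_labels:
  - toxicophore
  - liked_feature
global_properties:
  - size
reward:
  similarity_cutoff: 0.5
  size_window:
    low: 10
    high: 60
loop:
  k: 10
  strategy: maxmin
  temperature: 0.1
  n_iterations: 3
  n_generate: 30
  seed: 42
persona:
  disliked_smarts:
    - "[N+](=O)[O-]"
  liked_smarts:
    - "NC(C)=O"
  size_range: [5, 50]
  noise_rate: 0.0
paths:
  run_dir: runs/full_loop
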