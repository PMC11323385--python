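# Feedback capture plus preference-model training, merged with prior QSAR
# data; no generation loop. Useful when the trained model will be plugged
# into a separate de novo environment.
liability_labels:
  - toxicophore
  - unstable
  - liked_feature
global_properties:
  - size
  - synthetic_accessibility
model:
  use_model: true
  n_estimators: 100
  feedback_weight: 2.0
  prior_data: prior_qsar.csv
paths:
  molecules: molecules.smi
  run_dir: runs/reward_model
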