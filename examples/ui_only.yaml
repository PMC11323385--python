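# Feedback-capture-only setup: review molecules, store ratings and
# annotations; no reward model is trained and no generation loop runs.
liability_labels:
  - toxicophore
  - unstable
  - synthesis_concern
  - liked_feature
global_properties:
  - size
  - synthetic_accessibility
  - permeability
model:
  use_model: false
paths:
  molecules: molecules.smi
  run_dir: runs/ui_only
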