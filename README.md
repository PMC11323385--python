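# molfeedback

Chemist-in-the-loop feedback capture and reward shaping for de novo
molecular design — headless.

De novo design agents optimize a scoring function, but medicinal chemists
rarely think in descriptors: they judge structures holistically and react
to specific substructures. The result is a familiar gap between what a
generative model optimizes and what a chemist will actually accept.
`molfeedback` closes that gap by turning structured chemist feedback into
reward signal:

* **Feedback capture** — per-molecule ratings (*like / sort of like /
  dislike*), global liability flags (size, synthetic accessibility, …),
  and atom-level substructure annotations. A highlighted atom selection is
  stored as a pair of SMARTS patterns: a *core* pattern recording element,
  aromaticity, ring membership and hydrogen count for each selected atom,
  and an *expanded* pattern that also includes every directly bonded
  neighbor — so a flagged ketone carbonyl keeps matching other ketones
  without swallowing amides.
* **Reward function** — an additive, equally weighted score derived from
  the feedback:

  g(x) = 1/6 [ γ⁺(x) − γ⁻(x) + δ⁺(x) − δ⁻(x) + 0.5 δ±(x) + φ(MS(x)) ]

  where γ± indicate liked/disliked substructure patterns present in x,
  δ± are maximum ECFP4 Tanimoto similarities to the liked / disliked /
  sort-of-liked reference molecules (zeroed unless > 0.5), MS(x) is the
  heavy-atom count and φ a double sigmoid over an adaptive acceptable-size
  window. g is added to the project's own scoring function f:
  S(x) = f(x) + g(x).
* **Reward model** — a seeded random-forest like/dislike classifier over
  Morgan fingerprints, optionally merged with prior QSAR data; its
  predicted probability serves as f(x).
* **Closed loop** — a pluggable generator contract with a shipped toy
  generator (reward-proportional sampling from a molecule pool), diversity
  (MaxMin) selection of molecules for review, a simulated chemist persona
  for fully automatic experiments, and per-iteration archives that reload
  bit-reproducibly.

## Worked example

Extract the stored SMARTS for a carbonyl selection in acetone (atoms 1 and
2 are the carbonyl carbon and oxygen):

```
$ molfeedback extract-smarts "CC(=O)C" --atoms 1,2
core:     [#6;A;!R;H0]=[#8;A;!R;H0]
expanded: [#6;A]-[#6;A;!R;H0](-[#6;A])=[#8;A;!R;H0]
```

The expanded pattern matches acetone and 3-pentanone but not
N-methylacetamide: the two carbon neighbors recorded around the carbonyl
keep the liability from spilling onto amides.

Simulate feedback from a persona that dislikes nitro groups and likes
acetamides, then score molecules against that feedback:

```
$ molfeedback simulate-feedback mols.smi --config cfg.yaml --out fb
wrote feedback for 3 molecules to fb/
$ molfeedback score mols.smi --feedback fb -o scores.csv
$ cat scores.csv
id,smiles,gamma_plus,gamma_minus,delta_plus,delta_minus,delta_pm,size_score,g
nitrobenzene,O=[N+]([O-])c1ccccc1,0.0,1.0,0.0,1.0,0.0,0.2689414213699951,-0.28850976310500076
paracetamol_like,CC(=O)Nc1ccc(O)cc1,1.0,0.0,1.0,0.0,0.0,0.7310585786300049,0.45517642977166745
methylbiphenyl,Cc1cccc(-c2ccccc2)c1,0.0,0.0,0.0,0.0,1.0,0.9525741268224334,0.24209568780373886
```

Nitrobenzene is penalized twice (flagged nitro substructure γ⁻ = 1 and
similarity to a disliked molecule δ⁻ = 1) and lands at g ≈ −0.29; the
acetamide earns the mirrored bonuses (g ≈ +0.46); the unreviewed
methylbiphenyl sits in between, rewarded only for similarity to a
sort-of-liked molecule and a comfortable size. With the default
configuration g is bounded in [−1/3, 7/12].

Run a full closed loop (toy generator + simulated chemist):

```
$ molfeedback loop --config examples/full_loop.yaml
completed 3 iterations under runs/full_loop
```

Each `iter_<t>/` directory holds the generated batch with its scores, the
cumulative feedback table (`feedback.csv` + `annotations.json`), the
trained reward-model artifact and manifest, the generator state and a
config snapshot — enough to resume the run exactly.

Three example configurations under `examples/` cover feedback capture
only (`ui_only.yaml`), feedback plus reward-model training
(`reward_model.yaml`), and the full loop (`full_loop.yaml`).

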