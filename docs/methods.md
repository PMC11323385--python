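# Methods

## The problem being modeled

A de novo design agent proposes molecules; a chemist reviews a few of them
per round; the system must convert that review into reward signal so the
next round of proposals is better aligned with the chemist's (largely
implicit) preferences. `molfeedback` implements the computational side of
that loop headlessly: the feedback data model, the chemistry that makes
annotations transferable between molecules, two complementary reward
mechanisms, and the loop orchestration, with a simulated chemist standing
in for the human so every component is testable end-to-end.

## Feedback model

A feedback record couples one molecule (id, SMILES, optional external
score in [0, 1]) with:

* an overall **rating** on a three-level scale — *dislike*, *sort of
  like*, *like*. Three levels are exactly what the downstream reward
  consumes (three similarity reference sets, a binary classifier with the
  middle level down-weighted); a finer scale would carry no additional
  signal here.
* **global property flags** (`ok` / `concern`) per configured property.
  Only the size flag feeds the reward (see the size window below); the
  rest — synthetic accessibility, permeability and the like — are
  recorded verbatim because they cannot currently be scored
  computationally, but accumulate as labeled data for future models.
* **local substructure annotations**: the selected atom indices, a
  liability label with polarity (liked/disliked) and scope
  (project/general), and the two derived SMARTS patterns described next.
  Atom indices are 0-based positions in the parsed molecule's atom order;
  they are convenient for display but not stable across
  re-canonicalization, so all downstream chemistry uses the SMARTS.

The table is append-only; all derived views (rating-partitioned SMILES
sets, polarity-partitioned SMARTS lists, the current size window) are
recomputed from the records, and loading a saved table replays every
record through the same validation and update path rather than trusting
derived state on disk. Timestamps are informational and excluded from
equality.

## Annotation chemistry: core and expanded SMARTS

For a selected atom set, the **core** pattern encodes, per atom: atomic
number, aromaticity, ring membership, and total hydrogen count; bonds
between selected atoms keep their order/aromaticity. This is specific
enough that the pattern re-embeds in the source molecule exactly on the
selected atoms.

The **expanded** pattern additionally includes every atom at graph
distance 1 from the selection, but these shell atoms carry only atomic
number and aromaticity. The asymmetry is deliberate: a chemist flagging a
ketone typically selects C=O; the expansion records the two attached
carbons, so the pattern still hits 3-pentanone but no longer hits an
amide (whose carbonyl has a nitrogen neighbor). Encoding shell atoms at
full strength (H counts, ring flags) would pin the pattern to the exact
molecule reviewed and defeat the point of generalization. Consequences of
the loose shell encoding: the expanded pattern is strictly more
restrictive than the core (every molecule it matches, the core matches),
and monotonically larger in atom count, with equality exactly for
selections with no external neighbors. Disconnected selections are
emitted as one dot-joined multi-component pattern, each component
expanded independently. Stereochemistry is deliberately not encoded.

Patterns are constructed by writing the molecule fragment with per-atom
SMARTS primitives and explicit bond symbols, which yields strings that
are simultaneously valid SMARTS; charge is not constrained (a nitro
nitrogen is matched by `[#7;A;!R;H0]` regardless of formal charge).

## The reward function

g(x) = p · (γ⁺ − γ⁻ + δ⁺ − δ⁻ + w·δ± + φ(MS)) with defaults p = 1/6,
w = 0.5.

* **γ terms** count *distinct matching patterns*, not embeddings, and are
  normalized by a cap (default 1, i.e. presence/absence): a molecule with
  three esters and one flagged ester pattern contributes once. This keeps
  all six terms on a [0, 1] scale, which is what makes the equal 1/6
  weighting meaningful; the cap is configurable for users who want graded
  counts.
* **δ terms** take the maximum ECFP4 (radius-2, 2048-bit Morgan) Tanimoto
  similarity to the respective reference set — proximity to any one liked
  exemplar is rewarded, rather than an average over the set. A similarity
  not strictly greater than the cutoff (default 0.5) contributes exactly
  0; above it, the raw similarity is returned. The cutoff applies
  uniformly to all three sets. Tanimoto of two empty fingerprints is
  defined as 0, so featureless inputs never earn similarity reward.
* **φ(MS)** is a double sigmoid σ(a·(n − l)) · σ(b·(h − n)) over the
  heavy-atom count n, with the window (l = 10, h = 60, slopes 1.0)
  initialized wide so early iterations are effectively unconstrained by
  size. Size feedback moves one center toward the observed size by a
  fraction α = 0.25 of the gap: a `concern` on a molecule above the
  window midpoint pulls the upper center down (below: the lower center
  up), and an explicit `ok` on a molecule outside the window relaxes the
  violated bound outward. Updates are clipped to keep the centers at
  least 2 heavy atoms apart. The midpoint rule is needed because flags
  record only `ok`/`concern`, not a direction.

With defaults, g ∈ [−1/3, 7/12] (all-negative vs all-positive extremes of
the six bounded terms). g is *not* clamped; the total S(x) = f(x) + g(x)
can exceed 1, and downstream consumers are expected to know that.

## The reward model

Feedback maps to weighted binary rows: like → 1, dislike → 0, sort of
like → 1 at half weight (configurable to drop; discarding a third of
hard-won records by default seemed worse than a soft label). Prior QSAR
rows (CSV of smiles,label) merge in at weight 1 on the same binary axis;
a `feedback_weight ≥ 1` can up-weight chemist rows against a large prior.
The default classifier is a 100-tree random forest on the binary
fingerprint matrix, seeded for exact retraining reproducibility; the spec
is injectable for other scikit-learn-style classifiers. Training refuses
single-class input with an instruction to collect more feedback rather
than silently fitting a constant. The predicted probability of the liked
class is f(x) when no user-supplied scoring function exists.

## The closed loop

Per iteration t: derive reward inputs from the cumulative table → build
the scoring callable S = f + g (f from the model once one exists) →
generator proposes `n_generate` molecules → MaxMin-diverse `k` of them go
to the oracle for review → records enter the table → the model retrains →
everything persists to `iter_t/`. Feedback given at iteration t therefore
shapes generation from iteration t+1 on.

The **toy generator** samples `n` molecules from a fixed pool without
replacement with probability ∝ exp(S/temperature), implemented as
Gumbel-top-k on S/T (identical distribution, numerically exact down to
the T→0 argmax limit). Defaults: temperature 0.1 — on the g scale of
roughly ±0.6 this makes a one-liability penalty (≈0.17 before the model
term) already decisive while leaving real stochasticity among comparable
molecules; `n_generate` 30 and `k` 10 keep a review round at the size a
chemist would plausibly tolerate.

Per-iteration seeds are derived statelessly from (base seed, iteration)
via a seed sequence, so a run resumed from a reloaded archive reproduces
the continuation bit-identically; this is asserted in the tests by
comparing `molecules.csv` byte-for-byte.

## The simulated chemist and fixture pool

A **persona** is a rule set: disliked SMARTS, liked SMARTS, an acceptable
heavy-atom range, and a noise rate. Rating rule: any disliked match →
dislike (a single liability vetoes a molecule, as in practice); else a
liked match with size in range → like; else sort of like. Every matched
pattern is annotated over one actual embedding, so simulated annotations
exercise exactly the same SMARTS machinery as human ones. At noise 0 the
oracle is a deterministic function of (molecule, persona).

The **fixture pool** enumerates four scaffolds (benzene, pyridine,
cyclohexane, biphenyl) in several positional variants, decorated with up
to two of {methyl, hydroxyl, nitro, acetamido, carboxyl}: 234 unique
valid molecules, of which 74 carry a nitro group. This is deliberately
tiny — large enough for preference learning to have held-out structure,
small enough that a three-iteration loop runs in seconds. What it does
*not* emulate: real molecular diversity (no novel scaffolds, no
stereocenters, no property gradients beyond size), generator chemistry
errors, or inconsistent human raters. Passing loop tests therefore show
the machinery aligns against a consistent rule set on a closed pool, not
that it would tame a production generative model.

## Alignment measurement

The loop's learning curve is the mean assigned score S of each generated
batch at generation time (stored in the archives). Batches can also be
re-scored under one fixed set of reference inputs
(`batch_mean_rewards`) when cross-iteration comparability under a single
reward is wanted; note the fixed-reference curve saturates quickly on the
closed pool, after which small fluctuations between iterations are
expected.

## Numerical and degenerate-input choices

* Logistic evaluated via `scipy.special.expit` (no overflow at extreme
  sizes); φ is strictly inside (0, 1).
* The similarity cutoff is a strict inequality: a similarity of exactly
  0.5 scores 0.
* Duplicate (molecule id, iteration) feedback is rejected; duplicate
  molecules across rating sets deduplicate at the fingerprint-set level.
* Empty reference sets and empty pattern lists score 0 in their terms, so
  an empty table yields g = φ/6 ≈ 1/6 for a mid-window molecule.
* The breakdown's combination identity (g vs its six parts) holds to
  1e-12 and is asserted in tests.

## Known limitations

* No stereochemistry or tautomer awareness in patterns or fingerprints.
* The size-flag direction heuristic (window midpoint) can misread a
  `concern` on a molecule near the middle of a very wide window.
* `annotations.json` links annotations to records by molecule id, so a
  molecule id reviewed at several iterations with annotations is
  ambiguous on reload and rejected; the loop's id scheme (`it<t>_m<j>`)
  never produces this.
* The toy generator cannot invent molecules; alignment manifests as
  re-weighting a fixed pool. Plugging in a real generative model is the
  intended extension point of the generator contract.
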