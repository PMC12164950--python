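# Methods

`rxnrl` studies one question: when successful (positive) reaction examples are
scarce but failed (negative) ones are abundant, can a forward reaction
prediction model learn more from reinforcement-learning feedback against a
negative-aware reward model than from ordinary maximum-likelihood fine-tuning?
Everything in the package — the synthetic reaction language, the
sequence-to-sequence policy, the reward model, the RL tuner and the evaluation
harness — serves that comparison at desk scale (minutes on one CPU core).

## The task and its data regimes

A forward prediction model maps a serialized precursor set
`p1.p2.….pn` to a single product SMILES. Training data come in two kinds:

* **positives** — reactions whose recorded product is the true outcome;
* **negatives** — reactions whose recorded product is a plausible but wrong
  outcome (here: the right transformation at the wrong ring position), or a
  product observed only at negligible yield.

Two regimes are constructed from the same corpus. The *abundant* regime
(`K_high` in the bundled experiments) trains on every available positive, 200
by default, with roughly four enumerated negatives per positive (ratio chosen
so that the scarce regime below reaches a 40-fold negative excess; a
real-world reference corpus of this kind has ratio ≈ 3.4). The *scarce*
regime (`K_low`) subsamples the training positives to 10% — 20 positives by
default — while keeping the entire negative pool, so the positive:negative
ratio drops tenfold (0.25 → 0.025) exactly as in the reference protocol.
Validation and test splits contain positives only (60 + 60 by default):
accuracy is always *positive accuracy* — the fraction of positive reactions
whose true product the model ranks in its top-k predictions, with candidates
canonicalized before string comparison and invalid SMILES never matching.

## The synthetic reaction family

Real regioselectivity corpora are too large to train on in minutes and their
labels come from quantum chemistry. The generator replaces them with a toy
family that keeps every mechanically relevant property and none of the cost:

* **Substrates** are mono-substituted aromatic scaffolds built from ~30 ring
  templates (benzenes, azines, five-membered heterocycles, fused bicyclics)
  × ~34 substituents, capped at 14 heavy atoms. All molecules are real
  SMILES handled by RDKit, so tokenization, validity checking and the
  invalid-prediction metric are exercised unchanged.
* **The directing rule.** Electrophilic halogenation (Br₂ or Cl₂) places the
  halogen on an aromatic C–H position *ortho* to the substituent's attachment
  carbon; when the two ortho positions are distinguishable the
  lexicographically smaller canonical product is the designated positive.
  The rule is deterministic and injective per substrate, so ground truth is
  exactly recoverable and evaluation carries no label noise.
* **Negatives** are enumerated by moving the installed halogen to every other
  aromatic C–H position (`generate_regio_negatives`), canonicalized,
  deduplicated, and excluding the true product. The moved halogen is
  identified as the one whose deletion recovers a precursor, so halogens
  carried through from the substrate are never moved. Negatives share the
  positive's left-hand side and are isomeric with its product by
  construction. Scarce-regime negative pools are topped up with negatives
  from additional left-hand sides whose own positives are withheld — the
  structure a subsampled corpus has naturally.
* **The pretraining corpus** (4,000 reactions by default) plays the role of a
  large, heterogeneous patent corpus: functional-group transforms
  (O-methylation, N-acetylation, nitrile/aldehyde/alkene reductions, one per
  reagent per substrate so every input has a unique outcome) plus
  halogenations whose position follows the ortho rule only half of the time
  (a random alternative site otherwise). The pretrained model therefore
  speaks the reaction language and places halogens plausibly, but knows the
  family's regiochemistry only partially — mirroring a general-purpose model
  meeting a specialist dataset (its top-1 on the family validation split is
  ≈ 0.4–0.5). Pretraining substrates are drawn mostly from *disubstituted*
  scaffolds, a much larger combinatorial space disjoint from the family
  pool; corpus products overlapping family validation/test products are
  excluded outright.
* **The held-out pretraining slice** (10%) contains only the deterministic
  transforms — mixed-rule halogenations are irreducibly ambiguous on unseen
  substrates and cannot serve as a learnability or forgetting yardstick.
* **HTE grid.** For screening-style data, substrates × (catalyst, solvent)
  grids get a hidden deterministic yield rule (catalyst must match ring
  class, polar substituents demand the polar solvent, bulky substrates never
  react); yields land in (10, 90]% on success and (0, 1]% on failure, and
  labels follow the strict `yield > 1%` threshold. Success is deliberately
  non-uniform across substrates, and a `positive_fraction` knob reproduces
  the sparsity of competing positive/negative pairs seen in real screens.

What the toy family does *not* emulate: chemically realistic energetics,
multi-product outcomes, stereochemistry, reagent/condition effects on
regiochemistry, and the long-tailed structural diversity of patent data.
Passing tests therefore demonstrate that the method's machinery — reward
shaping from negatives, KL-anchored policy gradients, imbalance-aware
classification — behaves as designed, not that it will lift accuracy on any
particular real corpus.

## Aligned product serializations

All bookkeeping (identity, deduplication, comparison, storage) uses canonical
SMILES. Generation *targets*, however, are serialized in the substrate's atom
order with the edit in frame (`Reaction.product_aligned`): canonicalization is
a global graph algorithm that a 4,000-reaction corpus cannot teach, and with
canonical targets a desk-scale model plateaus near 50% exact match for purely
serialization-related reasons. With aligned targets the task measures what it
should — whether the model learned the chemistry — and the pretrained model
reaches >90% exact match on held-out transforms. Decoded candidates are
canonicalized before every comparison, so metrics never see the difference.

## Models

**Policy.** A pre-norm encoder–decoder transformer over SMILES tokens
(2+2 layers, width 64, 4 heads, feed-forward 128; ~250k parameters) with a
pointer-generator output: the next-token distribution is a learned-gate
mixture of the vocabulary softmax and a copy distribution given by attention
over source tokens. The copy path is what lets a small-corpus model reproduce
unseen substrate skeletons token-for-token; without it, held-out exact match
stalls some 30 points lower. Tokenization follows the standard molecular-
transformer regular expression (multi-character elements and bracket atoms
are single tokens). Training is teacher-forced cross-entropy (sentinels and
padding excluded) under Adam with cosine learning-rate decay; the checkpoint
with the best validation top-1 is kept, with the starting model as the
epoch-0 candidate so that an unproductive run falls back to it. Decoding is
length-bounded beam search (10 beams by default, no length normalization —
products are short) or ancestral sampling for RL rollouts. The neural stack,
including the reverse-mode autodiff engine underneath, lives in the package
(`rxnrl.nn`) and is verified against central finite differences in the test
suite.

**Reward model.** A separate bidirectional transformer encoder (2 layers,
width 64, mean pooling) embeds full reaction strings into fingerprint
vectors. It is *classification-tuned*: trained with a discardable linear head
and class-weighted binary cross-entropy to separate successful from failed
reactions, on a reward-tuning slice of the scaffold pool disjoint from both
pretraining and the family splits. An RBF-kernel SVM with class weights
inversely proportional to class frequency is then fitted on the training
split's embeddings (20 positives vs ~800 negatives in the scarce regime).
Probabilities come from a class-balanced sigmoid fit on cross-validated
decision margins; a plain Platt fit on 20:800 data pushes every score below
one half and destroys the reward's dynamic range. Encoder tuning is what
makes the classifier generalize: on held-out validation reactions the
balanced accuracy of the SVM is ≈ 0.83 on tuned embeddings versus ≈ 0.5 on
untuned ones, and the two-principal-component projection shows the same
separation (`separation_report`). Masked-language pretraining of this
encoder is omitted as a scale concern, not a mechanism: classification
tuning starts from random initialization.

**Composite reward.** For a decoded product given a left-hand side, in order:
invalid SMILES → 0; canonical match to a known training positive for that
input → 1; match to a known training negative → 0; otherwise the calibrated
probability of success (thresholded at 0.5 to {0, 1} in the binary/HTE mode).
The reward is a total function into [0, 1]. The exact-match rules make the
reward label-faithful where labels exist; the classifier extends it to the
policy's novel proposals — including the withheld positives of
negative-only inputs, which is precisely where negative data pays off.

**Value network.** Two linear layers separated by a ReLU with a sigmoid
output (zero-initialized head, so the untrained estimate is 0.5), reading the
mean-pooled encoder state of the left-hand side: a state-value baseline on
the same [0, 1] scale as the reward.

## RL tuning

The tuner follows the standard RLHF recipe. A frozen clone of the starting
policy serves as the reference π_ref (the input policy itself is never
mutated). Each epoch:

1. sample `rollouts_per_epoch` (default 128) left-hand sides uniformly from
   the training reactions — positives *and* negatives contribute their
   inputs — and one product sequence each at temperature 1.0;
2. score each with the composite reward and apply a per-sequence KL penalty,
   `r̃ = r − β·(log π(y|x) − log π_ref(y|x))` with β = `kl_coeff` (default
   0.1); at initialization the penalty is exactly zero;
3. take `update_iters` (default 2) clipped-surrogate policy-gradient steps
   (sequence-level importance ratio clipped at ±0.2; advantages `r̃ − V(x)`,
   normalized per batch) and regress the value network toward the realized
   r̃;
4. evaluate greedy top-1 positive accuracy on the validation split and keep
   the best checkpoint (epoch 0 = the starting model).

Reward is terminal and uniformly credited — it is defined on whole predicted
reactions, so no per-token shaping is attempted. A guard aborts training if
the mean sampled KL exceeds 50 nats (collapse). Defaults
(`lr_policy` 3e-5, `lr_value` 1e-3, 30 epochs) were chosen on mean behavior
across three seeds, never a single seed; the policy learning rate trades
speed of improvement against drift on the pretraining domain, and the default
sits where validation accuracy saturates while the pretraining-domain loss
stays within about two accuracy points (the no-catastrophic-forgetting
regime). The HTE workflow chains an MLE fine-tune (domain shift) before RL
with the binary reward.

At desk scale the comparison reproduces the qualitative pattern that
motivates the method: starting from a base policy at ≈ 0.4–0.6 validation
accuracy, MLE fine-tuning on 20 positives typically lands at ≈ 0.6–0.88 while
RL against the negative-aware reward reaches ≈ 0.83–0.90 and wins in the
majority of seeds; with all positives available, fine-tuning is at parity or
ahead. RL also all but eliminates invalid predictions among top-1
candidates, whereas scarce-data fine-tuning can leave several percent.
(Numbers are seed-dependent; the acceptance script recomputes them.)

## Evaluation and statistics

`evalx` computes top-k positive accuracy from a single beam decode per input
(k ≤ beams), and the invalid fraction over all k·n top-k candidate slots
(per-slot, not per-input — a ranking-depth property). The comparison harness
evaluates fine-tuning and RL on identical splits per seed. Multi-seed
summaries report per-seed metrics, mean and standard deviation (default five
seeds); individual seed failures are recorded in the summary rather than
aborting the run, and the per-seed breakdown makes outlier splits visible
without corrupting the mean-based comparison.

## Numerical and design notes

* The autodiff engine runs float32 by default; gradient tests switch it to
  float64 for finite-difference headroom. Gradient-norm clipping (1.0) and
  a log-probability floor of 1e-9 in the pointer mixture guard against
  overflow; a non-finite loss or gradient raises immediately rather than
  silently corrupting a run.
* Beam search breaks ties by expansion order; sampling draws via inverse-CDF
  on the tempered distribution, and reported per-token log-probabilities are
  those of the *untempered* policy (what importance ratios and KL need).
* Split sizes use largest-remainder rounding with ties to the earlier split;
  splits, subsampling, rollouts and all initializations are driven by
  explicit integer seeds, and identical seeds reproduce byte-identical
  datasets and training histories.
* Reagents and reactants are merged into one precursor list; multi-fragment
  products are rejected (the forward task predicts a single outcome
  species). Stereochemistry is out of scope.
* Degenerate inputs: empty rollout batches, single-class classification
  data, missing yields, k > beams, and unparsable SMILES all raise typed
  errors; the separation report returns NaN rather than raising on
  degenerate geometry.

## Known limitations

The toy family's regiochemistry is a string-local rule, far easier than real
electrophilic-substitution energetics; absolute accuracies here say nothing
about real corpora. The reward model sees rule-generated (type-1) negatives
and thresholded-yield (type-2) labels, but no experimental noise. The RL
tuner implements one member of the RLHF family (clipped surrogate with
per-sequence KL penalty); exact reward arithmetic and hyperparameters of the
reference pipeline are not public, so the composite-reward constants
(`invalid_reward`, `match_bonus`, threshold) are configuration, not claims.
Desk-scale sizes (corpus 4,000; 200/60/60 family splits; 128 rollouts/epoch;
25 RL epochs) are the package's chosen operating point so the full suite runs
in minutes; all of them are plain configuration fields.
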