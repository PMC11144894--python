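# Methods

## Problem setting

Given a set of drugs with known structures (SMILES) and a table of
observed interactions M = {(H_x, H_y, R)} over an interaction-type
vocabulary I, the task is binary: estimate the probability that a
candidate triple is a true interaction.  Only positives are observed,
so the problem is posed knowledge-graph style — each positive is paired
with a corrupted copy (one drug slot replaced by another drug, relation
kept, 1:1 ratio) and the model is trained to separate the two.
Relations are directional (x may affect the metabolism of y and not
conversely), so the scorer is deliberately order-sensitive; a
symmetrized prediction (mean of both orders) is available but off by
default.

## Molecular graph input

`chem_io` parses SMILES with RDKit into heavy-atom graphs: hydrogens
stay implicit, and bonds of any order or aromaticity become single
undirected edges, because no stage of the model consumes edge features.
Each atom is encoded by a fixed 55-wide descriptor composed of one-hot
blocks — element over {C,N,O,S,F,P,Cl,Br,I,B}+other (11), degree 0–5
+other (7), implicit hydrogens 0–4+other (6), formal charge −2..+2
+other (6), hybridization over six classes+other (7), total valence
0–6+other (8) — plus ring-size flags for rings of 3–8 atoms (6) and
{aromatic, in-ring, chiral, radical} flags (4).  Every one-hot block
carries a catch-all slot, so each block sums to exactly 1.  This
composition is a reconstruction of the conventional substructure-GNN
descriptor set at the stated width; the schema object is configurable
and alternatives are drop-in as long as the widths sum to the declared
total.  Descriptors are layer-normalized per atom (ε = 1e-5); the
LayerNorm affine is kept at identity since the trainable input
projection that follows absorbs any rescaling.

## Encoder

K stacked soft-mask layers (default K = 4, hidden width D = 128; the
synthetic-corpus experiments use K = 3, D = 64 — see "Problem sizes").
Layer k computes a scalar mask per atom from a two-layer perceptron
(hidden width D, ReLU inside, sigmoid output) over the concatenation of
a self term I₁(m h) and a neighbour sum Σ I₂(m h), then the masked
ReLU update, gated *outside* the activation:

    h_u ← m_u · ReLU(W_k [m_u h_u ∥ Σ_{s∈N(u)} m_s h_s]).

Design choices that were genuinely open:

* **Output gating.**  The masked update without the outer factor m_u
  does not by itself zero a masked node (the neighbour-sum branch
  survives).  Multiplying the post-activation update by m_u is the
  minimal form under which the claimed skipping property — clamping a
  node set's masks to zero reproduces the encoding of the graph with
  that set deleted — holds identically.  The property is tested to
  1e-6 elementwise (and holds to machine precision).
* **I₁/I₂ carry no bias.**  A per-neighbour bias survives a zero mask
  (the bias of a deleted neighbour would still be summed), which would
  break the same property for any trained parameters; as pure linear
  maps the property holds for *all* parameter values.
* **Initial masks are 1** (no masking before evidence), and N(u)
  excludes u (the update has an explicit self term).
* **Parameters are not shared across layers.**
* **Initialization** is Glorot-uniform with zero biases, fully
  seed-controlled.

A SUM readout after every layer produces the drug's substructure
sequence h¹..h^K.  The jump concatenation of all K vectors is computed
and exportable but unused downstream: the attention and scoring stages
consume the per-layer sequence, whose D-vectors are what the D×D
relation matrices can pair.

## Attention update and scoring

The two sequences are mapped by ReLU affine maps to attention vectors;
every layer pair (i, j) is scored as ReLU(W_a(ha_x^i + ha_y^j) + b) —
a D-vector per pair by default, so attention is resolved over layers
*and* channels; a scalar-per-pair variant sits behind
`channel_attention=False`.  The activation inside this map is ReLU
(matching the surrounding maps); the sigmoid that bounds attention
into (0,1) is applied only after averaging over the other drug's layer
index, avoiding a double squash.  The update ĥ = 0.5·h + h ⊙ A_h keeps
every channel within [0.5·h, 1.5·h] for nonnegative h, with a flat
A_h = 0.5 an exact fixed point; the 0.5 is a fixed constant, not a
tunable.  Disabling the module (`attention_module=False`) bypasses it
exactly.

Co-attention weights γ_ij = zᵀ tanh(W_x ĥ_x^i + W_y ĥ_y^j) are left
unnormalized — tanh is chosen precisely so that non-interacting
substructure pairs can carry negative weight, which a softmax would
forbid.  The final probability is the sigmoid of Σ γ_ij ĥ_x^i ᵀ M_R
ĥ_y^j over all K² layer pairs; the logit is clamped to ±30 purely for
numerical safety (|logit| = 30 leaves p within 1e-13 of {0,1}).
D′ (the co-attention width) defaults to D.  Classification uses the
strict rule p > 0.5.

## Training

Adam (β = 0.9/0.999, ε = 1e-8) with L2 weight decay 5e-4 folded into
the gradient, learning rate 5e-4·0.96^epoch, batches of 128 triples.
One negative is sampled per positive per epoch; corruptions replace
one uniformly chosen drug slot, avoid self-pairs, keep the relation,
and are resampled (bounded retries, then the other side) when they
collide with a known positive.  Validation negatives are drawn once
per run with a dedicated derived seed so that per-epoch validation
metrics are comparable; the checkpoint with the best validation AUROC
is selected.  Dropout (inverted scaling, applied to substructure
embeddings before the attention module) defaults to 0 for warm-start
and 0.2 for cold-start training.  All randomness derives from a single
integer seed via `numpy.random.SeedSequence`; two runs with the same
seed produce bitwise-identical histories.

**Head initialization.**  The scoring head (z and the relation
matrices) is initialized at 0.01× Glorot scale.  At full scale the
untrained logits are ±7 noise, the initial loss exceeds the trivial
p ≡ 0.5 loss (2 ln 2), and the fastest descent direction collapses the
soft masks to zero — a saturated fixed point with identically zero
embeddings that the optimizer cannot leave (observed directly: loss
pinned at 1.386294, deep-layer gradients ~1e-7).  Starting the head
small places the model *at* the trivial loss with every gradient path
alive, the standard small-head/zero-γ initialization remedy for
multiplicative output heads.  A positive initial mask bias was also
evaluated and made collapse more, not less, frequent, so mask biases
stay at zero.

Small-head initialization makes collapse rare but not impossible, and
a collapsed run is unambiguous: the training loss never leaves the
2 ln 2 plateau.  `fit` therefore retrains from a deterministically
re-derived initialization when the final-epoch loss is still within 5%
of that plateau, up to `max_restarts` (default 3) times — the
multi-start strategy familiar from k-means.  Detection uses the
training loss only, so genuinely hard tasks (which still reduce
training loss by memorization) never trigger it, and all restart seeds
derive from the run seed, preserving bitwise reproducibility.

## Evaluation protocols and metrics

*Transductive* (warm start): triples split 60/20/20, stratified by
relation (per-relation proportions within ±1 triple; relations with
fewer than 5 triples trigger a global-split fallback).  *Inductive*
(cold start): 20% of drugs held out; train/val use only retained-drug
triples (split 3:1, i.e. the same 60:20 ratio), S1 = both drugs held
out, S2 = exactly one.  Both splits are deterministic functions of
(data, spec, seed).  Metrics are ACC and F1 at the strict 0.5
threshold plus AUROC and AUPRC (average precision), computed via
scikit-learn and verified in the tests against exhaustive definitions
(pairwise concordance with half-weight ties; stepwise
precision-weighted recall increments) on all inputs up to length 20.

## Synthetic corpus

The generator emulates the premise that interactions are driven by
substructure co-occurrence.  Drugs are linear/branched alkane
scaffolds of 4–12 carbons with one motif (probability 0.3) or two
(0.7) grafted from a six-motif library (carboxylic acid, primary
amine, phenol, nitrile, aliphatic alcohol, chloro); motif presence is
verifiable by SMARTS matching.  An ordered rulebook maps directional
motif pairs to relation ids; a pair's label is the first firing rule.
Positives are sampled uniformly without replacement from the rule
closure (every labelled ordered pair); the closure is also exposed as
the negative-sampling filter, so corrupted triples are never unlisted
true positives — without this, roughly a sixth of "negatives" would be
rule-consistent and the measured ceiling would reflect label noise
rather than the model.  A noise rate relabels exactly
⌊noise·n_triples⌋ triples uniformly over the relation vocabulary.
The two-motif probability 0.7 makes the closure comfortably larger
than the default 600 sampled triples at 60 drugs.

What the corpus does *not* emulate: realistic pharmacology, relation
semantics beyond motif pairing, molecule sizes beyond ~25 heavy atoms,
ring-system diversity, stereochemistry, or class imbalance across
relations.  Passing the learnability tests therefore shows the
pipeline can discover planted substructure logic end to end — not that
it reaches any particular accuracy on DrugBank-scale data.

## Problem sizes

The synthetic experiments run at 60 drugs / 3 relations / 600 triples
with K = 3, D = 64 and 50 epochs — small enough that a full
warm-start + cold-start + ablation battery runs in about a minute on
one CPU, while leaving the planted signal non-trivial (held-out ACC at
chance is 0.5).  The memorization check uses 20 triples with fixed
negatives for 200 epochs.  Encoder-level properties (gating,
permutation invariance) are checked on random graphs of up to 12 nodes
at D = 16.

## Known limitations

* The NumPy autodiff core is single-threaded per operation and builds
  one tape per batch; it is sized for tens-of-atoms graphs and
  hundreds of drugs, not for DrugBank-scale corpora.
* AUROC/AUPRC are reported as NaN (with a warning) when an evaluation
  fold contains a single class.
* Negative sampling can exhaust legal corruptions on very small or
  fully-connected drug pools and raises rather than silently reusing a
  known positive.
* The 55-feature schema is a faithful-width reconstruction, not a
  published enumeration; models trained under different schemas are
  not checkpoint-compatible (the checkpoint stores the input width and
  refuses mismatches at load time via the projection shape).
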