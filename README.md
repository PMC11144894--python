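# masmddi

Drug–drug interaction (DDI) prediction from molecular structure, built
around a **multi-layer adaptive soft-mask graph neural network** with
**substructure co-attention**.

Co-administered drugs can interact — one drug altering the metabolism,
efficacy or toxicity of another — and screening candidate pairs *in
silico* is far cheaper than discovering interactions in the clinic.
Interactions are largely driven by specific chemical substructures
(functional groups and their environments), so this package scores a
drug pair by first *finding* the relevant substructures in each
molecule and then scoring all pairings of those substructures against a
learnable representation of each interaction type.

## The model

Each drug's SMILES string becomes a heavy-atom graph whose nodes carry
a 55-dimensional chemical descriptor (element, degree, hydrogens,
charge, hybridization, valence, ring membership), layer-normalized per
atom and projected to width D.  The encoder stacks K soft-mask GNN
layers; layer k computes for every atom u a mask m_u^k ∈ (0,1) from a
sigmoid-terminated perceptron,

    m_u^k = σ(MLP(ReLU[ I₁(m_u h_u) ∥ Σ_{s∈N(u)} I₂(m_s h_s) ]))

and the masked update

    h_u^k = m_u^k · ReLU(W_k [ m_u^k h_u^{k−1} ∥ Σ_{s∈N(u)} m_s^k h_s^{k−1} ]),

so a zero-masked atom is exactly invisible — masking a node set
reproduces, to machine precision, the encoding of the graph with that
set deleted.  A SUM readout after every layer gives K graph-level
vectors h_x^1..h_x^K per drug: substructure views at growing receptive
field.

For a pair (x, y), an attention module rescales the two view sequences
channel-wise (ĥ = 0.5·h + h ⊙ A_h with A_h ∈ (0,1), computed from all
view pairs), co-attention weights every view pair

    γ_ij = zᵀ tanh(W_x ĥ_x^i + W_y ĥ_y^j)

(unnormalized; tanh lets non-interacting substructure pairs go
negative), and the interaction probability under relation R is

    p = σ( Σ_ij γ_ij · (ĥ_x^i)ᵀ M_R ĥ_y^j ),

with one learnable D×D matrix M_R per interaction type.  Training pairs
every observed positive triple with a corrupted negative (one drug slot
replaced, 1:1 ratio) under the paired binary cross-entropy
−mean(log p_pos + log(1−p_neg)), optimized by Adam with
lr = 5·10⁻⁴·0.96^epoch and weight decay 5·10⁻⁴.

The network is implemented directly on NumPy with a small reverse-mode
autodiff core (`masmddi.autodiff`), verified against finite differences
in the test suite.

## Worked example

```python
from masmddi import generate_corpus, TrainConfig, split_transductive, sample_negatives
from masmddi.model import DDIModel
import numpy as np

corpus = generate_corpus(n_drugs=60, n_relations=3, n_triples=600, seed=11)
train, val, test = split_transductive(corpus.triples, seed=1)
model = DDIModel(train, corpus.drug_map,
                 config=TrainConfig(n_layers=3, hidden_dim=64, epochs=50, seed=1),
                 n_relations=3, known_positives=corpus.rule_closure())
results = model.fit(train=train, val=val)
print(results.summary())
negatives = sample_negatives(test, corpus.drugs, corpus.rule_closure(),
                             np.random.default_rng([1, 1]))
print(results.evaluate(test, negatives).as_dict())
```

prints

```
DDI soft-mask co-attention model
================================================
drugs: 60    relations: 3    training triples: 360
encoder: K=3 layers, D=64, attention=on
optimizer: Adam lr=0.0005*0.96^t, weight decay=0.0005, batch=128
epochs run: 50    selected epoch: 30
validation at selection: ACC=0.9790 AUROC=1.0000 AUPRC=1.0000 F1=0.9794
final training loss: 0.0208
{'ACC': 0.9876..., 'AUROC': 1.0, 'AUPRC': 1.0, 'F1': 0.9877...}
```

The corpus is synthetic: each drug is an alkane scaffold carrying one
or two functional-group motifs (carboxylic acid, primary amine, phenol,
nitrile, alcohol, chloro), and an ordered rulebook maps motif pairs to
interaction types.  Labels therefore depend only on substructure
presence — exactly the signal the soft masks are meant to isolate — so
held-out accuracy near 1 means the planted chemistry was recovered.
The same workflow applies to any real DDI table plus SMILES map loaded
through `masmddi.chem_io`.

## Command line

```sh
masmddi simulate --n-drugs 60 --n-relations 3 --n-triples 600 --seed 0 --out corpus/
masmddi split    --triples corpus/triples.tsv --drugs corpus/drugs.tsv \
                 --mode transductive --seed 0 --out splits/
masmddi train    --triples splits/train.tsv --val-triples splits/val.tsv \
                 --drugs corpus/drugs.tsv --layers 3 --dim 64 --epochs 50 \
                 --checkpoint model.npz --log history.tsv
masmddi predict  --checkpoint model.npz --triples splits/test.tsv \
                 --drugs corpus/drugs.tsv --out predictions.tsv
masmddi evaluate --checkpoint model.npz --triples splits/test.tsv \
                 --drugs corpus/drugs.tsv
```

`--mode inductive` splits by *drugs* instead of triples: 20% of drugs
are held out entirely, S1 test triples have both drugs unseen and S2
exactly one — the cold-start protocols under which structure-based DDI
prediction is genuinely hard.

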