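# cypdfi

Drug–food interaction (DFI) prediction with CYP450-guided attention
regularization.

Food compounds routinely change how drugs are absorbed and metabolized, and
the majority of clinically relevant DFIs run through the cytochrome P450
(CYP450) enzyme family — grapefruit juice inhibiting CYP3A4 being the
textbook case. `cypdfi` is for computational chemists and drug-safety
researchers who want to (a) score arbitrary drug–food compound pairs for
interaction risk from SMILES alone, so new compounds need no retraining,
and (b) read off *why*: which substructures of a compound the model
associates with substrate or inhibition behavior against each of five
CYP450 isoenzymes (CYP1A2, CYP3A4, CYP2C19, CYP2C9, CYP2D6).

## The model

Each compound is featurized twice: as the set of on-bits of its 1024-bit
radius-2 extended-connectivity fingerprint (each bit = a "substructure",
embedded through a trainable table), and as its heavy-atom molecular graph
(encoded by edge-attributed GIN convolutions with mean pooling). A panel of
five isoenzyme embeddings (480-dim protein-language-model vectors, injected
as data) queries the compound's substructure set through a
Set-Transformer-style multihead attention block with additive attention:

- `n_ρ` trainable **pseudo-substructures** are appended to every compound's
  real substructures before attention;
- for head 1 (substrate) and head 2 (inhibition), the attention mass that
  isoenzyme *j*'s query places on the **real** columns is the model's
  predicted probability that the compound is a substrate/inhibitor of *j* —
  the pseudo rows act as an "no interaction" sink;
- where a compound has a curated CYP450 annotation, that probability is
  supervised with binary cross-entropy (the auxiliary loss `L₂`); where the
  annotation is missing — as for essentially all food compounds — the
  attention stays unsupervised. Heads 3–4 are always free.

The attended isoenzyme rows are mean-pooled into a compound-integrated
CYP450 embedding `H_I`; the drug's `H_I` is fused with the food's graph
embedding by a vector outer product (and vice versa), the two flattened
blocks are concatenated (width `2h²`), and a four-layer feedforward head
emits the interaction probability ŷ. The training objective is

```
L = L₁ + α·L₂ ,   L₁ = BCE(ŷ, y),   α = 5
```

with AdamW, dropout 0.3, and all compound-side parameters shared between
the drug and the food compound. Evaluation uses Butina-cluster **cold
splits**: every cluster of (drug or food) compounds is confined to one of
train/valid/test, so test compounds are structurally unseen.

No deep-learning framework is required: the package includes a compact
numpy reverse-mode autodiff engine (`cypdfi.nn`) that implements exactly
the operations this architecture needs, with gradients verified against
finite differences.

## Worked example

Train on a synthetic benchmark with planted CYP structure and explain a
prediction (the numbers below are what the commands print with these
seeds):

```bash
cypdfi simulate --out bench/ --n-drugs 20 --n-foods 14 --seed 4
cypdfi split --dfi bench/dfi.tsv --mode cold_drug --seed 4 --out split.tsv
# -> split written to split.tsv (leakage: 0)
cypdfi train --dfi bench/dfi.tsv --split split.tsv \
             --dci bench/dci_observed.tsv --config cfg.yaml --out model.npz
cypdfi evaluate --ckpt model.npz --dfi bench/dfi.tsv --split split.tsv \
                --partition test --out metrics.json
cypdfi explain --ckpt model.npz \
               --drug-smiles "CC(=O)Nc1ccc(O)cc1" --food-smiles "CCO" --out explain/
```

`explain/` then contains, per compound, one tab-delimited 5×(n+n_ρ)
attention matrix per head (isoenzyme rows, fingerprint-bit columns, then
`pseudo_0…`), a 2×5 DCI score matrix whose entries are exactly the row
sums over the real columns, and the top-3 attended substructures per
(head, isoenzyme) with their atom index sets for highlighting.

The same pipeline is available as a scikit-learn estimator:

```python
from cypdfi.estimator import DFIClassifier
clf = DFIClassifier(h=32, random_state=0).fit(X, y, dci=annotations)
proba = clf.predict_proba(X_new)[:, 1]   # interaction probabilities
scores = clf.dci_scores(["CC(=O)Nc1ccc(O)cc1"])  # (1, 2, 5) substrate/inhibition
```

where `X` is an (n, 2) array of (drug SMILES, food SMILES) pairs.

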