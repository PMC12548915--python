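# Methods

## Problem and model

`cypdfi` treats drug–food interaction (DFI) prediction as binary
classification of compound pairs, with the working assumption that most
DFIs are mediated by the five CYP450 isoenzymes with the best annotation
coverage (CYP1A2, CYP3A4, CYP2C19, CYP2C9, CYP2D6). The architecture has
six parts; drug and food compounds share all compound-side parameters.

**Substructure encoder.** A compound's 1024-bit radius-2 binary circular
fingerprint is read as a *set* of on-bits. Each bit indexes a trainable
2h-dimensional row of a global table; rows pass through
Linear(2h → h) → LeakyReLU → Dropout. The fingerprint is binary
(presence), hashed without chirality; chirality is still visible to the
graph branch. Multi-fragment SMILES are reduced to the largest organic
fragment (logged) before any featurization, so salts behave like their
parent compound.

**Graph encoder.** The heavy-atom molecular graph carries 9 categorical
atom channels (atomic number, chirality tag, total degree, formal charge,
H count, radical electrons, hybridization, aromaticity, ring membership)
and 3 bond channels (bond type, stereo, conjugation), each embedded to
width h and summed. Three edge-attributed GIN convolution layers
(message = LeakyReLU(source + bond embedding), sum aggregation, linear
update, LeakyReLU between layers) are followed by global mean pooling.
The depth of three is a package choice; the source architecture names the
convolution but not its depth.

**CYP450 panel encoder.** Each isoenzyme is one 480-dimensional embedding
of its amino-acid sequence, passed through Linear(480 → h) → LeakyReLU →
Dropout. The embeddings are an *injected input*: in production they come
from a protein language model (per-residue embeddings mean-pooled); this
package runs fully offline, so the panel is loaded from a precomputed
table, from a deterministic sequence-hash featurizer (a synthetic stand-in
with the right shape, not a learned embedding), or drawn seeded-random for
benchmarks. The 5×h output is computed once and reused for every pair.

**Compound–CYP interaction block.** n_ρ = 10 trainable pseudo-substructure
rows are appended after the compound's real substructure embeddings. One
multihead attention block follows the Set-Transformer layout with pre-set-
normalization: `MAB(x, y) = (x + z) + RFF(SetNorm(x + z))` with
`z = Multihead(SetNorm(x), SetNorm(y), SetNorm(y))` and
`RFF(x) = GeLU(GeLU(xW₁+b₁)W₂+b₂)`. Attention is additive with four
heads: per head i, score `e = vᵢᵀ tanh(W_q,i q + W_k,i k)` with per-head
projections of width h/4, row-softmax over keys, per-head value
projections concatenated and linearly mixed. Set normalization
standardizes jointly over set elements and features with a per-feature
affine; padded key positions are excluded from the statistics and carry
exactly zero attention. Head 0 is bound to substrate signals and head 1 to
inhibition; heads 2–3 are never supervised. The DCI score of compound c
for (type t, isoenzyme j) is the attention mass head t places on the
*real* columns of row j; score + pseudo-mass = 1 by construction.

**Fusion and prediction head.** The drug's pooled CYP embedding is fused
with the food's graph embedding by a vector outer product, flattened
row-major, and concatenated with the mirrored food–drug block (width 2h²).
The head is Linear(2h² → H₁) → BatchNorm → LeakyReLU → Dropout →
Linear(H₁ → 2h) → LeakyReLU → Dropout → Linear(2h → h) → BatchNorm →
LeakyReLU → Dropout → Linear(h → 1) → sigmoid. H₁ defaults to 4h: the
first hidden width is not recoverable from the source text (the printed
expression is typographically corrupt), and 4h gives a monotone taper
between 2h² and 2h where the literal readings are degenerate. Batch
normalization refuses training batches of size 1 (statistics undefined);
evaluation uses running statistics.

**Losses.** L₁ is mean binary cross-entropy on the pair labels. L₂ is
binary cross-entropy of the DCI scores against annotations, averaged as a
flat mean over all non-missing (compound, type, isoenzyme) cells in the
batch — unbiased under heterogeneous missingness; per-compound averaging
would up-weight sparsely annotated compounds. Scores are clipped to
[1e-7, 1 − 1e-7] because attention mass can be exactly 0 or 1. With no
labeled cell in a batch, L₂ is identically zero with zero gradient. Both
sides of a pair contribute if labeled (food annotations are supported by
the same code path even though shipped data leaves them missing). The
total is L = L₁ + α·L₂ with α = 5.

## Training defaults and units

| parameter | default | meaning |
|---|---|---|
| h | 128 | embedding width (dimensionless) |
| n_pseudo | 10 | pseudo-substructure rows |
| heads | 4 | attention heads (0 = substrate, 1 = inhibition) |
| dropout | 0.3 | rate, all dropout layers |
| α | 5 | auxiliary loss coefficient |
| batch_size | 1024 | pairs per optimization step |
| lr / weight decay | 1e-4 / 1e-4 | AdamW (β = 0.9/0.999) |
| max_epochs / patience | 100 / 10 | early stopping on validation loss |

Initialization: Xavier-uniform weight matrices, zero biases, N(0, 0.02)
for the substructure table, feature-vocabulary embeddings and pseudo rows
— fixed for reproducibility, as the source leaves initialization
unstated. Early stopping and checkpoint selection monitor the validation
value of the optimized objective L₁ + α·L₂ (for the α = 0 ablation this
reduces to the task term).

## Cold-split evaluation

Compounds on the cold side are clustered by sphere exclusion (Butina) on
Tanimoto distance between the same 1024-bit fingerprints the model uses,
at a default distance cutoff of 0.6 (the clustering algorithm is named by
the source; the cutoff is not). Clusters are assigned whole to partitions,
largest first (ties shuffled by seed), each to the partition with the
largest remaining deficit against target fractions 0.72/0.06/0.22; if a
partition ends empty while enough clusters exist, a smallest cluster is
moved into it. A leakage audit (zero cold-side compounds shared between
partitions) is part of the test suite. Metrics are AUROC, AUPRC, F1,
precision and recall, the last three at a fixed threshold of 0.5 (the
source does not state a threshold rule), aggregated over seeds as mean ±
sample (n−1) standard deviation.

## The synthetic benchmark

The generator emulates the *statistical shape* of the real task — sparse
semi-supervised CYP annotations on drugs, none on foods, pair labels
driven by shared-isoenzyme metabolism — without any claim to medicinal-
chemistry realism. Compounds are assembled from a fixed fragment grammar:
a carbon backbone interleaved (through single-carbon linkers) with 1–3
neutral filler fragments and, independently with probability 0.25 per
cell, one of ten chemically distinctive motif fragments (sulfonamide,
ester, pyridine, amide, gem-dichloride, phenol, thiophene, alkyne,
cyclohexane, acetal). Each of the ten (type, isoenzyme) annotation cells
is anchored to one fingerprint bit chosen, once and deterministically, as
the bit that best separates probe compounds containing the motif from
those lacking it. A compound's **true** label for a cell is defined as
presence of that anchor bit, so labels are exactly expressible in the
model's own substructure vocabulary and attention recovery is well-posed.
Observed drug labels hide each cell independently with probability 0.5;
food labels are fully hidden. The pair label is 1 iff some isoenzyme has
the drug as substrate and the food as substrate or inhibitor, flipped
independently with probability 0.05. Defaults: 80 drugs × 60 foods (the
full 4800-pair grid), cold-drug split.

What passing on this benchmark shows: that the implementation can learn
the planted bit→isoenzyme attention routing from partial supervision and
transfer it to structurally held-out drugs. What it does not show:
performance on real chemistry, where substructure–enzyme relations are
many-to-many, noisy, and not expressible as single fingerprint bits.

## Desk-scale experiment configuration

The recovery experiment (`cypdfi.benchmark`) runs the benchmark at
h = 32, batch 256, lr 5e-4, 60 epochs — the model and optimizer scaled
down together with the data (the reference configuration pairs h = 128
and batch 1024 with a ~450k-pair corpus; at 3.5k training pairs that batch
gives four updates per epoch, and the 300-pair validation partition is too
small for patience-style stopping or checkpoint selection to be reliable,
so the desk configuration trains its fixed epoch budget and keeps the
final-epoch parameters, identically in both arms). Three model seeds per
arm; the α = 0 ablation differs only in α. At this scale the attention
supervision reliably improves held-out-drug DCI recovery over the
ablation, while the two arms' pair-level DFI AUROCs are statistically
indistinguishable — the pair rule is learnable from the primary labels
alone here, unlike in the sparse real-data regime.

## Numerical choices and degenerate inputs

- All arithmetic is float64 on a tape-based numpy autodiff engine;
  gradients of every primitive are finite-difference tested.
- Softmax subtracts the row max; fully-masked rows raise.
- SetNorm variance floor ε = 1e-5; BatchNorm ε = 1e-5, momentum 0.1.
- Top-k substructure ties break by ascending bit index.
- Empty substructure sets, empty graphs, unparseable SMILES and
  zero-heavy-atom molecules raise featurization errors carrying the
  offending string; errors in pair tables carry the row number.
- Checkpoints (npz) store parameters, buffers, config, panel and the
  feature-vocabulary version; loading refuses a version mismatch.

## Known limitations

- The protein-language-model path is an injection point, not an internal
  dependency; shipped embeddings are synthetic stand-ins.
- Induction-type CYP interactions and isoenzymes beyond the panel of five
  are out of scope.
- ŷ is uncalibrated; F1/precision/recall at 0.5 are sensitive to class
  balance.
- The fingerprint's radius-2 resolution caps how much of a large
  substructure the attention can point to; the hash is not injective, so a
  bit can stand for more than one environment.
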