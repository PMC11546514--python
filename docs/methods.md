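# Methods

## Problem and model

A drug–drug interaction (DDI) dataset is a list of SMILES pairs with a
binary interaction label. `ddipair` models the probability of interaction
as

p(A, B) = σ( w · [ MLP(BiLSTM(A)) ; MLP(BiLSTM(B)) ] + b ),

where each drug's SMILES is tokenized to a fixed-length ID sequence,
embedded, and encoded by a bidirectional LSTM whose final forward and
backward hidden states are concatenated. Per-gate weights act on the
concatenation [x_t, h_{t−1}]; the memory cell follows
c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t and h_t = o_t ⊙ tanh(c_t). The MLP is
ReLU(W_h h + b_h) W_o + b_o with no activation after the output affine.

The model is deliberately minimal: no attention, no pretrained
transformer, no 2-D/3-D structure. Its distinguishing switch is the
branch layout. In **sharing** mode one set of embedding/BiLSTM/MLP
weights encodes both drugs (the two branch references point at the same
storage, so shared weights are counted once, updated once, and serialized
once); in **independent** mode each drug has its own branch. The
embedding table is included in the shared scope — a per-branch table
would dominate the parameter count and defeat the mode's purpose; a
config-level split remains possible by constructing the parameters
directly.

## Tokenizer

Pre-tokenization splits on lexical classes: bracket atoms `[...]`,
two-letter organic-subset atoms Cl/Br, aromatic `b c n o s p`,
single-letter atoms, bonds `- = # / \ : ~`, branches `( )`, ring digits
and `%nn`, and the dot disconnection. Only lexical validity is enforced
(balanced brackets/parentheses, known characters, with the offending
position reported); valence and aromaticity are out of scope.

BPE merges are learned greedily: the most frequent adjacent pair is
merged, ties broken by lexicographically smallest (left, right) so
training is deterministic, and pairs occurring fewer than twice are never
merged (frequency-based merging is meaningless below 2). Consequently the
first k merges of a (k+1)-merge vocabulary equal the k-merge vocabulary.
Special IDs are pinned (PAD=0, BOS=1, EOS=2, UNK=3) for stable
serialization. Truncation keeps the first max_len−2 content tokens and
forces a terminal EOS so the backward recurrence still starts at a
sequence-end marker. Externally supplied vocabularies are accepted either
as the package's bundled JSON or as the common token→ID JSON plus
`merges.txt` pair.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| embed_dim | 512 | token embedding width (encoder input layer) |
| lstm_hidden | 128 | per-direction hidden size; concatenated state 256 |
| mlp_hidden / mlp_out | 128 / 4 | MLP widths; predictor input is 2·mlp_out = 8 |
| max_len | 512 | fixed token-sequence length |
| learning_rate | 2e-5 | AdamW step size (benchmark profile) |
| weight_decay | 2e-4 | decoupled decay; 1e-2 is the larger-benchmark profile |
| batch_size / epochs | 8 / 30 | benchmark profile |
| scheduler γ / step | 0.8 / 10 | lr = base·γ^⌊epoch/step⌋, stepped per epoch |
| n_runs | 3 | replicate seeds (seed, seed+1, …), reported mean ± sample std |

The published hidden-layer width of 256 for the bidirectional encoder is
read as 128 per direction, the only reading that makes the encoder
output, the MLP input (256) and the predictor input (8) mutually
consistent. Token IDs feed a learned embedding because an integer ID
cannot enter a continuous recurrence; its width matches the encoder's
input layer (512). Final-state pooling (last forward state, last backward
state, masked to real tokens) feeds the MLP. Drug A's feature vector
always occupies the first predictor slot — the output is not symmetrized,
so any learned asymmetry is measurable rather than hidden.

Initialization is uniform ±1/√fan_in per weight matrix with zero biases,
drawn from a seeded generator (branch A before branch B in independent
mode). Checkpoint selection uses best validation ROC-AUC, the lead
metric. Probabilities are clamped to [1e-7, 1−1e-7] before logs; the BCE
rescaling weight is 1 (the datasets are balanced). AdamW uses β₁ = 0.9,
β₂ = 0.999, ε = 1e-8, with decay applied to all parameter tensors.

## Numerical implementation

Forward pass, BPTT and AdamW are written directly on float64 numpy
arrays. The recurrence is batched with a mask-carry update
(h ← m·h_new + (1−m)·h), so PAD positions never affect either direction
and appending padding is bit-neutral; per-batch, trailing all-PAD columns
are trimmed, which is a pure speed optimization under that invariance.
The four gates are evaluated as one stacked matmul per time step.
Gradients are validated against central finite differences at eps = 1e-4
(worst relative error ~1e-5 on toy configs; smaller eps makes the
difference quotient itself noisier than the gradient on entries of
magnitude ~1e-8).

Metrics are computed from explicit threshold sweeps: tied scores are
grouped, the ROC curve gains (0,0)/(1,1) sentinels and its trapezoidal
area equals the Mann–Whitney concordance probability with ties counted ½
(property-tested against exhaustive enumeration). The PR curve is
anchored at (recall 0, precision 1) and integrated by trapezoid over
recall — not average precision; the two differ on coarse score sets.
Classification at a threshold is strictly greater-than, so a score of
exactly 0.5 is a non-interaction call. Degenerate 0/0 precision, recall
and F1 are defined as 0. Reported percentages round half-up at the
printed precision. The train/valid/test split draws round(N·0.2) test
rows, then round(remaining·0.2) validation rows, with half-up rounding.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical shape of the public DDI
benchmarks: two SMILES columns, exactly balanced classes, and a label
that depends on the substructure content of both molecules. Molecules
are 3–12 fragments drawn uniformly from a 10-fragment alphabet and
concatenated; pairs are rejection-sampled (bounded at 10⁶ attempts) to
exact balance, then each label flips independently with probability
ε = 0.05 to emulate annotation error. Clean labels are retained
internally so tests can re-derive the rule with an independent substring
search — with this alphabet no fragment boundary can spell a motif by
accident, so substring presence coincides with fragment presence.

The planted rule is symmetric in (A, B), matching the unordered nature of
DDI labels. Its default is "both molecules contain `c1ccccc1`". The
choice of *equal* motif sets on the two sides is deliberate: the
predictor is a single affine map over the concatenated branch features,
hence an additive function u(A) + v(B), and equal-motif conjunction is
exactly the symmetric rule an additive scorer can order correctly
(u₁+u₁ > u₁+u₀ > u₀+u₀). A cross rule — motif X in one drug AND motif Y
in the other, symmetrized — is *not* additively separable; measured on
this generator it caps ROC-AUC near 0.91 under 5% label noise no matter
how well the encoder trains. That configuration remains available
(`motif_a=("c1ccccc1",), motif_b=("C(=O)O",)`) as a probe of the
architecture's expressiveness ceiling rather than of its training.

What passing on synthetic data does **not** show: the molecules are
fragment concatenations, not valence-correct chemistry; the label
mechanism is lexical, not pharmacokinetic (dose is ignored); and the
negative-pair distribution is the generator's rejection sampler, not the
benchmarks' (undocumented) negative construction. Results on this task
therefore validate the pipeline's mechanics and learning dynamics, not
real-world DDI accuracy.

## Desk-scale study sizes

The scaled workflow uses 2,000 pairs (1,280/320/400 after the 80/20 and
8:2 splits), a 32-merge vocabulary, a reduced encoder (embedding 32,
per-direction hidden 16, MLP 32→4), batch size 8 and 15 epochs at
lr 1e-3 under the same γ = 0.8 / step-10 schedule. One run takes roughly
ten seconds on one CPU; the acceptance script's five seeds plus a
no-signal control (ε = 0.5, expecting chance-level AUC) finish in about a
minute. The 32-merge count keeps frequent fragments as single tokens
without over-merging across fragment boundaries, which would smear one
motif over many surface forms.

## Fingerprints

Tanimoto similarity |A∩B|/|A∪B| (empty∩empty defined 0) is computed over
bit sets from either a built-in hashed n-gram fingerprint — all 1–4-grams
of the atom-level token stream hashed by md5 onto 2048 positions,
salt-free and hence stable across processes — or RDKit Morgan/ECFP bit
sets when the chemistry toolkit is installed. The n-gram fingerprint is a
purely lexical descriptor and makes no claim of matching circular
fingerprints' similarity values.

## Known limitations

- Full-scale benchmark training (hundreds of thousands of pairs, 512-wide
  embeddings, 30 epochs) is supported by the same code paths but is a
  multi-hour CPU job; the shipped workflows run the reduced profile.
- The predictor's additivity bounds which pair rules are representable
  (see the synthetic-data section); richer interactions would need a
  bilinear or MLP head, which is outside this architecture.
- The tokenizer checks lexical structure only; chemically invalid SMILES
  that are lexically well-formed are encoded without complaint.
- Checkpoints store float64 tensors; there is no quantized or streaming
  inference path.
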