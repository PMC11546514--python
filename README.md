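# ddipair

Binary drug–drug interaction (DDI) prediction from SMILES strings alone.
Given a pair of molecules written as 1-D SMILES, `ddipair` estimates the
probability that the two drugs interact — the screening task behind DDI
benchmark datasets such as BIOSNAP and DrugBank, where each row is
`(SMILES_A, SMILES_B, label ∈ {0,1})` with balanced classes.

The package is aimed at cheminformatics practitioners who want a small,
fully inspectable sequence model for pair classification: every stage —
tokenizer, recurrent encoder, backpropagation, optimizer, metrics — is
implemented in plain numpy and covered by oracle tests, so it doubles as a
reference implementation.

## Model

1. **Tokenizer.** SMILES are segmented into atom-level symbols (bracket
   atoms `[...]`, two-letter halogens, aromatic atoms, bonds, ring digits,
   branches), then a byte-pair encoder (BPE) greedily merges the most
   frequent adjacent symbol pair so functional groups become single tokens.
   Sequences are wrapped in BOS/EOS and padded to a fixed length with an
   attention mask. A pretrained vocabulary (`vocab.json` + `merges.txt`)
   can be loaded instead of training one.
2. **BiLSTM encoder.** Each embedded token sequence is run through a
   forward and a backward LSTM over real (non-PAD) positions:

   f_t = σ(w_f·[x_t, h_{t−1}] + b_f),  i_t, o_t analogous,
   c̃_t = tanh(w_c·[x_t, h_{t−1}] + b_c),
   c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t,  h_t = o_t ⊙ tanh(c_t),

   and the final states are concatenated: h = [h→; h←] (2×128 = 256 by
   default).
3. **MLP.** O = ReLU(W_h h + b_h) W_o + b_o per drug (256 → 128 → 4).
4. **Predictor.** p = σ(w·[O_A; O_B] + b), the interaction probability;
   a pair is called an interaction when p > 0.5 (strict).

Two branch layouts: **parameter-sharing** (one siamese encoder serves both
drugs) and **parameter-independent** (each drug has its own encoder).
Training uses binary cross-entropy, AdamW (decoupled weight decay) and a
step learning-rate schedule (γ = 0.8 every 10 epochs); the checkpoint with
the best validation ROC-AUC is kept and results are aggregated over
replicate seeds as mean ± sample std.

The evaluation suite implements confusion counts and row-normalized rates,
precision/recall/F1, ROC and precision–recall curves with trapezoidal
areas (ROC-AUC equals the Mann–Whitney concordance, ties counted ½),
relative-improvement arithmetic and Tanimoto fingerprint similarity.

Because full benchmark training is expensive, the package ships a
synthetic generator that emulates the benchmarks' shape: balanced pairs of
fragment-concatenated molecules with a planted substructure rule (by
default, "both molecules carry an aromatic ring") plus label noise, so the
whole pipeline is exercisable in minutes with no downloads.

## Worked example

Library pipeline — simulate 2,000 pairs, learn a 32-merge BPE vocabulary,
train the reduced encoder for 15 epochs, evaluate on the held-out 20%:

```python
from ddipair import workflows
r = workflows.scaled_learning_run(seed=1)
print(f"held-out AUC-ROC {r.auc_roc:.3f}  PR-AUC {r.pr_auc:.3f}  F1 {r.f1:.3f}")
```

```
held-out AUC-ROC 0.965  PR-AUC 0.966  F1 0.867  (test pairs: 400, best epoch 1)
```

With 5% label noise the best reachable AUC is well below 1.0 even for a
perfect rule detector; 0.96 here means the planted rule was recovered
almost exactly (scoring against the noise-free labels gives 1.0).

The same workflow from the shell:

```sh
ddipair simulate --n-pairs 400 --seed 5 --out data.csv
ddipair train --data data.csv --out run --embed-dim 32 --hidden 16 \
    --mlp-hidden 32 --mlp-out 4 --max-len 80 --epochs 3 --batch-size 8 \
    --lr 1e-3 --seed 5
ddipair predict --checkpoint run/checkpoint.npz --pairs pairs.csv --out pred.csv
cat pred.csv
```

```
smiles_a,smiles_b,probability,call
c1ccccc1CC,Cc1ccccc1,0.491,0
CCO,NCC,0.488,0
```

Each prediction row carries the interaction probability (3 decimals) and
the thresholded call at 0.5. `ddipair evaluate` scores a checkpoint on a
labeled file and writes the full metric report; every command writes a
JSON manifest (config, seeds, input hashes) from which the run reproduces
bit-identically.

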