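"""Dual-mode BiLSTM pair encoder for drug-drug interaction prediction.

Each drug's token-ID sequence is embedded, encoded by a bidirectional LSTM
(final forward state concatenated with final backward state), and passed
through a two-layer MLP with ReLU.  The two drug feature vectors are
concatenated and a single affine + sigmoid layer produces the interaction
probability.

Two branch layouts are supported:

* ``sharing`` — both drugs are encoded by one set of branch weights (a
  siamese encoder); branch A and branch B are literally the same objects.
* ``independent`` — each drug has its own embedding/BiLSTM/MLP weights.

The forward pass, backpropagation (BPTT through the masked recurrences) and
parameter initialization are implemented directly on numpy arrays; the
gradient path is validated against finite differences in the test suite.

All recurrences respect the attention mask: PAD positions never enter
either LSTM direction, so appending padding leaves outputs bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .tokenizer import TokenSequence

__all__ = [
    "ModelConfig",
    "LSTMParams",
    "MLPParams",
    "BranchParams",
    "ModelParameters",
    "init_parameters",
    "lstm_cell_step",
    "bilstm_encode",
    "mlp_forward",
    "predict_pair",
    "predict_batch",
    "count_parameters",
    "forward_pairs",
    "backward_pairs",
    "batchify",
]

GATES = ("f", "i", "o", "c")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``embed_dim`` is the input-layer width of the recurrent encoder;
    ``lstm_hidden`` is the per-direction hidden size, so the concatenated
    bidirectional state (and hence the MLP input) has width
    ``2 * lstm_hidden``.  The predictor consumes the concatenation of the
    two ``mlp_out``-dimensional drug features.
    """

    vocab_size: int
    embed_dim: int = 512
    lstm_hidden: int = 128
    mlp_hidden: int = 128
    mlp_out: int = 4
    mode: Literal["sharing", "independent"] = "sharing"
    max_len: int = 512

    def __post_init__(self) -> None:
        for name in ("vocab_size", "embed_dim", "lstm_hidden", "mlp_hidden", "mlp_out", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("sharing", "independent"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def bilstm_out(self) -> int:
        return 2 * self.lstm_hidden

    @property
    def predictor_in(self) -> int:
        return 2 * self.mlp_out


@dataclass
class LSTMParams:
    """One direction's gate weights; each w_g acts on [x_t, h_{t-1}]."""

    w_f: np.ndarray
    w_i: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        h, zin = self.w_f.shape
        for g in GATES:
            if getattr(self, f"w_{g}").shape != (h, zin):
                raise ValueError("gate weight shapes disagree")
            if getattr(self, f"b_{g}").shape != (h,):
                raise ValueError("gate bias shapes disagree")

    @property
    def hidden(self) -> int:
        return self.w_f.shape[0]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Gate weights stacked (f, i, o, c) for one-matmul recurrence steps."""
        W = np.concatenate([self.w_f, self.w_i, self.w_o, self.w_c], axis=0)
        b = np.concatenate([self.b_f, self.b_i, self.b_o, self.b_c])
        return W, b


@dataclass
class MLPParams:
    """Two affine layers; ReLU between them, none after the output layer."""

    W_h: np.ndarray
    b_h: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray


@dataclass
class BranchParams:
    """Everything one drug passes through before the predictor."""

    embedding: np.ndarray  # (vocab_size, embed_dim)
    fwd: LSTMParams
    bwd: LSTMParams
    mlp: MLPParams


@dataclass
class ModelParameters:
    """All trainable weights.

    In sharing mode ``branch_a is branch_b`` — one storage referenced
    twice, so shared weights are counted, updated and serialized once.
    """

    config: ModelConfig
    branch_a: BranchParams
    branch_b: BranchParams
    pred_w: np.ndarray  # (2 * mlp_out,)
    pred_b: np.ndarray  # scalar, shape ()

    @property
    def shared(self) -> bool:
        return self.branch_a is self.branch_b

    def named_arrays(self) -> list[tuple[str, np.ndarray]]:
        """Unique (name, array) pairs; shared storage appears once."""
        out: list[tuple[str, np.ndarray]] = []
        branches = [("a", self.branch_a)]
        if not self.shared:
            branches.append(("b", self.branch_b))
        for tag, br in branches:
            out.append((f"{tag}.embedding", br.embedding))
            for dname, d in (("fwd", br.fwd), ("bwd", br.bwd)):
                for g in GATES:
                    out.append((f"{tag}.{dname}.w_{g}", getattr(d, f"w_{g}")))
                    out.append((f"{tag}.{dname}.b_{g}", getattr(d, f"b_{g}")))
            out.append((f"{tag}.mlp.W_h", br.mlp.W_h))
            out.append((f"{tag}.mlp.b_h", br.mlp.b_h))
            out.append((f"{tag}.mlp.W_o", br.mlp.W_o))
            out.append((f"{tag}.mlp.b_o", br.mlp.b_o))
        out.append(("pred.w", self.pred_w))
        out.append(("pred.b", self.pred_b))
        return out

    def copy(self) -> "ModelParameters":
        a = _copy_branch(self.branch_a)
        b = a if self.shared else _copy_branch(self.branch_b)
        return ModelParameters(self.config, a, b, self.pred_w.copy(), self.pred_b.copy())


def _copy_branch(br: BranchParams) -> BranchParams:
    return BranchParams(
        embedding=br.embedding.copy(),
        fwd=replace(br.fwd, **{k: getattr(br.fwd, k).copy() for k in
                               [f"w_{g}" for g in GATES] + [f"b_{g}" for g in GATES]}),
        bwd=replace(br.bwd, **{k: getattr(br.bwd, k).copy() for k in
                               [f"w_{g}" for g in GATES] + [f"b_{g}" for g in GATES]}),
        mlp=MLPParams(br.mlp.W_h.copy(), br.mlp.b_h.copy(), br.mlp.W_o.copy(), br.mlp.b_o.copy()),
    )


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _init_branch(cfg: ModelConfig, rng: np.random.Generator) -> BranchParams:
    D, H = cfg.embed_dim, cfg.lstm_hidden
    def lstm() -> LSTMParams:
        kw = {}
        for g in GATES:
            kw[f"w_{g}"] = _uniform(rng, (H, D + H), D + H)
            kw[f"b_{g}"] = np.zeros(H)
        return LSTMParams(**kw)
    return BranchParams(
        embedding=_uniform(rng, (cfg.vocab_size, D), D),
        fwd=lstm(),
        bwd=lstm(),
        mlp=MLPParams(
            W_h=_uniform(rng, (cfg.mlp_hidden, 2 * H), 2 * H),
            b_h=np.zeros(cfg.mlp_hidden),
            W_o=_uniform(rng, (cfg.mlp_out, cfg.mlp_hidden), cfg.mlp_hidden),
            b_o=np.zeros(cfg.mlp_out),
        ),
    )


def init_parameters(cfg: ModelConfig, seed: int | np.random.Generator = 0) -> ModelParameters:
    """Seeded initialization: uniform ±1/√fan_in weights, zero biases.

    In sharing mode one branch is drawn and referenced twice; in
    independent mode branch B is drawn after branch A from the same
    generator stream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    branch_a = _init_branch(cfg, rng)
    branch_b = branch_a if cfg.mode == "sharing" else _init_branch(cfg, rng)
    return ModelParameters(
        config=cfg,
        branch_a=branch_a,
        branch_b=branch_b,
        pred_w=_uniform(rng, (2 * cfg.mlp_out,), 2 * cfg.mlp_out),
        pred_b=np.zeros(()),
    )


# ---------------------------------------------------------------------------
# forward operations (also exposed singly for oracle tests)
# ---------------------------------------------------------------------------

def lstm_cell_step(
    x_t: np.ndarray, prev: tuple[np.ndarray, np.ndarray], params: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update.

    Gates are logistic-sigmoid affine maps of ``[x_t, h_{t-1}]`` and the
    candidate cell is tanh of the same concatenation::

        f, i, o = σ(w_g·[x, h] + b_g)      c̃ = tanh(w_c·[x, h] + b_c)
        c' = f ⊙ c + i ⊙ c̃                h' = o ⊙ tanh(c')

    Returns the new ``(h, c)`` state.
    """
    h_prev, c_prev = prev
    z = np.concatenate([np.asarray(x_t, dtype=float), np.asarray(h_prev, dtype=float)])
    if z.shape[0] != params.w_f.shape[1]:
        raise ValueError(
            f"dimension mismatch: got [x,h] of size {z.shape[0]}, "
            f"gate weights expect {params.w_f.shape[1]}"
        )
    f = sigmoid(params.w_f @ z + params.b_f)
    i = sigmoid(params.w_i @ z + params.b_i)
    o = sigmoid(params.w_o @ z + params.b_o)
    c_tilde = np.tanh(params.w_c @ z + params.b_c)
    c = f * np.asarray(c_prev, dtype=float) + i * c_tilde
    h = o * np.tanh(c)
    return h, c


def _lstm_scan(
    X: np.ndarray, mask: np.ndarray, params: LSTMParams, reverse: bool
) -> tuple[np.ndarray, list]:
    """Masked batched recurrence over time; returns final h and step cache.

    Masked (PAD) steps carry the previous state through unchanged, so with
    trailing padding the final state is the state after the last real token
    (forward) or after the first token (backward scan).
    """
    B, L, D = X.shape
    H = params.hidden
    W, b = params.stacked()
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    order = range(L - 1, -1, -1) if reverse else range(L)
    for t in order:
        z = np.concatenate([X[:, t, :], h], axis=1)  # (B, D+H)
        A = z @ W.T + b
        f = sigmoid(A[:, 0 * H:1 * H])
        i = sigmoid(A[:, 1 * H:2 * H])
        o = sigmoid(A[:, 2 * H:3 * H])
        cb = np.tanh(A[:, 3 * H:4 * H])
        c_new = f * c + i * cb
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        m = mask[:, t:t + 1]
        cache.append((t, z, f, i, o, cb, c.copy(), tanh_c, m))
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
    return h, cache


def _lstm_scan_backward(
    cache: list, params: LSTMParams, dh_final: np.ndarray, dX: np.ndarray
) -> dict[str, np.ndarray]:
    """BPTT through one masked scan; accumulates into dX, returns gate grads."""
    H = params.hidden
    D = dX.shape[2]
    W, _ = params.stacked()
    dW = np.zeros_like(W)
    db = np.zeros(4 * H)
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for (t, z, f, i, o, cb, c_prev, tanh_c, m) in reversed(cache):
        dh_new = dh * m
        dh_carry = dh * (1.0 - m)
        dc_carry = dc * (1.0 - m)
        do = dh_new * tanh_c
        dc_new = dc * m + dh_new * o * (1.0 - tanh_c ** 2)
        df = dc_new * c_prev
        di = dc_new * cb
        dcb = dc_new * i
        dc = dc_new * f + dc_carry
        dA = np.concatenate(
            [df * f * (1 - f), di * i * (1 - i), do * o * (1 - o), dcb * (1 - cb ** 2)],
            axis=1,
        )
        dW += dA.T @ z
        db += dA.sum(axis=0)
        dz = dA @ W
        dX[:, t, :] += dz[:, :D]
        dh = dz[:, D:] + dh_carry
    grads = {}
    for k, g in enumerate(GATES):
        grads[f"w_{g}"] = dW[k * H:(k + 1) * H]
        grads[f"b_{g}"] = db[k * H:(k + 1) * H]
    return grads


def batchify(seqs: Sequence[TokenSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack token sequences into (ids, mask) arrays, trimming columns that
    are padding in every row (masking invariance makes this a no-op on the
    outputs)."""
    ids = np.asarray([s.ids for s in seqs], dtype=np.int64)
    mask = np.asarray([s.mask for s in seqs], dtype=float)
    n = int(mask.sum(axis=1).max()) if len(seqs) else 0
    if n == 0:
        raise ValueError("all sequences are empty/all-PAD")
    return ids[:, :n], mask[:, :n]


def _branch_forward(br: BranchParams, ids: np.ndarray, mask: np.ndarray):
    if ids.max() >= br.embedding.shape[0] or ids.min() < 0:
        raise ValueError("token ID out of range for embedding table")
    X = br.embedding[ids]  # (B, L, D)
    hf, cache_f = _lstm_scan(X, mask, br.fwd, reverse=False)
    hb, cache_b = _lstm_scan(X, mask, br.bwd, reverse=True)
    hcat = np.concatenate([hf, hb], axis=1)  # (B, 2H)
    pre = hcat @ br.mlp.W_h.T + br.mlp.b_h
    Hh = np.maximum(pre, 0.0)
    O = Hh @ br.mlp.W_o.T + br.mlp.b_o
    cache = {"ids": ids, "mask": mask, "X": X, "cache_f": cache_f, "cache_b": cache_b,
             "hcat": hcat, "pre": pre, "Hh": Hh}
    return O, cache


def _branch_backward(br: BranchParams, cache: dict, dO: np.ndarray, out: dict, tag: str) -> None:
    Hh, pre, hcat = cache["Hh"], cache["pre"], cache["hcat"]
    out[f"{tag}.mlp.W_o"] += dO.T @ Hh
    out[f"{tag}.mlp.b_o"] += dO.sum(axis=0)
    dHh = dO @ br.mlp.W_o
    dpre = dHh * (pre > 0)
    out[f"{tag}.mlp.W_h"] += dpre.T @ hcat
    out[f"{tag}.mlp.b_h"] += dpre.sum(axis=0)
    dhcat = dpre @ br.mlp.W_h
    H = br.fwd.hidden
    dX = np.zeros_like(cache["X"])
    gf = _lstm_scan_backward(cache["cache_f"], br.fwd, dhcat[:, :H], dX)
    gb = _lstm_scan_backward(cache["cache_b"], br.bwd, dhcat[:, H:], dX)
    for g in GATES:
        out[f"{tag}.fwd.w_{g}"] += gf[f"w_{g}"]
        out[f"{tag}.fwd.b_{g}"] += gf[f"b_{g}"]
        out[f"{tag}.bwd.w_{g}"] += gb[f"w_{g}"]
        out[f"{tag}.bwd.b_{g}"] += gb[f"b_{g}"]
    flat_ids = cache["ids"].reshape(-1)
    np.add.at(out[f"{tag}.embedding"], flat_ids, dX.reshape(-1, dX.shape[2]))


def forward_pairs(
    params: ModelParameters,
    ids_a: np.ndarray, mask_a: np.ndarray,
    ids_b: np.ndarray, mask_b: np.ndarray,
):
    """Batched pair forward pass: returns probabilities (B,) and a cache."""
    OA, cache_a = _branch_forward(params.branch_a, ids_a, mask_a)
    OB, cache_b = _branch_forward(params.branch_b, ids_b, mask_b)
    u = np.concatenate([OA, OB], axis=1)  # (B, 2*mlp_out)
    logit = u @ params.pred_w + params.pred_b
    p = sigmoid(logit)
    return p, {"cache_a": cache_a, "cache_b": cache_b, "u": u}


def backward_pairs(params: ModelParameters, cache: dict, dlogit: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss given d(loss)/d(logit) per pair.

    In sharing mode contributions from the A-pass and B-pass accumulate
    into the single shared branch's arrays (tag ``a``).
    """
    grads = {name: np.zeros_like(arr) for name, arr in params.named_arrays()}
    u = cache["u"]
    grads["pred.w"] += u.T @ dlogit
    grads["pred.b"] += np.asarray(dlogit.sum())
    du = np.outer(dlogit, params.pred_w)
    K = params.config.mlp_out
    tag_b = "a" if params.shared else "b"
    _branch_backward(params.branch_a, cache["cache_a"], du[:, :K], grads, "a")
    _branch_backward(params.branch_b, cache["cache_b"], du[:, K:], grads, tag_b)
    return grads


def bilstm_encode(
    seq: TokenSequence, embedding: np.ndarray, fwd: LSTMParams, bwd: LSTMParams
) -> np.ndarray:
    """Encode one sequence: concat(final forward state, final backward state)."""
    if seq.n_real == 0:
        raise ValueError("sequence has no real tokens")
    ids, mask = batchify([seq])
    X = embedding[ids]
    hf, _ = _lstm_scan(X, mask, fwd, reverse=False)
    hb, _ = _lstm_scan(X, mask, bwd, reverse=True)
    return np.concatenate([hf[0], hb[0]])


def mlp_forward(h: np.ndarray, params: MLPParams) -> np.ndarray:
    """O = ReLU(W_h h + b_h) W_oᵀ + b_o — no activation after the output affine."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.W_h.shape[1]:
        raise ValueError(
            f"dimension mismatch: input {h.shape[-1]}, W_h expects {params.W_h.shape[1]}"
        )
    return np.maximum(h @ params.W_h.T + params.b_h, 0.0) @ params.W_o.T + params.b_o


def predict_pair(seq_a: TokenSequence, seq_b: TokenSequence, params: ModelParameters) -> float:
    """Interaction probability for one SMILES pair, strictly inside (0, 1)."""
    return float(predict_batch([(seq_a, seq_b)], params)[0])


def predict_batch(
    pairs: Sequence[tuple[TokenSequence, TokenSequence]], params: ModelParameters
) -> np.ndarray:
    """Interaction probabilities for a batch of pairs."""
    ids_a, mask_a = batchify([a for a, _ in pairs])
    ids_b, mask_b = batchify([b for _, b in pairs])
    p, _ = forward_pairs(params, ids_a, mask_a, ids_b, mask_b)
    return p


def count_parameters(cfg: ModelConfig) -> dict[str, int]:
    """Closed-form trainable parameter counts; shared storage counted once."""
    D, H = cfg.embed_dim, cfg.lstm_hidden
    per_direction = 4 * (H * (D + H) + H)
    mlp = (2 * H * cfg.mlp_hidden + cfg.mlp_hidden) + (cfg.mlp_hidden * cfg.mlp_out + cfg.mlp_out)
    branch = cfg.vocab_size * D + 2 * per_direction + mlp
    encoder = branch if cfg.mode == "sharing" else 2 * branch
    predictor = 2 * cfg.mlp_out + 1
    return {"encoder_params": encoder, "predictor_params": predictor,
            "total": encoder + predictor}
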