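"""File I/O: dataset CSV reading/writing, checkpoints, run manifests.

Dataset files are UTF-8 comma-separated text with a header —
``smiles_a,smiles_b,label`` when labeled, ``smiles_a,smiles_b`` otherwise.
Prediction files add ``probability`` (3 decimals) and the thresholded
``call`` column.  Checkpoints are numpy archives with the model config
embedded; manifests are JSON snapshots sufficient to re-execute a run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    GATES,
    BranchParams,
    LSTMParams,
    MLPParams,
    ModelConfig,
    ModelParameters,
)
from .synthetic import LabeledPairDataset
from .tokenizer import SmilesSyntaxError, pretokenize

__all__ = [
    "read_pairs",
    "write_pairs",
    "write_predictions",
    "save_checkpoint",
    "load_checkpoint",
    "file_sha256",
    "write_manifest",
]


def read_pairs(path: str | Path, labeled: bool = True):
    """Read a SMILES-pair CSV.

    Labeled mode returns a :class:`LabeledPairDataset` and requires a 0/1
    ``label`` column; unlabeled mode returns a list of (smiles_a, smiles_b)
    tuples.  Every SMILES is validated lexically; all rejected rows are
    reported together with their 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["smiles_a", "smiles_b"] + (["label"] if labeled else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    errors: list[str] = []
    labels = np.zeros(len(df), dtype=int)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        for col in ("smiles_a", "smiles_b"):
            try:
                pretokenize(getattr(row, col))
            except SmilesSyntaxError as exc:
                errors.append(f"row {i}: invalid {col}: {exc}")
        if labeled:
            raw = getattr(row, "label").strip()
            if raw not in ("0", "1"):
                errors.append(f"row {i}: label must be 0 or 1, got {raw!r}")
            else:
                labels[i - 1] = int(raw)
    if errors:
        raise ValueError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    if labeled:
        return LabeledPairDataset(
            smiles_a=df["smiles_a"].tolist(),
            smiles_b=df["smiles_b"].tolist(),
            labels=labels,
        )
    return list(zip(df["smiles_a"].tolist(), df["smiles_b"].tolist()))


def write_pairs(dataset: LabeledPairDataset, path: str | Path) -> None:
    """Write a labeled dataset as ``smiles_a,smiles_b,label`` CSV."""
    df = pd.DataFrame(
        {"smiles_a": dataset.smiles_a, "smiles_b": dataset.smiles_b, "label": dataset.labels}
    )
    df.to_csv(path, index=False)


def write_predictions(
    pairs: list[tuple[str, str]],
    probabilities: np.ndarray,
    path: str | Path,
    threshold: float = 0.5,
) -> None:
    """Write predictions with probabilities at 3 decimals and the call at
    the strict > threshold rule (1 = interaction)."""
    rows = [
        {
            "smiles_a": a,
            "smiles_b": b,
            "probability": f"{p:.3f}",
            "call": int(p > threshold),
        }
        for (a, b), p in zip(pairs, probabilities)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_checkpoint(params: ModelParameters, path: str | Path) -> None:
    """Serialize parameters + config to a numpy archive."""
    arrays = {name: arr for name, arr in params.named_arrays()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(params.config)).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def _branch_from(arrays: dict[str, np.ndarray], tag: str) -> BranchParams:
    def lstm(dname: str) -> LSTMParams:
        kw = {}
        for g in GATES:
            kw[f"w_{g}"] = arrays[f"{tag}.{dname}.w_{g}"]
            kw[f"b_{g}"] = arrays[f"{tag}.{dname}.b_{g}"]
        return LSTMParams(**kw)

    return BranchParams(
        embedding=arrays[f"{tag}.embedding"],
        fwd=lstm("fwd"),
        bwd=lstm("bwd"),
        mlp=MLPParams(
            W_h=arrays[f"{tag}.mlp.W_h"],
            b_h=arrays[f"{tag}.mlp.b_h"],
            W_o=arrays[f"{tag}.mlp.W_o"],
            b_o=arrays[f"{tag}.mlp.b_o"],
        ),
    )


def load_checkpoint(path: str | Path) -> ModelParameters:
    """Load a checkpoint and validate array shapes against its config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    cfg = ModelConfig(**json.loads(bytes(arrays.pop("__config__")).decode("utf-8")))
    branch_a = _branch_from(arrays, "a")
    branch_b = branch_a if cfg.mode == "sharing" else _branch_from(arrays, "b")
    params = ModelParameters(
        config=cfg,
        branch_a=branch_a,
        branch_b=branch_b,
        pred_w=arrays["pred.w"],
        pred_b=arrays["pred.b"],
    )
    D, H = cfg.embed_dim, cfg.lstm_hidden
    if branch_a.embedding.shape != (cfg.vocab_size, D):
        raise ValueError("checkpoint embedding shape disagrees with config")
    if branch_a.fwd.w_f.shape != (H, D + H):
        raise ValueError("checkpoint LSTM shape disagrees with config")
    if params.pred_w.shape != (2 * cfg.mlp_out,):
        raise ValueError("checkpoint predictor shape disagrees with config")
    return params


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, payload: dict) -> None:
    """Write a run manifest: config snapshot, seeds, input hashes, outputs."""
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
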