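"""Binary-classifier evaluation: confusion analytics, ROC/PR curves, AUCs,
relative-improvement arithmetic and Tanimoto fingerprint similarity.

All metrics are computed from first principles so their conventions are
explicit and testable:

* classification at a threshold is *strictly greater than* (a score equal
  to the threshold is called negative);
* ROC-AUC is a trapezoid over the full threshold sweep with tied scores
  grouped, which makes it exactly the Mann-Whitney concordance probability
  with ties counted one half;
* PR-AUC is a trapezoid over recall on the same sweep (not average
  precision), anchored at (recall 0, precision 1);
* degenerate 0/0 precision/recall/F1 cases are defined as 0;
* reported percentages round half-up to the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import hashlib

import numpy as np

from .tokenizer import pretokenize

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "precision_recall_f1",
    "fpr",
    "roc_auc",
    "pr_auc",
    "normalize_confusion",
    "relative_improvement",
    "round_half_up",
    "tanimoto",
    "ngram_fingerprint",
    "morgan_fingerprint",
    "evaluate",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed-report conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a thresholded binary classification."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int)


def confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; predicted positive iff score > threshold (strict)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        threshold=threshold,
    )


def precision_recall_f1(cc: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 cases are 0."""
    p = cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp else 0.0
    r = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def fpr(cc: ConfusionCounts) -> float:
    """False-positive rate FP/(FP+TN)."""
    if cc.fp + cc.tn == 0:
        raise ValueError("FPR undefined: no true negatives or false positives")
    return cc.fp / (cc.fp + cc.tn)


def _sweep(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP after each distinct-score group, descending."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tied group
    boundaries = np.nonzero(np.diff(s))[0]
    idx = np.r_[boundaries, len(s) - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(1 - y)[idx]
    return tps.astype(float), fps.astype(float)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC curve and area.

    Sweeps the threshold over all distinct scores (tied scores grouped),
    prepends the (0, 0) sentinel, and integrates TPR over FPR with the
    trapezoid rule; this equals the probability that a random positive
    outscores a random negative, ties counted half.

    Returns ``(points, auc)`` with points as an (k, 2) array of (FPR, TPR)
    from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes present")
    tps, fps = _sweep(scores, labels)
    tpr = np.r_[0.0, tps / n_pos]
    fpr_ = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr_))
    return np.column_stack([fpr_, tpr]), auc


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """Precision-recall curve and trapezoidal area over recall.

    The curve is anchored at (recall 0, precision 1); points at equal
    recall contribute zero area.  Returns ``(points, auc)`` with points as
    an (k, 2) array of (recall, precision).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC requires at least one positive")
    tps, fps = _sweep(scores, labels)
    recall = np.r_[0.0, tps / n_pos]
    precision = np.r_[1.0, tps / (tps + fps)]
    auc = float(np.trapezoid(precision, recall))
    return np.column_stack([recall, precision]), auc


def normalize_confusion(cc: ConfusionCounts) -> dict[str, float]:
    """Row-normalized confusion rates {TPR, FNR, FPR, TNR}; rows sum to 1."""
    if cc.fp + cc.tn == 0:
        raise ValueError("no true-negative-class examples")
    if cc.tp + cc.fn == 0:
        raise ValueError("no true-positive-class examples")
    return {
        "TPR": cc.tp / (cc.tp + cc.fn),
        "FNR": cc.fn / (cc.tp + cc.fn),
        "FPR": cc.fp / (cc.fp + cc.tn),
        "TNR": cc.tn / (cc.fp + cc.tn),
    }


def relative_improvement(new_value: float, old_value: float) -> float:
    """Percent improvement 100·(new − old)/old, rounded half-up to 1 decimal."""
    if old_value <= 0:
        raise ValueError("old_value must be positive")
    return round_half_up(100.0 * (new_value - old_value) / old_value, 1)


def tanimoto(fp_a: Iterable[int], fp_b: Iterable[int]) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two fingerprint bit sets.

    Two empty sets have similarity 0 by convention.
    """
    a, b = set(fp_a), set(fp_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def ngram_fingerprint(smiles: str, n_max: int = 4, n_bits: int = 2048) -> frozenset[int]:
    """Hashed substring fingerprint over the atom-level token stream.

    Every n-gram of pretokenized symbols (n = 1..n_max) is hashed (md5,
    salt-free, hence stable across processes) onto ``n_bits`` positions.
    A purely lexical descriptor: it supports similarity reporting without
    a chemistry toolkit but is not a circular/Morgan fingerprint.
    """
    symbols = pretokenize(smiles)
    bits = set()
    for n in range(1, n_max + 1):
        for i in range(len(symbols) - n + 1):
            gram = "\x1f".join(symbols[i:i + n])
            digest = hashlib.md5(gram.encode("utf-8")).digest()
            bits.add(int.from_bytes(digest[:8], "big") % n_bits)
    return frozenset(bits)


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> frozenset[int]:
    """Circular (Morgan/ECFP) fingerprint bit set via RDKit.

    Requires the optional chemistry toolkit; raises ``ImportError`` when
    RDKit is unavailable and ``ValueError`` for unparseable SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"RDKit could not parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


@dataclass
class EvaluationReport:
    """Full evaluation of scored pairs at one operating threshold."""

    counts: ConfusionCounts
    rates: dict[str, float]
    precision: float
    recall: float
    f1: float
    auc_roc: float
    pr_auc: float
    roc_points: np.ndarray
    pr_points: np.ndarray

    def metrics(self) -> dict[str, float]:
        return {
            "auc_roc": self.auc_roc,
            "pr_auc": self.pr_auc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }

    def to_dict(self) -> dict:
        out = {
            "confusion": asdict(self.counts),
            "rates": self.rates,
            **self.metrics(),
            "roc_points": self.roc_points.tolist(),
            "pr_points": self.pr_points.tolist(),
        }
        return out


def evaluate(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvaluationReport:
    """Compute the full report: confusion counts and rates, P/R/F1, both
    curves and both areas."""
    cc = confusion(scores, labels, threshold)
    p, r, f1 = precision_recall_f1(cc)
    roc_points, auc = roc_auc(scores, labels)
    pr_points, ap = pr_auc(scores, labels)
    return EvaluationReport(
        counts=cc,
        rates=normalize_confusion(cc),
        precision=p,
        recall=r,
        f1=f1,
        auc_roc=auc,
        pr_auc=ap,
        roc_points=roc_points,
        pr_points=pr_points,
    )


def aggregate(metric_runs: Sequence[dict[str, float]]) -> dict[str, tuple[float, float]]:
    """Across-run mean and sample standard deviation per metric.

    A single run reports a standard deviation of 0.
    """
    if not metric_runs:
        raise ValueError("no runs to aggregate")
    keys = metric_runs[0].keys()
    out = {}
    for k in keys:
        vals = np.asarray([m[k] for m in metric_runs], dtype=float)
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[k] = (float(vals.mean()), std)
    return out
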