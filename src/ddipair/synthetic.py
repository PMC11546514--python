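"""Balanced synthetic SMILES-pair datasets with a planted interaction rule.

Real DDI benchmarks pair two drug SMILES strings with a 0/1 interaction
label, balanced between classes.  The generator emulates that shape:
molecules are built by concatenating SMILES fragments from a small
alphabet, and a pair interacts exactly when one molecule carries a member
of ``motif_a`` and the other a member of ``motif_b`` (in either order), so
the label depends on substructure content of *both* molecules and a pair
encoder must read both to learn it.  Labels are exactly balanced by
rejection sampling, then optionally flipped with probability ``label_noise``
to emulate annotation error; the clean labels are kept for oracle checks.

The molecules are lexically valid SMILES but chemically naive — fragments
are concatenated, not bonded with correct valence.  That is sufficient here
because the downstream pipeline is purely lexical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GeneratorConfig",
    "LabeledPairDataset",
    "generate_molecule",
    "generate_dataset",
    "split_dataset",
    "pair_label",
]

DEFAULT_ALPHABET = ("C", "CC", "CO", "N", "O", "Cl", "c1ccccc1", "C(=O)O", "C(=O)N", "S")

Split = Literal["train", "valid", "test"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a balanced 2,000-pair dataset whose interaction rule is
    "both molecules carry an aromatic ring", with 5% label noise.  The two
    motif sets default to the same fragment deliberately: the predictor is
    a single affine map over the concatenated branch features, i.e. an
    additive function u(A) + v(B) of the pair, and a rule with equal motif
    sets is the symmetric rule an additive scorer can represent exactly
    (u₁+u₁ > u₁+u₀ > u₀+u₀).  Distinct motif sets plant a cross rule
    (motif-a in one AND motif-b in the other) that no additive scorer
    separates — configure that deliberately to probe the architecture's
    expressiveness ceiling rather than its training.
    """

    n_pairs: int = 2000
    fragment_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    motif_a: tuple[str, ...] = ("c1ccccc1",)
    motif_b: tuple[str, ...] = ("c1ccccc1",)
    min_fragments: int = 3
    max_fragments: int = 12
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0 or self.n_pairs % 2:
            raise ValueError("n_pairs must be a positive even integer")
        if not self.fragment_alphabet:
            raise ValueError("fragment alphabet must be non-empty")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must be in [0, 1)")
        if not (0 < self.min_fragments <= self.max_fragments):
            raise ValueError("invalid fragment length range")
        for m in self.motif_a + self.motif_b:
            if m not in self.fragment_alphabet:
                raise ValueError(f"motif {m!r} is not in the fragment alphabet")


@dataclass
class LabeledPairDataset:
    """Rows of (SMILES_A, SMILES_B, label) with optional split bookkeeping."""

    smiles_a: list[str]
    smiles_b: list[str]
    labels: np.ndarray  # int {0,1}, shape (n,)
    splits: list[Split] | None = None
    clean_labels: np.ndarray | None = None  # pre-noise labels, for oracles

    def __post_init__(self) -> None:
        n = len(self.smiles_a)
        if len(self.smiles_b) != n or len(self.labels) != n:
            raise ValueError("columns must have equal length")
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.smiles_a)

    def subset(self, split: Split) -> "LabeledPairDataset":
        if self.splits is None:
            raise ValueError("dataset has no split assignment")
        idx = [i for i, s in enumerate(self.splits) if s == split]
        if not idx:
            raise ValueError(f"split {split!r} is empty")
        return LabeledPairDataset(
            smiles_a=[self.smiles_a[i] for i in idx],
            smiles_b=[self.smiles_b[i] for i in idx],
            labels=self.labels[idx],
            clean_labels=None if self.clean_labels is None else self.clean_labels[idx],
        )

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.smiles_a, self.smiles_b))

    def all_smiles(self) -> list[str]:
        return self.smiles_a + self.smiles_b


def generate_molecule(config: GeneratorConfig, rng: np.random.Generator) -> str:
    """One molecule: k fragments concatenated, k uniform on the length range."""
    k = int(rng.integers(config.min_fragments, config.max_fragments + 1))
    idx = rng.integers(0, len(config.fragment_alphabet), size=k)
    return "".join(config.fragment_alphabet[i] for i in idx)


def _contains_any(smiles: str, motifs: Sequence[str]) -> bool:
    return any(m in smiles for m in motifs)


def pair_label(smiles_a: str, smiles_b: str, config: GeneratorConfig) -> int:
    """Ground-truth interaction rule, symmetric in the pair.

    1 iff (A carries a motif_a fragment and B a motif_b fragment) or vice
    versa, judged by plain substring containment.
    """
    fwd = _contains_any(smiles_a, config.motif_a) and _contains_any(smiles_b, config.motif_b)
    rev = _contains_any(smiles_b, config.motif_a) and _contains_any(smiles_a, config.motif_b)
    return int(fwd or rev)


_MAX_ATTEMPTS = 10 ** 6


def generate_dataset(config: GeneratorConfig) -> LabeledPairDataset:
    """Rejection-sample to exactly n_pairs/2 positives and negatives, then
    flip each label independently with probability ``label_noise``.

    Deterministic per seed.  Raises if either class cannot be filled within
    a bounded number of attempts (rule unsatisfiable under the alphabet).
    """
    rng = np.random.default_rng(config.seed)
    quota = config.n_pairs // 2
    rows: list[tuple[str, str, int]] = []
    remaining = {0: quota, 1: quota}
    for _ in range(_MAX_ATTEMPTS):
        if remaining[0] == 0 and remaining[1] == 0:
            break
        a = generate_molecule(config, rng)
        b = generate_molecule(config, rng)
        y = pair_label(a, b, config)
        if remaining[y] > 0:
            rows.append((a, b, y))
            remaining[y] -= 1
    else:
        raise RuntimeError(
            "could not fill both label classes; interaction rule may be "
            "unsatisfiable with the given fragment alphabet"
        )
    clean = np.array([y for _, _, y in rows], dtype=int)
    flips = rng.random(len(clean)) < config.label_noise
    noisy = np.where(flips, 1 - clean, clean)
    return LabeledPairDataset(
        smiles_a=[a for a, _, _ in rows],
        smiles_b=[b for _, b, _ in rows],
        labels=noisy,
        clean_labels=clean,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    dataset: LabeledPairDataset,
    test_fraction: float = 0.2,
    valid_fraction: float = 0.2,
    seed: int = 0,
) -> LabeledPairDataset:
    """Assign train/valid/test splits by a seeded shuffle.

    The test split takes ``round(N * test_fraction)`` rows; the validation
    split takes ``round(remaining * valid_fraction)`` of the rest (the
    benchmark convention: 20% held-out test, then train:valid = 8:2).
    """
    if not (0 < test_fraction < 1 and 0 < valid_fraction < 1):
        raise ValueError("fractions must be in (0, 1)")
    n = len(dataset)
    n_test = _round_half_up(n * test_fraction)
    n_valid = _round_half_up((n - n_test) * valid_fraction)
    n_train = n - n_test - n_valid
    if min(n_test, n_valid, n_train) <= 0:
        raise ValueError("dataset too small: a split would be empty")
    order = np.random.default_rng(seed).permutation(n)
    splits: list[Split] = ["train"] * n
    for i in order[:n_test]:
        splits[i] = "test"
    for i in order[n_test:n_test + n_valid]:
        splits[i] = "valid"
    return replace_splits(dataset, splits)


def replace_splits(dataset: LabeledPairDataset, splits: list[Split]) -> LabeledPairDataset:
    return LabeledPairDataset(
        smiles_a=dataset.smiles_a,
        smiles_b=dataset.smiles_b,
        labels=dataset.labels,
        splits=splits,
        clean_labels=dataset.clean_labels,
    )
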