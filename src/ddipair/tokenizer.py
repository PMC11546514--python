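"""SMILES tokenization: atom-level pre-tokenization plus byte-pair encoding.

The tokenizer turns a raw SMILES string into a fixed-length sequence of
integer token IDs.  It first segments the string into chemically meaningful
lexical units (bracket atoms, two-letter halogens, aromatic atoms, bonds,
ring-closure digits, branch parentheses) and then applies an ordered list of
learned byte-pair merges, so that frequent multi-atom substrings (functional
groups, ring motifs) become single vocabulary entries.  Rare or unseen
symbols fall back to ``UNK``.

Only lexical validity is checked: the tokenizer never builds a molecular
graph and does not verify valence or aromaticity.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SmilesSyntaxError",
    "Vocabulary",
    "TokenSequence",
    "pretokenize",
    "train_bpe",
    "encode",
    "decode",
    "save_vocab",
    "load_vocab",
]

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
PAD_ID, BOS_ID, EOS_ID, UNK_ID = 0, 1, 2, 3
SPECIAL_TOKENS = {PAD: PAD_ID, BOS: BOS_ID, EOS: EOS_ID, UNK: UNK_ID}

# Lexical classes, tried in order at each position: bracket atoms, %nn ring
# closures, two-letter organic-subset atoms, single-letter atoms (aliphatic
# and aromatic), bonds, branches, ring digits, dot disconnection.
_TOKEN_RE = re.compile(
    r"\[[^\[\]]+\]"
    r"|%\d{2}"
    r"|Cl|Br"
    r"|[BCNOPSFI]"
    r"|[bcnops]"
    r"|[-=#/\\:~.]"
    r"|[()]"
    r"|\d"
)


class SmilesSyntaxError(ValueError):
    """Raised for lexically invalid SMILES; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


def pretokenize(smiles: str) -> list[str]:
    """Segment a SMILES string into atom/bond/branch symbols.

    The concatenation of the returned symbols equals the input exactly.
    Bracket atoms ``[...]`` and the two-letter atoms Cl/Br are single
    symbols; everything else is one character (or ``%nn`` for two-digit
    ring closures).

    Raises
    ------
    SmilesSyntaxError
        If the string is empty, contains a character outside the SMILES
        alphabet, or has an unterminated/unbalanced bracket.
    """
    if not smiles:
        raise SmilesSyntaxError("empty SMILES string", 0)
    symbols: list[str] = []
    pos = 0
    depth = 0
    n = len(smiles)
    while pos < n:
        ch = smiles[pos]
        if ch == "]":
            raise SmilesSyntaxError("unmatched ']'", pos)
        if ch == "[" and "]" not in smiles[pos:]:
            raise SmilesSyntaxError("unterminated '['", pos)
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise SmilesSyntaxError(f"invalid SMILES character {ch!r}", pos)
        tok = m.group(0)
        if tok == "(":
            depth += 1
        elif tok == ")":
            if depth == 0:
                raise SmilesSyntaxError("unmatched ')'", pos)
            depth -= 1
        symbols.append(tok)
        pos = m.end()
    if depth != 0:
        raise SmilesSyntaxError("unclosed '('", n)
    return symbols


@dataclass
class Vocabulary:
    """Token inventory: base symbols, ordered BPE merges and special tokens.

    ``token_to_id`` is a bijection onto contiguous IDs starting at 0, with
    the four special tokens pinned to IDs 0-3.
    """

    base_symbols: list[str]
    merges: list[tuple[str, str]]
    token_to_id: dict[str, int]
    special_tokens: dict[str, int] = field(default_factory=lambda: dict(SPECIAL_TOKENS))

    def __post_init__(self) -> None:
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("token IDs must be contiguous from 0")
        for tok, i in self.special_tokens.items():
            if self.token_to_id.get(tok) != i:
                raise ValueError(f"special token {tok!r} must map to ID {i}")
        for left, right in self.merges:
            if left not in self.token_to_id or right not in self.token_to_id:
                raise ValueError(f"merge operand missing from vocabulary: {(left, right)}")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return (
            self.token_to_id == other.token_to_id
            and self.merges == other.merges
            and self.special_tokens == other.special_tokens
        )


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length encoded sequence: IDs plus a 0/1 attention mask."""

    ids: tuple[int, ...]
    mask: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.mask):
            raise ValueError("ids and mask must have equal length")

    @property
    def n_real(self) -> int:
        return sum(self.mask)

    @property
    def max_len(self) -> int:
        return len(self.ids)


def _apply_merge(symbols: list[str], left: str, right: str) -> list[str]:
    # greedy left-to-right replacement of adjacent (left, right)
    out: list[str] = []
    i = 0
    n = len(symbols)
    while i < n:
        if i + 1 < n and symbols[i] == left and symbols[i + 1] == right:
            out.append(left + right)
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    return out


def train_bpe(corpus: Iterable[str], n_merges: int) -> Vocabulary:
    """Learn a vocabulary from a SMILES corpus by greedy pair merging.

    Starting from the atom-level segmentation, the most frequent adjacent
    token pair is merged into a new token, ``n_merges`` times.  Pairs seen
    fewer than twice are never merged; ties are broken by lexicographically
    smallest ``(left, right)``, so training is deterministic.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    if n_merges < 0:
        raise ValueError("n_merges must be non-negative")
    words = [pretokenize(s) for s in corpus]
    base = sorted({sym for w in words for sym in w})
    merges: list[tuple[str, str]] = []
    for _ in range(n_merges):
        pairs: Counter[tuple[str, str]] = Counter()
        for w in words:
            for a, b in zip(w, w[1:]):
                pairs[(a, b)] += 1
        if not pairs:
            break
        best = min(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
        (left, right), count = best
        if count < 2:
            break
        merges.append((left, right))
        words = [_apply_merge(w, left, right) for w in words]
    token_to_id = dict(SPECIAL_TOKENS)
    next_id = len(token_to_id)
    for tok in base + [l + r for l, r in merges]:
        if tok not in token_to_id:
            token_to_id[tok] = next_id
            next_id += 1
    return Vocabulary(base_symbols=base, merges=merges, token_to_id=token_to_id)


def tokenize(smiles: str, vocab: Vocabulary) -> list[str]:
    """Pre-tokenize and apply the vocabulary's merges in learned order."""
    symbols = pretokenize(smiles)
    for left, right in vocab.merges:
        symbols = _apply_merge(symbols, left, right)
    return symbols


def encode(smiles: str, vocab: Vocabulary, max_len: int = 512) -> TokenSequence:
    """Encode a SMILES string to a fixed-length ID sequence.

    The token stream is wrapped in BOS/EOS and padded with PAD to
    ``max_len``.  If there are more than ``max_len - 2`` content tokens, the
    sequence is truncated to the first ``max_len - 2`` and EOS is kept
    terminal, so the backward recurrence still starts at a sequence-end
    marker.  Symbols missing from the vocabulary map to UNK.
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3")
    symbols = tokenize(smiles, vocab)
    content = [vocab.token_to_id.get(sym, UNK_ID) for sym in symbols]
    content = content[: max_len - 2]
    ids = [BOS_ID, *content, EOS_ID]
    n_real = len(ids)
    ids.extend([PAD_ID] * (max_len - n_real))
    mask = [1] * n_real + [0] * (max_len - n_real)
    return TokenSequence(ids=tuple(ids), mask=tuple(mask))


def decode(seq: TokenSequence, vocab: Vocabulary) -> str:
    """Inverse of :func:`encode` on in-vocabulary inputs.

    Returns the concatenation of the content tokens (specials stripped);
    UNK tokens cannot be inverted and raise ``ValueError``.
    """
    parts: list[str] = []
    for i, m in zip(seq.ids, seq.mask):
        if not m or i in (PAD_ID, BOS_ID, EOS_ID):
            continue
        if i == UNK_ID:
            raise ValueError("cannot decode UNK token")
        parts.append(vocab.id_to_token[i])
    return "".join(parts)


def save_vocab(vocab: Vocabulary, path: str | Path) -> None:
    """Serialize a vocabulary as a single JSON bundle."""
    payload = {
        "token_to_id": vocab.token_to_id,
        "merges": [list(m) for m in vocab.merges],
        "special_tokens": vocab.special_tokens,
        "base_symbols": vocab.base_symbols,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _load_merges_txt(path: Path) -> list[tuple[str, str]]:
    merges: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 'left right', got {line!r}")
        merges.append((parts[0], parts[1]))
    return merges


def load_vocab(path: str | Path, merges_path: str | Path | None = None) -> Vocabulary:
    """Load a vocabulary from file.

    Two dialects are accepted: the bundled JSON written by
    :func:`save_vocab`, or a pretrained-tokenizer pair — a JSON map
    token→ID plus a separate merges text file with one ``left right`` pair
    per line (``#``-prefixed header lines are ignored).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: line {exc.lineno}: malformed JSON: {exc.msg}") from exc
    if "token_to_id" in payload:  # bundled dialect
        token_to_id = {str(t): int(i) for t, i in payload["token_to_id"].items()}
        merges = [tuple(m) for m in payload.get("merges", [])]
        specials = {str(t): int(i) for t, i in payload.get("special_tokens", SPECIAL_TOKENS).items()}
        base = list(payload.get("base_symbols", []))
    else:  # flat token→ID map (pretrained dialect)
        token_to_id = {str(t): int(i) for t, i in payload.items()}
        merges = _load_merges_txt(Path(merges_path)) if merges_path is not None else []
        specials = {t: i for t, i in SPECIAL_TOKENS.items() if token_to_id.get(t) == i}
        if len(specials) != len(SPECIAL_TOKENS):
            raise ValueError(f"{path}: special tokens {sorted(SPECIAL_TOKENS)} with IDs 0-3 are required")
        merged = {l + r for l, r in merges}
        base = sorted(t for t in token_to_id if t not in merged and t not in specials)
    if not base:
        merged = {l + r for l, r in merges}
        base = sorted(t for t in token_to_id if t not in merged and t not in specials)
    return Vocabulary(base_symbols=base, merges=merges, token_to_id=token_to_id, special_tokens=specials)


def encode_corpus(
    smiles: Sequence[str], vocab: Vocabulary, max_len: int = 512
) -> list[TokenSequence]:
    """Encode many SMILES strings with one vocabulary."""
    return [encode(s, vocab, max_len) for s in smiles]
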