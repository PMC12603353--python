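"""Local Context Aware (LCA) k-mer tokenization.

Overlapping k-mer tokens advance by a shift <= k, so consecutive tokens
share k - shift characters of context.  Two stock variants are provided:
``mini`` (k=6) for the 6-mer models and ``mini-c`` (k=1) for the
character-level model.  Encoding frames the token ids with [CLS] ... [SEP],
pads to a fixed maximum length and returns an attention mask.

The vocabulary is fixed and reproducible: the four special tokens followed
by all 4**k k-mers over {A,C,G,T} in lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP)


@dataclass(frozen=True)
class Vocabulary:
    """Token <-> id bijection: [PAD, UNK, CLS, SEP] + lexicographic k-mers."""

    k: int
    tokens: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    @classmethod
    def build(cls, k: int) -> "Vocabulary":
        if k < 1:
            raise ValueError("k must be >= 1")
        kmers = ["".join(p) for p in product("ACGT", repeat=k)]
        tokens = tuple(SPECIAL_TOKENS) + tuple(kmers)
        return cls(k=k, tokens=tokens, index={t: i for i, t in enumerate(tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    @property
    def cls_id(self) -> int:
        return 2

    @property
    def sep_id(self) -> int:
        return 3

    def save(self, path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        tokens = tuple(Path(path).read_text().splitlines())
        if tokens[:4] != SPECIAL_TOKENS:
            raise ValueError("vocabulary file does not start with the special tokens")
        k = len(tokens[4])
        vocab = cls.build(k)
        if vocab.tokens != tokens:
            raise ValueError("vocabulary file is not the canonical ordering")
        return vocab


@dataclass
class TokenizedSegment:
    """Fixed-length id sequence: [CLS] payload [SEP] PAD...; mask marks real tokens."""

    ids: np.ndarray  # int32, shape (max_len,)
    attention_mask: np.ndarray  # int8, shape (max_len,)
    n_real_tokens: int
    origin: object = None  # typically a Segment


@dataclass
class LCATokenizer:
    """LCA tokenizer with fixed k, shift and maximum encoded length."""

    k: int = 6
    shift: int = 1
    max_len: int = 512

    def __post_init__(self) -> None:
        if not (1 <= self.shift <= self.k):
            raise ValueError("require 1 <= shift <= k (larger shifts drop sequence)")
        if self.max_len < 3:
            raise ValueError("max_len must be >= 3 ([CLS] + >=1 + [SEP])")
        self.vocab = Vocabulary.build(self.k)

    # -- token-string level ------------------------------------------------

    def tokenize(self, seq: str) -> list[str]:
        """Windows seq[i:i+k] for i = 0, shift, 2*shift, ...; N-windows -> [UNK]."""
        k, shift = self.k, self.shift
        if len(seq) < k:
            return []
        tokens = []
        for i in range(0, len(seq) - k + 1, shift):
            window = seq[i : i + k]
            tokens.append(UNK if "N" in window else window)
        return tokens

    def detokenize(self, tokens: Sequence[str], shift: Optional[int] = None) -> str:
        """Inverse of tokenize on overlap-consistent tokens."""
        shift = self.shift if shift is None else shift
        if not tokens:
            return ""
        seq = tokens[0]
        for prev, tok in zip(tokens, tokens[1:]):
            if prev[shift:] != tok[: len(prev) - shift]:
                raise ValueError(f"overlap mismatch between {prev!r} and {tok!r}")
            seq += tok[-shift:]
        return seq

    # -- id level ----------------------------------------------------------

    def encode_tokens(self, tokens: Sequence[str], origin=None) -> TokenizedSegment:
        """Frame with [CLS]/[SEP], truncate keeping SEP last, pad to max_len."""
        vocab = self.vocab
        payload = [vocab.index.get(t, vocab.unk_id) for t in tokens]
        payload = payload[: self.max_len - 2]
        ids = np.zeros(self.max_len, dtype=np.int32)  # PAD id is 0
        n_real = len(payload) + 2
        ids[0] = vocab.cls_id
        ids[1 : n_real - 1] = payload
        ids[n_real - 1] = vocab.sep_id
        mask = np.zeros(self.max_len, dtype=np.int8)
        mask[:n_real] = 1
        return TokenizedSegment(ids=ids, attention_mask=mask, n_real_tokens=n_real, origin=origin)

    def encode(self, seq: str, origin=None) -> TokenizedSegment:
        return self.encode_tokens(self.tokenize(seq), origin=origin)

    def n_tokens(self, seq_len: int) -> int:
        """floor((len - k)/shift) + 1 for len >= k, else 0."""
        if seq_len < self.k:
            return 0
        return (seq_len - self.k) // self.shift + 1

    def settings(self) -> dict:
        return {"k": self.k, "shift": self.shift, "max_len": self.max_len}


def mini_tokenizer(max_len: int = 512, shift: int = 1) -> LCATokenizer:
    """The 6-mer LCA variant."""
    return LCATokenizer(k=6, shift=shift, max_len=max_len)


def mini_c_tokenizer(max_len: int = 512) -> LCATokenizer:
    """The character-level variant (k = 1)."""
    return LCATokenizer(k=1, shift=1, max_len=max_len)
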