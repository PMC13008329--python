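"""Tokenization of cleaned barcode sequences.

Two strategies are provided:

- **Non-overlapping k-mers** (the default): the sequence is cut into
  consecutive, non-overlapping substrings of length k, each mapped to one
  of the 4^k vocabulary ids; any k-mer containing a non-ACGT character
  maps to [UNK]. The vocabulary is the 4^k k-mers plus [MASK] and [UNK]
  (4^k + 2 ids); padding uses a dedicated pad id outside that count,
  paired with a validity mask. During pretraining each sequence is
  tokenized from a random frame offset in [0, k) as augmentation; at
  inference the offset is fixed to 0.

- **Byte-pair encoding (BPE)**: merges are learned over the alphabet
  {A, C, G, T, N} from a training corpus until the vocabulary reaches a
  target size v; token sequences are capped at a maximum length that
  depends on v (128 for v in {4096, 1024}, 256 for v in {256, 128}).

Sequences are padded or truncated at 660 nucleotides before k-mer
tokenization, covering the COI barcode region; padding is realized at the
token level (pad id + validity mask), never as fake nucleotides.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

MAX_NUCLEOTIDES = 660

BPE_MAX_TOKENS = {4096: 128, 1024: 128, 256: 256, 128: 256}


@dataclass
class TokenizedBatch:
    """A dense (n, T) matrix of token ids with a validity mask.

    ``validity_mask`` is True at real-token positions and False at padding;
    padded cells of ``token_ids`` hold ``pad_id``. ``offsets`` records the
    per-sequence frame offset used (all zero in inference mode).
    """

    token_ids: np.ndarray
    validity_mask: np.ndarray
    offsets: np.ndarray
    pad_id: int

    def __post_init__(self) -> None:
        assert self.token_ids.shape == self.validity_mask.shape
        assert np.all(self.token_ids[~self.validity_mask] == self.pad_id)

    @property
    def n(self) -> int:
        return self.token_ids.shape[0]

    @property
    def T(self) -> int:
        return self.token_ids.shape[1]


def pad_or_truncate(sequence: str, max_nucleotides: int = MAX_NUCLEOTIDES) -> str:
    """Cap a cleaned sequence at ``max_nucleotides`` (keep the prefix).

    Shorter sequences are returned unchanged — the length difference is
    covered downstream by the token-level validity mask, not by fake
    nucleotides.
    """
    return sequence[:max_nucleotides]


def sample_offset(k: int, rng: np.random.Generator) -> int:
    """Uniform frame offset in {0, ..., k-1} for pretraining augmentation."""
    return int(rng.integers(0, k))


class KmerTokenizer:
    """Non-overlapping k-mer tokenizer with [MASK]/[UNK] and a pad id.

    Vocabulary layout: ids 0 .. 4^k - 1 are the k-mers in lexicographic
    order, then [MASK], then [UNK] (published size 4^k + 2); ``pad_id`` is
    the next id, outside the published count.
    """

    def __init__(self, k: int = 4, max_nucleotides: int = MAX_NUCLEOTIDES):
        if not 1 <= k <= 8:
            raise ValueError(f"k must be in [1, 8], got {k}")
        self.k = k
        self.max_nucleotides = max_nucleotides
        kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
        self._kmer_to_id = {kmer: i for i, kmer in enumerate(kmers)}
        self.mask_id = len(kmers)
        self.unk_id = len(kmers) + 1
        self.pad_id = len(kmers) + 2

    @property
    def vocab_size(self) -> int:
        """Published vocabulary size 4^k + 2 (pad id excluded)."""
        return 4**self.k + 2

    @property
    def max_tokens(self) -> int:
        return self.max_nucleotides // self.k

    def token_id(self, kmer: str) -> int:
        return self._kmer_to_id.get(kmer, self.unk_id)

    def tokenize(self, sequence: str, offset: int = 0) -> list[int]:
        """Tokenize from frame ``offset``; a trailing remainder < k is dropped."""
        if not 0 <= offset < self.k:
            raise ValueError(f"offset must be in [0, {self.k}), got {offset}")
        seq = pad_or_truncate(sequence, self.max_nucleotides)[offset:]
        k = self.k
        return [self.token_id(seq[i : i + k]) for i in range(0, len(seq) - k + 1, k)]

    def batch(
        self,
        sequences: Sequence[str],
        rng: np.random.Generator | None = None,
        max_tokens: int | None = None,
    ) -> TokenizedBatch:
        """Tokenize a batch; random offsets are drawn iff ``rng`` is given.

        The matrix width is the longest token list in the batch (capped at
        ``max_tokens`` or the tokenizer maximum) — shorter batches stay
        narrow instead of always padding to floor(660/k).
        """
        cap = max_tokens if max_tokens is not None else self.max_tokens
        offsets = np.array(
            [sample_offset(self.k, rng) if rng is not None else 0 for _ in sequences],
            dtype=np.int64,
        )
        token_lists = [
            self.tokenize(seq, int(off))[:cap] for seq, off in zip(sequences, offsets)
        ]
        T = max((len(t) for t in token_lists), default=1) or 1
        ids = np.full((len(sequences), T), self.pad_id, dtype=np.int64)
        mask = np.zeros((len(sequences), T), dtype=bool)
        for i, toks in enumerate(token_lists):
            ids[i, : len(toks)] = toks
            mask[i, : len(toks)] = True
        return TokenizedBatch(ids, mask, offsets, self.pad_id)

    def to_json(self) -> dict:
        return {"type": "kmer", "k": self.k, "max_nucleotides": self.max_nucleotides}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "KmerTokenizer":
        data = json.loads(Path(path).read_text())
        if data.get("type") != "kmer":
            raise ValueError(f"not a k-mer tokenizer file: {path}")
        return cls(k=data["k"], max_nucleotides=data["max_nucleotides"])


# ---------------------------------------------------------------------------
# Byte-pair encoding


@dataclass
class BpeTokenizer:
    """A trained BPE tokenizer over the alphabet {A, C, G, T, N}.

    The vocabulary is [MASK], [UNK], the 5 base symbols, then one entry per
    learned merge, totalling exactly ``vocab_size`` ids; ``pad_id`` sits
    outside that count. Encoding applies merges greedily in training order
    (standard BPE).
    """

    merges: list[tuple[str, str]]
    max_tokens: int
    vocab: list[str] = field(init=False)
    mask_id: int = field(init=False)
    unk_id: int = field(init=False)

    BASE_ALPHABET = ("A", "C", "G", "T", "N")

    def __post_init__(self) -> None:
        self.vocab = ["[MASK]", "[UNK]", *self.BASE_ALPHABET]
        for a, b in self.merges:
            self.vocab.append(a + b)
        self._token_to_id = {tok: i for i, tok in enumerate(self.vocab)}
        self.mask_id = 0
        self.unk_id = 1
        self._merge_rank = {pair: r for r, pair in enumerate(self.merges)}

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @property
    def pad_id(self) -> int:
        return len(self.vocab)

    def encode_symbols(self, sequence: str) -> list[str]:
        symbols = [c if c in self.BASE_ALPHABET else "[UNK]" for c in sequence]
        while len(symbols) > 1:
            best_rank, best_i = None, None
            for i in range(len(symbols) - 1):
                rank = self._merge_rank.get((symbols[i], symbols[i + 1]))
                if rank is not None and (best_rank is None or rank < best_rank):
                    best_rank, best_i = rank, i
            if best_i is None:
                break
            symbols[best_i : best_i + 2] = [symbols[best_i] + symbols[best_i + 1]]
        return symbols

    def tokenize(self, sequence: str) -> list[int]:
        toks = [self._token_to_id.get(s, self.unk_id) for s in self.encode_symbols(sequence)]
        return toks[: self.max_tokens]

    def batch(self, sequences: Sequence[str]) -> TokenizedBatch:
        T = self.max_tokens
        ids = np.full((len(sequences), T), self.pad_id, dtype=np.int64)
        mask = np.zeros((len(sequences), T), dtype=bool)
        for i, seq in enumerate(sequences):
            toks = self.tokenize(seq)
            ids[i, : len(toks)] = toks
            mask[i, : len(toks)] = True
        return TokenizedBatch(ids, mask, np.zeros(len(sequences), dtype=np.int64), self.pad_id)

    def to_json(self) -> dict:
        return {
            "type": "bpe",
            "merges": [list(m) for m in self.merges],
            "max_tokens": self.max_tokens,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "BpeTokenizer":
        data = json.loads(Path(path).read_text())
        if data.get("type") != "bpe":
            raise ValueError(f"not a BPE tokenizer file: {path}")
        return cls(
            merges=[tuple(m) for m in data["merges"]], max_tokens=data["max_tokens"]
        )


def train_bpe(
    corpus: Sequence[str], v: int, max_tokens: int | None = None
) -> BpeTokenizer:
    """Learn BPE merges over a cleaned barcode corpus to vocabulary size v.

    The most frequent adjacent symbol pair is merged at each step (ties
    broken lexicographically for determinism) until the vocabulary — two
    special tokens, the 5-symbol base alphabet, and one entry per merge —
    reaches exactly ``v`` entries.

    Raises
    ------
    ValueError
        If the corpus is empty, v is below the base vocabulary size, or the
        corpus is too small/uniform to support enough merges.
    """
    base_size = 2 + len(BpeTokenizer.BASE_ALPHABET)
    if not corpus:
        raise ValueError("BPE training corpus is empty")
    if v < base_size:
        raise ValueError(f"v must be at least the base vocabulary size {base_size}")
    if max_tokens is None:
        max_tokens = BPE_MAX_TOKENS.get(v, 256)

    sequences = [[c if c in BpeTokenizer.BASE_ALPHABET else "N" for c in s] for s in corpus]
    merges: list[tuple[str, str]] = []
    n_merges = v - base_size
    for _ in range(n_merges):
        pair_counts: Counter = Counter()
        for seq in sequences:
            for i in range(len(seq) - 1):
                pair_counts[(seq[i], seq[i + 1])] += 1
        if not pair_counts:
            raise ValueError(
                f"corpus exhausted after {len(merges)} merges; achievable "
                f"vocabulary size is {base_size + len(merges)}, requested {v}"
            )
        max_count = max(pair_counts.values())
        pair = min(p for p, c in pair_counts.items() if c == max_count)
        merges.append(pair)
        merged = pair[0] + pair[1]
        for s_idx, seq in enumerate(sequences):
            i, out = 0, []
            while i < len(seq):
                if i + 1 < len(seq) and seq[i] == pair[0] and seq[i + 1] == pair[1]:
                    out.append(merged)
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            sequences[s_idx] = out
    return BpeTokenizer(merges=merges, max_tokens=max_tokens)
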