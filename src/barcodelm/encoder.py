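"""Bidirectional transformer encoder for tokenized DNA barcodes.

A BERT-family encoder: token + learned absolute positional embeddings,
pre-norm transformer blocks (multi-head self-attention, GELU feed-forward
of width 4*d), a final layer norm, a linear masked-token prediction head,
and mean pooling over non-special positions to produce one embedding
vector per barcode. The default configuration follows the published
recipe: four layers, four attention heads, model width d = 768; tests and
toy runs use smaller presets.

No [CLS]/[SEP] tokens are used — the vocabulary holds only the k-mers (or
BPE tokens) plus [MASK] and [UNK], and the barcode-level embedding is a
global average pool that ignores padding and [MASK] positions. [UNK]
positions are included in the pool: they carry sequence content, and at
inference [MASK] never occurs.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import IO

import numpy as np

from barcodelm import autodiff as ad
from barcodelm.autodiff import Tensor
from barcodelm.tokenizers import TokenizedBatch

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    ``vocab_size`` is the published vocabulary (4^k + 2 for k-mer mode);
    the embedding table holds one extra row for the pad id. ``max_positions``
    is floor(660/k) in k-mer mode or the BPE max token count.
    """

    vocab_size: int
    max_positions: int
    num_layers: int = 4
    num_heads: int = 4
    model_dim: int = 768
    feedforward_dim: int | None = None  # defaults to 4 * model_dim
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.model_dim % self.num_heads != 0:
            raise ValueError(
                f"model_dim {self.model_dim} not divisible by num_heads {self.num_heads}"
            )

    @property
    def ff_dim(self) -> int:
        return self.feedforward_dim or 4 * self.model_dim

    @property
    def head_dim(self) -> int:
        return self.model_dim // self.num_heads


class TransformerEncoder:
    """Pre-norm transformer encoder with an MLM head, on numpy autodiff."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, f = config.model_dim, config.ff_dim
        V = config.vocab_size

        def init(*shape, scale=0.02):
            return ad.parameter(rng.normal(0.0, scale, shape).astype(np.float32))

        self.params: dict[str, Tensor] = {}
        p = self.params
        p["tok_emb"] = init(V + 1, d)  # +1 row for pad id
        p["pos_emb"] = init(config.max_positions, d)
        for layer in range(config.num_layers):
            pre = f"layer{layer}."
            p[pre + "ln1_g"] = ad.parameter(np.ones(d, dtype=np.float32))
            p[pre + "ln1_b"] = ad.parameter(np.zeros(d, dtype=np.float32))
            p[pre + "wq"] = init(d, d)
            p[pre + "wk"] = init(d, d)
            p[pre + "wv"] = init(d, d)
            p[pre + "wo"] = init(d, d)
            p[pre + "bo"] = ad.parameter(np.zeros(d, dtype=np.float32))
            p[pre + "ln2_g"] = ad.parameter(np.ones(d, dtype=np.float32))
            p[pre + "ln2_b"] = ad.parameter(np.zeros(d, dtype=np.float32))
            p[pre + "w_ff1"] = init(d, f)
            p[pre + "b_ff1"] = ad.parameter(np.zeros(f, dtype=np.float32))
            p[pre + "w_ff2"] = init(f, d)
            p[pre + "b_ff2"] = ad.parameter(np.zeros(d, dtype=np.float32))
        p["ln_f_g"] = ad.parameter(np.ones(d, dtype=np.float32))
        p["ln_f_b"] = ad.parameter(np.zeros(d, dtype=np.float32))
        p["head_w"] = init(d, V)
        p["head_b"] = ad.parameter(np.zeros(V, dtype=np.float32))

    # ------------------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def _attention(
        self, x: Tensor, layer: int, attn_mask: np.ndarray,
        rng: np.random.Generator | None,
    ) -> Tensor:
        cfg = self.config
        p = self.params
        pre = f"layer{layer}."
        n, T, d = x.shape
        h, hd = cfg.num_heads, cfg.head_dim

        def split_heads(t: Tensor) -> Tensor:
            # (n, T, d) -> (n, h, T, hd)
            return t.reshape(n, T, h, hd).transpose(0, 2, 1, 3)

        q = split_heads(x @ p[pre + "wq"])
        k = split_heads(x @ p[pre + "wk"])
        v = split_heads(x @ p[pre + "wv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = ad.softmax(scores, key_mask=attn_mask)
        attn = ad.dropout(attn, cfg.dropout, rng)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, T, d)
        return ctx @ p[pre + "wo"] + p[pre + "bo"]

    def encode(
        self, batch: TokenizedBatch, rng: np.random.Generator | None = None
    ) -> Tensor:
        """Per-token representations, shape (n, T, d).

        ``rng`` enables dropout (training mode); with ``rng=None`` the
        forward pass is deterministic. Padding positions attend to nothing
        and are excluded from attention keys; their output values are
        arbitrary and must be masked downstream.
        """
        cfg = self.config
        ids = batch.token_ids
        n, T = ids.shape
        if T > cfg.max_positions:
            raise ValueError(
                f"batch length {T} exceeds max_positions {cfg.max_positions}"
            )
        if ids.max() > cfg.vocab_size:  # pad id == vocab_size is the extra row
            raise ValueError("token id out of range for the configured vocabulary")
        p = self.params
        # positional rows broadcast over the batch: (n,T,d) + (T,d)
        x = ad.embedding(p["tok_emb"], ids) + ad.embedding(p["pos_emb"], np.arange(T))
        x = ad.dropout(x, cfg.dropout, rng)
        # keys at padding positions are excluded from every attention softmax
        attn_mask = batch.validity_mask.astype(np.float32)[:, None, None, :]
        for layer in range(cfg.num_layers):
            pre = f"layer{layer}."
            h = ad.layer_norm(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            x = x + ad.dropout(self._attention(h, layer, attn_mask, rng), cfg.dropout, rng)
            h = ad.layer_norm(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            ff = ad.gelu(h @ p[pre + "w_ff1"] + p[pre + "b_ff1"])
            x = x + ad.dropout(ff @ p[pre + "w_ff2"] + p[pre + "b_ff2"], cfg.dropout, rng)
        if cfg.num_layers == 0:
            # identity stub: raw token + position embeddings, for testing
            return x
        return ad.layer_norm(x, p["ln_f_g"], p["ln_f_b"])

    def mlm_logits(self, hidden: Tensor) -> Tensor:
        """Linear classification head over the vocabulary, (n, T, |V|)."""
        return hidden @ self.params["head_w"] + self.params["head_b"]

    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single-file checkpoint (config JSON + named weights).

        Written atomically: a temporary file is renamed into place.
        """
        path = Path(path)
        tmp = path.with_name(path.name + ".tmp")
        with zipfile.ZipFile(tmp, "w") as zf:
            meta = {"version": CHECKPOINT_VERSION, "config": asdict(self.config)}
            zf.writestr("config.json", json.dumps(meta))
            for name, tensor in self.params.items():
                with zf.open(f"weights/{name}.npy", "w") as handle:
                    np.save(handle, tensor.data)
        tmp.replace(path)

    @classmethod
    def load(cls, path: str | Path) -> "TransformerEncoder":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("config.json"))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            model = cls(EncoderConfig(**meta["config"]))
            for name in model.params:
                with zf.open(f"weights/{name}.npy") as handle:
                    model.params[name].data = np.load(handle)
        return model


def pool_embedding(
    hidden: Tensor | np.ndarray,
    validity_mask: np.ndarray,
    special_positions: np.ndarray | None = None,
) -> Tensor | np.ndarray:
    """Global average pool over eligible positions, one d-vector per sequence.

    Eligible positions are valid (non-pad) and not flagged special
    ([MASK] during training; [UNK] counts as content and is pooled).
    Differentiable when ``hidden`` is a Tensor; plain numpy otherwise.

    Raises
    ------
    ValueError
        If any sequence has no eligible position.
    """
    eligible = validity_mask.copy()
    if special_positions is not None:
        eligible &= ~special_positions
    counts = eligible.sum(axis=1)
    if np.any(counts == 0):
        bad = int(np.nonzero(counts == 0)[0][0])
        raise ValueError(f"empty pooling set for sequence at row {bad}")
    w = (eligible / counts[:, None]).astype(np.float32)  # (n, T)
    if isinstance(hidden, Tensor):
        return (hidden * Tensor(w[:, :, None])).sum(axis=1)
    return (hidden * w[:, :, None]).sum(axis=1)


def embed_records(
    model: TransformerEncoder, tokenizer, sequences, batch_size: int = 64
) -> np.ndarray:
    """Pooled embeddings for a list of cleaned sequences (inference mode).

    Tokenizes without random offsets, encodes deterministically, and mean
    pools over real tokens. Returns an (n, d) float matrix.
    """
    out = []
    for start in range(0, len(sequences), batch_size):
        chunk = sequences[start : start + batch_size]
        batch = tokenizer.batch(chunk)
        hidden = model.encode(batch)
        out.append(np.asarray(pool_embedding(hidden.data, batch.validity_mask)))
    return np.concatenate(out, axis=0)
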