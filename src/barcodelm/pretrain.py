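"""Masked-token pretraining with a weighted substitution/context loss.

Per sequence, floor(r_s * n_valid) positions — the *substitution* tokens —
are sampled uniformly without replacement among valid positions and
replaced by [MASK]; the remaining valid positions are *context* tokens.
The model predicts the original token at every valid position, and the
loss combines the two groups:

    loss = w_s * meanCE(substitution) + (1 - w_s) * meanCE(context)

The defaults r_s = 0.5 and w_s = 1.0 are the selected optimum: half the
tokens masked, and all weight on the substitution component (so context
predictions receive zero gradient). Substitution positions are replaced
purely by [MASK] — no BERT-style 80/10/10 random/keep mixture.

Optimization is AdamW (weight decay 1e-5) under a one-cycle learning-rate
schedule with a default peak of 1e-4, with global gradient-norm clipping.
Fresh random frame offsets are drawn per sequence each epoch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from barcodelm import autodiff as ad
from barcodelm.autodiff import Tensor
from barcodelm.encoder import EncoderConfig, TransformerEncoder
from barcodelm.tokenizers import KmerTokenizer, TokenizedBatch


@dataclass(frozen=True)
class MaskingConfig:
    substitution_ratio: float = 0.5   # r_s: fraction of valid tokens masked
    substitution_weight: float = 1.0  # w_s: loss weight of the masked group
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_ratio <= 1.0:
            raise ValueError(f"substitution_ratio must be in [0,1], got {self.substitution_ratio}")
        if not 0.0 <= self.substitution_weight <= 1.0:
            raise ValueError(f"substitution_weight must be in [0,1], got {self.substitution_weight}")


@dataclass
class MaskingPlan:
    """Boolean (n, T) matrix: True at substitution positions.

    Substitution positions are a subset of valid positions; the complement
    within the valid positions is the context set.
    """

    substitution: np.ndarray
    validity_mask: np.ndarray

    @property
    def context(self) -> np.ndarray:
        return self.validity_mask & ~self.substitution


@dataclass(frozen=True)
class OptimConfig:
    max_lr: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 10
    batch_size: int = 64
    pct_start: float = 0.3
    grad_clip: float = 1.0


def make_masking_plan(
    validity_mask: np.ndarray, config: MaskingConfig, rng: np.random.Generator
) -> MaskingPlan:
    """Sample floor(r_s * n_valid) substitution positions per sequence."""
    sub = np.zeros_like(validity_mask, dtype=bool)
    for i in range(validity_mask.shape[0]):
        valid_idx = np.nonzero(validity_mask[i])[0]
        if valid_idx.size == 0:
            raise ValueError(f"sequence at row {i} has no valid positions")
        n_sub = int(config.substitution_ratio * valid_idx.size)
        if n_sub > 0:
            chosen = rng.choice(valid_idx, size=n_sub, replace=False)
            sub[i, chosen] = True
    return MaskingPlan(substitution=sub, validity_mask=validity_mask.copy())


def apply_mask(
    token_ids: np.ndarray, plan: MaskingPlan, mask_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Replace substitution positions by [MASK]; targets are the originals.

    Context positions keep their input token but are still predicted
    (input reconstruction); the loss decides how much they weigh.
    """
    masked = token_ids.copy()
    masked[plan.substitution] = mask_id
    return masked, token_ids.copy()


def weighted_mlm_loss(
    logits: Tensor | np.ndarray,
    targets: np.ndarray,
    plan: MaskingPlan,
    w_s: float,
) -> Tensor:
    """w_s * meanCE(substitution) + (1 - w_s) * meanCE(context).

    Each component is the mean cross-entropy over its own position set; an
    empty component contributes 0. With w_s = 1 the loss — and its
    gradient — is exactly invariant to the logits at context positions.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    sub, ctx = plan.substitution, plan.context
    n_sub, n_ctx = int(sub.sum()), int(ctx.sum())
    if n_sub == 0 and n_ctx == 0:
        raise ValueError("both loss components are empty")
    weights = np.zeros(targets.shape, dtype=np.float64)
    if n_sub > 0 and w_s != 0.0:
        weights[sub] = w_s / n_sub
    if n_ctx > 0 and w_s != 1.0:
        weights[ctx] = (1.0 - w_s) / n_ctx
    return ad.weighted_cross_entropy(logits, targets, weights)


def _sparse_mlm_loss(
    model: TransformerEncoder,
    hidden: Tensor,
    targets: np.ndarray,
    plan: MaskingPlan,
    w_s: float,
) -> Tensor:
    """Same value and gradient as ``weighted_mlm_loss`` over the full logits,
    but the prediction head runs only on positions with nonzero loss weight
    (all padding, and all context positions when w_s = 1, are skipped)."""
    sub, ctx = plan.substitution, plan.context
    n_sub, n_ctx = int(sub.sum()), int(ctx.sum())
    if n_sub == 0 and n_ctx == 0:
        raise ValueError("both loss components are empty")
    active = np.zeros_like(sub)
    weights_full = np.zeros(targets.shape, dtype=np.float64)
    if n_sub > 0 and w_s != 0.0:
        active |= sub
        weights_full[sub] = w_s / n_sub
    if n_ctx > 0 and w_s != 1.0:
        active |= ctx
        weights_full[ctx] = (1.0 - w_s) / n_ctx
    rows, cols = np.nonzero(active)
    gathered = ad.take_rows(hidden, rows, cols)
    logits = gathered @ model.params["head_w"] + model.params["head_b"]
    return ad.weighted_cross_entropy(logits, targets[rows, cols], weights_full[rows, cols])


def masked_token_accuracy(
    logits: np.ndarray, targets: np.ndarray, plan: MaskingPlan
) -> float:
    """Fraction of substitution positions whose argmax prediction is correct."""
    sub = plan.substitution
    if sub.sum() == 0:
        return float("nan")
    pred = logits[sub].argmax(axis=-1)
    return float((pred == targets[sub]).mean())


def pretrain(
    sequences: Sequence[str],
    tokenizer: KmerTokenizer,
    encoder_config: EncoderConfig,
    masking_config: MaskingConfig | None = None,
    optim_config: OptimConfig | None = None,
    seed: int = 0,
    checkpoint_path: str | Path | None = None,
    loss_log_path: str | Path | None = None,
) -> tuple[TransformerEncoder, list[float]]:
    """Masked-token pretraining over cleaned barcode sequences.

    Returns the trained encoder and the per-step loss trace. Fully
    deterministic for a fixed seed: model init, per-epoch shuffling, frame
    offsets and masking plans all derive from it.

    Raises
    ------
    RuntimeError
        On divergence (non-finite loss).
    """
    if not sequences:
        raise ValueError("pretraining corpus is empty")
    masking_config = masking_config or MaskingConfig()
    optim_config = optim_config or OptimConfig()

    model = TransformerEncoder(encoder_config, seed=seed)
    opt = ad.AdamW(
        model.parameters(),
        lr=optim_config.max_lr,
        weight_decay=optim_config.weight_decay,
    )
    n = len(sequences)
    bs = optim_config.batch_size
    steps_per_epoch = (n + bs - 1) // bs
    total_steps = steps_per_epoch * optim_config.epochs
    trace: list[float] = []
    step = 0
    for epoch in range(optim_config.epochs):
        # fresh augmentation each pass: offsets/masks seeded per epoch
        rng = np.random.default_rng([seed, epoch])
        order = rng.permutation(n)
        for start in range(0, n, bs):
            chunk = [sequences[i] for i in order[start : start + bs]]
            batch = tokenizer.batch(chunk, rng=rng)
            plan = make_masking_plan(batch.validity_mask, masking_config, rng)
            masked_ids, targets = apply_mask(batch.token_ids, plan, tokenizer.mask_id)
            masked_batch = TokenizedBatch(
                masked_ids, batch.validity_mask, batch.offsets, batch.pad_id
            )
            hidden = model.encode(masked_batch, rng=rng)  # rng enables dropout
            loss = _sparse_mlm_loss(
                model, hidden, targets, plan, masking_config.substitution_weight
            )
            loss_value = float(loss.data)
            if not np.isfinite(loss_value):
                raise RuntimeError(
                    f"pretraining diverged at step {step}: loss={loss_value}"
                )
            trace.append(loss_value)
            opt.zero_grad()
            loss.backward()
            ad.clip_grad_norm(model.parameters(), optim_config.grad_clip)
            opt.lr = ad.one_cycle_lr(
                step, total_steps, optim_config.max_lr, optim_config.pct_start
            )
            opt.step()
            step += 1
    if loss_log_path is not None:
        with open(loss_log_path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["step", "loss"])
            writer.writerows(enumerate(trace))
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model, trace
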