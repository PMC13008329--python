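"""Masking plans, the weighted substitution/context loss, and toy pretraining."""

import numpy as np
import pytest

from barcodelm import autodiff as ad
from barcodelm.encoder import EncoderConfig, TransformerEncoder
from barcodelm.pretrain import (
    MaskingConfig,
    OptimConfig,
    _sparse_mlm_loss,
    apply_mask,
    make_masking_plan,
    masked_token_accuracy,
    pretrain,
    weighted_mlm_loss,
)
from barcodelm.tokenizers import KmerTokenizer, TokenizedBatch


def full_mask(n, T):
    return np.ones((n, T), dtype=bool)


class TestMaskingPlan:
    @pytest.mark.parametrize(
        "r_s, n_valid, expected",
        [(0.5, 10, 5), (0.0, 10, 0), (1.0, 10, 10), (0.5, 165, 82), (0.3, 7, 2)],
    )
    def test_floor_count(self, r_s, n_valid, expected, rng):
        mask = full_mask(1, n_valid)
        plan = make_masking_plan(mask, MaskingConfig(substitution_ratio=r_s), rng)
        assert plan.substitution.sum() == expected

    def test_only_valid_positions(self, rng):
        mask = np.zeros((3, 12), dtype=bool)
        mask[:, :7] = True
        plan = make_masking_plan(mask, MaskingConfig(), rng)
        assert not np.any(plan.substitution & ~mask)
        assert np.all(plan.substitution.sum(axis=1) == 3)  # floor(0.5 * 7)
        # context is the complement within valid positions
        assert np.all((plan.substitution | plan.context) == mask)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="substitution_ratio"):
            MaskingConfig(substitution_ratio=1.5)

    def test_aggregate_masked_fraction(self, rng):
        mask = full_mask(200, 165)
        plan = make_masking_plan(mask, MaskingConfig(), rng)
        frac = plan.substitution.sum() / mask.sum()
        assert frac == pytest.approx(82 / 165)


class TestApplyMask:
    def test_definition(self, rng):
        ids = np.array([[11, 22, 33]])
        plan = make_masking_plan(full_mask(1, 3), MaskingConfig(substitution_ratio=0.0), rng)
        plan.substitution[0, 0] = True
        masked, targets = apply_mask(ids, plan, mask_id=99)
        assert masked.tolist() == [[99, 22, 33]]
        assert targets.tolist() == [[11, 22, 33]]

    def test_empty_and_full_plans(self, rng):
        ids = np.arange(8).reshape(2, 4)
        empty = make_masking_plan(full_mask(2, 4), MaskingConfig(substitution_ratio=0.0), rng)
        masked, _ = apply_mask(ids, empty, mask_id=99)
        assert np.array_equal(masked, ids)
        full = make_masking_plan(full_mask(2, 4), MaskingConfig(substitution_ratio=1.0), rng)
        masked, targets = apply_mask(ids, full, mask_id=99)
        assert np.all(masked == 99)
        assert np.array_equal(targets, ids)


class TestWeightedLoss:
    def _plan(self, sub_positions, T=4, rng=None):
        validity = full_mask(1, T)
        plan = make_masking_plan(validity, MaskingConfig(substitution_ratio=0.0),
                                 rng or np.random.default_rng(0))
        for p in sub_positions:
            plan.substitution[0, p] = True
        return plan

    def test_ws1_invariant_to_context_logits(self, rng):
        plan = self._plan([0, 2], T=4)
        targets = np.array([[1, 0, 2, 3]])
        logits = rng.normal(size=(1, 4, 5)).astype(np.float32)
        base = weighted_mlm_loss(logits, targets, plan, w_s=1.0)
        perturbed = logits.copy()
        perturbed[0, 1] += 100.0
        perturbed[0, 3] -= 7.0
        after = weighted_mlm_loss(perturbed, targets, plan, w_s=1.0)
        assert float(base.data) == float(after.data)

    def test_ws1_zero_gradient_at_context(self, rng):
        plan = self._plan([1], T=3)
        targets = np.array([[0, 1, 2]])
        logits = ad.parameter(rng.normal(size=(1, 3, 4)).astype(np.float32))
        loss = weighted_mlm_loss(logits, targets, plan, w_s=1.0)
        loss.backward()
        assert np.all(logits.grad[0, 0] == 0.0)
        assert np.all(logits.grad[0, 2] == 0.0)
        assert np.any(logits.grad[0, 1] != 0.0)

    def test_single_substitution_closed_form(self):
        plan = self._plan([0], T=1)
        targets = np.array([[2]])
        logits = np.log(np.array([[[0.1, 0.2, 0.6, 0.1]]], dtype=np.float32))
        loss = weighted_mlm_loss(logits, targets, plan, w_s=1.0)
        assert float(loss.data) == pytest.approx(-np.log(0.6), rel=1e-5)

    def test_convex_combination(self, rng):
        # both components equal value c -> loss = c for any w_s
        plan = self._plan([0], T=2)
        targets = np.array([[1, 1]])
        logits = np.tile(rng.normal(size=(1, 1, 6)).astype(np.float32), (1, 2, 1))
        c = float(weighted_mlm_loss(logits, targets, plan, w_s=1.0).data)
        half = float(weighted_mlm_loss(logits, targets, plan, w_s=0.5).data)
        assert half == pytest.approx(c, rel=1e-6)

    def test_mean_within_each_component(self, rng):
        plan = self._plan([0, 1], T=4)
        targets = np.array([[0, 1, 2, 3]])
        logits = rng.normal(size=(1, 4, 5)).astype(np.float32)

        def ce(pos):
            z = logits[0, pos] - logits[0, pos].max()
            return -(z[targets[0, pos]] - np.log(np.exp(z).sum()))

        expected = 0.7 * np.mean([ce(0), ce(1)]) + 0.3 * np.mean([ce(2), ce(3)])
        loss = weighted_mlm_loss(logits, targets, plan, w_s=0.7)
        assert float(loss.data) == pytest.approx(expected, rel=1e-5)

    def test_empty_components_error(self, rng):
        validity = np.zeros((1, 3), dtype=bool)
        plan = make_masking_plan(full_mask(1, 3), MaskingConfig(substitution_ratio=0.0), rng)
        plan.validity_mask = validity
        plan.substitution = np.zeros((1, 3), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            weighted_mlm_loss(np.zeros((1, 3, 4), dtype=np.float32),
                              np.zeros((1, 3), dtype=np.int64), plan, w_s=0.5)

    def test_sparse_path_matches_full_logits(self, rng):
        """The trainer's gathered-head loss equals the reference formula."""
        tk = KmerTokenizer(k=4)
        cfg = EncoderConfig(vocab_size=tk.vocab_size, max_positions=tk.max_tokens,
                            num_layers=1, num_heads=2, model_dim=16)
        model = TransformerEncoder(cfg, seed=0)
        batch = tk.batch(["ACGTACGTACGTACGTAAGG", "TTGACA" * 8])
        plan = make_masking_plan(batch.validity_mask, MaskingConfig(), rng)
        masked, targets = apply_mask(batch.token_ids, plan, tk.mask_id)
        mb = TokenizedBatch(masked, batch.validity_mask, batch.offsets, batch.pad_id)
        for w_s in (1.0, 0.4):
            full = weighted_mlm_loss(
                model.mlm_logits(model.encode(mb)), targets, plan, w_s
            )
            sparse = _sparse_mlm_loss(model, model.encode(mb), targets, plan, w_s)
            assert float(sparse.data) == pytest.approx(float(full.data), rel=1e-5)


@pytest.fixture(scope="module")
def toy_run():
    rng = np.random.default_rng(0)
    root = rng.choice(list("ACGT"), size=240)
    seqs = []
    for _ in range(60):  # correlated corpus: mutated copies of one root
        seq = root.copy()
        hit = rng.random(240) < 0.05
        seq[hit] = rng.choice(list("ACGT"), size=hit.sum())
        seqs.append("".join(seq))
    tk = KmerTokenizer(k=4)
    cfg = EncoderConfig(vocab_size=tk.vocab_size, max_positions=tk.max_tokens,
                        num_layers=1, num_heads=2, model_dim=32)
    model, trace = pretrain(
        seqs, tk, cfg,
        MaskingConfig(),
        OptimConfig(max_lr=1e-2, epochs=8, batch_size=16),
        seed=4,
    )
    return seqs, tk, cfg, model, trace


class TestPretrain:

    def test_initial_loss_near_log_vocab(self, toy_run):
        _, tk, _, _, trace = toy_run
        assert trace[0] == pytest.approx(np.log(4**4 + 2), rel=0.1)

    def test_loss_decreases(self, toy_run):
        _, _, _, _, trace = toy_run
        assert trace[-1] < 0.7 * trace[0]

    def test_masked_accuracy_above_chance(self, toy_run):
        seqs, tk, _, model, _ = toy_run
        rng = np.random.default_rng(123)
        batch = tk.batch(seqs)
        plan = make_masking_plan(batch.validity_mask, MaskingConfig(), rng)
        masked, targets = apply_mask(batch.token_ids, plan, tk.mask_id)
        mb = TokenizedBatch(masked, batch.validity_mask, batch.offsets, batch.pad_id)
        logits = model.mlm_logits(model.encode(mb)).data
        acc = masked_token_accuracy(logits, targets, plan)
        assert acc > 5 / (4**4 + 2)

    def test_determinism_same_seed(self, toy_run):
        seqs, tk, cfg, _, trace = toy_run
        _, trace2 = pretrain(
            seqs, tk, cfg, MaskingConfig(),
            OptimConfig(max_lr=1e-2, epochs=8, batch_size=16), seed=4,
        )
        np.testing.assert_array_equal(trace, trace2)

    def test_empty_corpus_rejected(self):
        tk = KmerTokenizer(k=4)
        cfg = EncoderConfig(vocab_size=tk.vocab_size, max_positions=tk.max_tokens)
        with pytest.raises(ValueError, match="empty"):
            pretrain([], tk, cfg)

    def test_checkpoint_and_log_written(self, toy_run, tmp_path):
        seqs, tk, cfg, _, _ = toy_run
        ckpt = tmp_path / "model.zip"
        log = tmp_path / "loss.csv"
        pretrain(
            seqs[:16], tk, cfg, MaskingConfig(),
            OptimConfig(max_lr=1e-3, epochs=1, batch_size=16),
            seed=0, checkpoint_path=ckpt, loss_log_path=log,
        )
        assert ckpt.exists()
        header, first = log.read_text().splitlines()[:2]
        assert header == "step,loss"
        assert float(first.split(",")[1]) > 0
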