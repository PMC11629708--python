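"""Self-supervised objective contracts: masking, MLM closed forms, SimSiam
stop-gradient, triplet construction/hinge, and the margin schedule."""

import math

import numpy as np
import pytest

from pocketdti.autograd import Tensor
from pocketdti.contrastive import (
    MarginSchedule,
    SiamBranch,
    _neg_cosine,
    build_triplets,
    margin,
    mask_tokens,
    mlm_loss,
    simsiam_loss,
    triplet_loss,
)
from pocketdti.io_featurize import MASK_ID, PROTEIN_VOCAB_SIZE, repeat_pad


class TestMaskTokens:
    def test_expected_mask_count(self):
        rp = repeat_pad("ACDEFGHIKL")  # 192 copies x 10 residues = 1920 real
        mb = mask_tokens(rp, rate=0.15, seed=0)
        n = len(mb.mask_positions)
        # binomial(1920, 0.15): mean 288, sd ~15.6; allow 5 sigma
        assert 210 < n < 370
        assert np.all(mb.tokens[mb.mask_positions] == MASK_ID)
        assert np.all(mb.labels == rp.tokens[mb.mask_positions])

    def test_seeded_reproducibility(self):
        rp = repeat_pad("ACDEFGHIKLMNP")
        a = mask_tokens(rp, rate=0.2, seed=9)
        b = mask_tokens(rp, rate=0.2, seed=9)
        assert np.array_equal(a.mask_positions, b.mask_positions)
        assert np.array_equal(a.tokens, b.tokens)

    def test_rate_one_masks_every_real_position(self):
        rp = repeat_pad("ACDEF")
        mb = mask_tokens(rp, rate=1.0, seed=0)
        assert len(mb.mask_positions) == rp.copy_count * 5
        assert not np.any(mb.tokens[mb.mask_positions] != MASK_ID)

    def test_pad_positions_never_masked(self):
        rp = repeat_pad("ACDEF")
        mb = mask_tokens(rp, rate=1.0, seed=0)
        assert np.all(rp.tokens[mb.mask_positions] != 0)


class TestMLMLoss:
    def one_hot_logits(self, labels, scale=100.0):
        logits = np.full((len(labels), PROTEIN_VOCAB_SIZE), -scale, np.float32)
        logits[np.arange(len(labels)), labels] = scale
        return Tensor(logits)

    def test_perfect_predictions_zero(self):
        labels = np.array([1, 5, 9, 20])
        lg = self.one_hot_logits(labels)
        assert mlm_loss(lg, lg, labels).item() < 1e-5

    def test_uniform_predictions_log_vocab(self):
        labels = np.array([1, 2, 3])
        uniform = Tensor(np.zeros((3, PROTEIN_VOCAB_SIZE), np.float32))
        loss = mlm_loss(uniform, uniform, labels).item()
        assert math.isclose(loss, math.log(25.0), rel_tol=1e-5)

    def test_mixed_paths_average(self):
        labels = np.array([4, 7])
        perfect = self.one_hot_logits(labels)
        uniform = Tensor(np.zeros((2, PROTEIN_VOCAB_SIZE), np.float32))
        loss = mlm_loss(perfect, uniform, labels).item()
        assert math.isclose(loss, math.log(25.0) / 2.0, rel_tol=1e-4)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mlm_loss(Tensor(np.zeros((2, 25))), Tensor(np.zeros((2, 25))),
                     np.array([1, 2, 3]))


class TestSimSiam:
    def test_negative_cosine_identical_unit_vectors(self):
        v = Tensor(np.array([[0.6, 0.8]], np.float32), requires_grad=True)
        loss = _neg_cosine(v, Tensor(np.array([[0.6, 0.8]], np.float32)))
        assert math.isclose(loss.item(), -1.0, rel_tol=1e-6)

    def test_negative_cosine_orthogonal(self):
        a = Tensor(np.array([[1.0, 0.0]], np.float32), requires_grad=True)
        b = Tensor(np.array([[0.0, 1.0]], np.float32))
        assert abs(_neg_cosine(a, b).item()) < 1e-7

    def test_zero_norm_input_rejected(self):
        branch = SiamBranch(3, 3, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            simsiam_loss(np.zeros((1, 3), np.float32),
                         np.ones((1, 3), np.float32), branch)

    def test_loss_bounded(self, rng):
        branch = SiamBranch(8, 8, 8, np.random.default_rng(0))
        e = rng.standard_normal((6, 8)).astype(np.float32)
        m = rng.standard_normal((6, 8)).astype(np.float32)
        loss = simsiam_loss(e, m, branch).item()
        assert -1.0 - 1e-6 <= loss <= 1.0 + 1e-6

    def test_stop_gradient_is_exactly_zero(self, rng):
        """Parameters feeding only the starred (detached) operand get a
        gradient of exactly zero — here: the m-projection under the first
        loss term alone."""
        branch = SiamBranch(8, 8, 8, np.random.default_rng(0))
        e = Tensor(rng.standard_normal((4, 8)).astype(np.float32))
        m = Tensor(rng.standard_normal((4, 8)).astype(np.float32))
        term = _neg_cosine(branch.predictor(branch.proj_e(e)),
                           branch.proj_m(m).detach())
        term.backward()
        for prm in branch.proj_m.parameters():
            assert prm.grad is None
        assert any(prm.grad is not None for prm in branch.proj_e.parameters())

    def test_no_representation_collapse_under_training(self, rng):
        """50 optimisation steps of the SimSiam objective alone must not
        collapse the batch to a single point (stop-gradient contract)."""
        from pocketdti.nn import Adam

        branch = SiamBranch(8, 8, 8, np.random.default_rng(1))
        e = Tensor(rng.standard_normal((16, 8)).astype(np.float32),
                   requires_grad=True)
        m = Tensor(rng.standard_normal((16, 8)).astype(np.float32),
                   requires_grad=True)
        optim = Adam(branch.parameters() + [e, m], lr=1e-3)
        for _ in range(50):
            optim.zero_grad()
            loss = simsiam_loss(e, m, branch)
            loss.backward()
            optim.step()
        proj = branch.proj_e(e.detach()).data
        assert proj.std(axis=0).mean() > 1e-3


class TestTriplets:
    def test_exhaustive_two_by_two(self, rng):
        pv = rng.standard_normal((2, 4)).astype(np.float32)
        dv = rng.standard_normal((2, 4)).astype(np.float32)
        inter = np.array([[1, 0], [0, 1]])
        tb = build_triplets(pv, dv, inter, seed=0)
        assert tb.n_triplets == 2
        # forced choices: anchor 0 -> (d0 positive, d1 negative); anchor 1 mirrored
        assert np.allclose(tb.positives.data[0], dv[0])
        assert np.allclose(tb.negatives.data[0], dv[1])
        assert np.allclose(tb.positives.data[1], dv[1])
        assert np.allclose(tb.negatives.data[1], dv[0])

    def test_anchor_without_negative_skipped(self, rng):
        pv = rng.standard_normal((2, 4)).astype(np.float32)
        dv = rng.standard_normal((2, 4)).astype(np.float32)
        inter = np.array([[1, 1], [1, 0]])  # first protein has no negative
        tb = build_triplets(pv, dv, inter, seed=0)
        assert tb.n_triplets == 1

    def test_empty_batch(self, rng):
        tb = build_triplets(rng.standard_normal((1, 4)),
                            rng.standard_normal((1, 4)),
                            np.array([[1]]), seed=0)
        assert tb.n_triplets == 0

    def test_seeded_sampling_stable(self, rng):
        pv = rng.standard_normal((4, 4)).astype(np.float32)
        dv = rng.standard_normal((6, 4)).astype(np.float32)
        inter = (rng.random((4, 6)) < 0.5).astype(int)
        a = build_triplets(pv, dv, inter, seed=11)
        b = build_triplets(pv, dv, inter, seed=11)
        assert np.array_equal(a.positives.data, b.positives.data)
        assert np.array_equal(a.negatives.data, b.negatives.data)


class TestTripletLoss:
    def make_tb(self, a, p, n):
        from pocketdti.contrastive import TripletBatch

        return TripletBatch(anchors=Tensor(np.asarray(a, np.float32)),
                            positives=Tensor(np.asarray(p, np.float32)),
                            negatives=Tensor(np.asarray(n, np.float32)),
                            anchor_ids=list(range(len(a))))

    def test_satisfied_margin_zero_loss(self):
        tb = self.make_tb([[0.0, 0.0]], [[0.0, 0.0]], [[2.0, 0.0]])
        assert triplet_loss(tb, 1.0).item() < 1e-5

    def test_degenerate_triplet_returns_margin(self):
        v = [[1.0, 2.0]]
        tb = self.make_tb(v, v, v)
        assert math.isclose(triplet_loss(tb, 0.5).item(), 0.5, rel_tol=1e-5)

    def test_matches_per_triplet_loop(self, rng):
        a = rng.standard_normal((50, 8)).astype(np.float32)
        p = rng.standard_normal((50, 8)).astype(np.float32)
        n = rng.standard_normal((50, 8)).astype(np.float32)
        m = 0.7
        tb = self.make_tb(a, p, n)
        oracle = np.mean([
            max(np.linalg.norm(a[i] - p[i]) - np.linalg.norm(a[i] - n[i]) + m, 0.0)
            for i in range(50)
        ])
        assert math.isclose(triplet_loss(tb, m).item(), oracle, rel_tol=1e-5)

    def test_invalid_inputs(self):
        tb = self.make_tb([[1.0]], [[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            triplet_loss(tb, -0.1)


class TestMarginSchedule:
    def test_cycle_start_value(self):
        sched = MarginSchedule(m_max=1.0, n_re=10)
        expected = 1.0 - math.tanh(2.0)
        assert math.isclose(margin(0, sched), expected, rel_tol=1e-9)
        assert math.isclose(margin(10, sched), expected, rel_tol=1e-9)
        assert math.isclose(expected, 0.03597, abs_tol=1e-5)

    def test_monotone_within_cycle(self):
        sched = MarginSchedule(m_max=2.0, n_re=12)
        values = [margin(t, sched) for t in range(12)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_periodicity(self):
        sched = MarginSchedule(m_max=1.5, n_re=7)
        for t in range(30):
            assert math.isclose(margin(t, sched), margin(t + 7, sched),
                                rel_tol=1e-12)

    def test_range_invariant(self):
        for m_max in (0.5, 1.0, 3.0):
            sched = MarginSchedule(m_max=m_max, n_re=9)
            for t in range(40):
                v = margin(t, sched)
                assert m_max * (1 - math.tanh(2)) - 1e-9 <= v < m_max

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            MarginSchedule(m_max=1.0, n_re=0)
        with pytest.raises(ValueError):
            MarginSchedule(m_max=-1.0, n_re=5)
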