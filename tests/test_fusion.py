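"""Fusion contracts: co-attention stochasticity and masking, paired-stream
symmetry and residual identity, gating, prediction head and the BCE loss."""

import math

import numpy as np
import pytest

from pocketdti.autograd import Tensor
from pocketdti.fusion import PGCA, PMMA, FinalFusion, PredictionHead, bce_loss


def rand(rng, *shape):
    return Tensor(rng.standard_normal(shape).astype(np.float32))


class TestPGCA:
    def test_attention_rows_stochastic(self, rng):
        pgca = PGCA(16, 2, np.random.default_rng(0))
        pockets = rand(rng, 3, 256, 16)
        drug = rand(rng, 3, 20, 16)
        mask = np.ones((3, 20), np.float32)
        mask[:, 15:] = 0.0
        f_mixed, attn = pgca(pockets, drug, mask)
        assert f_mixed.shape == (3, 256, 16)
        sums = attn.data.sum(axis=-1)
        assert np.abs(sums - 1.0).max() < 1e-5

    def test_masked_tokens_get_zero_weight(self, rng):
        pgca = PGCA(16, 2, np.random.default_rng(0))
        mask = np.ones((1, 10), np.float32)
        mask[:, 4:] = 0.0
        _, attn = pgca(rand(rng, 1, 256, 16), rand(rng, 1, 10, 16), mask)
        assert np.all(attn.data[..., 4:] == 0.0)

    def test_single_real_token_closed_form(self, rng):
        h = 16
        pgca = PGCA(h, 2, np.random.default_rng(0))
        token = rng.standard_normal((1, 1, h)).astype(np.float32)
        pockets = rand(rng, 1, 256, h)
        f_coattn, attn = pgca.coattn(pockets, Tensor(token), Tensor(token),
                                     key_mask=np.ones((1, 1), np.float32))
        assert np.allclose(attn.data, 1.0, atol=1e-6)
        expected = (token.reshape(1, h) @ pgca.coattn.wv.weight.data
                    @ pgca.coattn.wo.weight.data + pgca.coattn.wo.bias.data)
        # every pocket row equals the projected single value vector
        assert np.allclose(f_coattn.data[0], expected, atol=1e-5)

    def test_width_mismatch_and_empty_mask_errors(self, rng):
        pgca = PGCA(16, 2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="width"):
            pgca(rand(rng, 1, 256, 16), rand(rng, 1, 5, 8),
                 np.ones((1, 5), np.float32))
        with pytest.raises(ValueError, match="unmasked"):
            pgca(rand(rng, 1, 256, 16), rand(rng, 1, 5, 16),
                 np.zeros((1, 5), np.float32))


class TestPMMA:
    def test_shapes(self, rng):
        pmma = PMMA(16, 2, np.random.default_rng(0))
        f_e, f_m = pmma(rand(rng, 2, 256, 16), rand(rng, 2, 256, 16))
        assert f_e.shape == (2, 256, 16) and f_m.shape == (2, 256, 16)

    def test_residual_identity_at_zero_init(self, rng):
        pmma = PMMA(16, 2, np.random.default_rng(0), zero_init_residual=True)
        a, b = rand(rng, 1, 256, 16), rand(rng, 1, 256, 16)
        f_e, f_m = pmma(a, b)
        assert np.array_equal(f_e.data, a.data)
        assert np.array_equal(f_m.data, b.data)

    def test_stream_swap_symmetry(self, rng):
        pmma = PMMA(16, 2, np.random.default_rng(3), zero_init_residual=False)
        a, b = rand(rng, 1, 256, 16), rand(rng, 1, 256, 16)
        f_e, f_m = pmma(a, b)
        # exchange the stream-labelled weights, then swap the inputs
        pmma.self_e, pmma.self_m = pmma.self_m, pmma.self_e
        pmma.cross_e, pmma.cross_m = pmma.cross_m, pmma.cross_e
        pmma.proj_e, pmma.proj_m = pmma.proj_m, pmma.proj_e
        g_e, g_m = pmma(b, a)
        assert np.allclose(g_e.data, f_m.data, atol=1e-6)
        assert np.allclose(g_m.data, f_e.data, atol=1e-6)


class TestFinalFusion:
    def test_gate_weights_sum_to_one(self, rng):
        fuse = FinalFusion(16, np.random.default_rng(0))
        _, (g_e, g_m) = fuse(rand(rng, 4, 256, 16), rand(rng, 4, 256, 16))
        assert np.allclose(g_e.data + g_m.data, 1.0, atol=1e-6)

    def test_identical_streams_pass_through(self, rng):
        fuse = FinalFusion(16, np.random.default_rng(0))
        x = rand(rng, 2, 256, 16)
        f_final, _ = fuse(x, Tensor(x.data.copy()))
        mlp_out = fuse.mlp_e(x.layer_norm()) + x
        pooled = mlp_out.data.mean(axis=-2)
        assert np.allclose(f_final.data, pooled, atol=1e-5)

    def test_zero_init_mlp_residual_path(self, rng):
        # residual MLPs have zero-initialised output layers, so at init the
        # fused vector is a convex combination of the raw pooled streams
        fuse = FinalFusion(16, np.random.default_rng(1))
        a, b = rand(rng, 1, 256, 16), rand(rng, 1, 256, 16)
        f_final, (g_e, g_m) = fuse(a, b)
        expected = (a.data.mean(-2) * g_e.data + b.data.mean(-2) * g_m.data)
        assert np.allclose(f_final.data, expected, atol=1e-5)

    def test_cross_mode_shape(self, rng):
        fuse = FinalFusion(16, np.random.default_rng(0), mode="cross", n_heads=2)
        f_final, _ = fuse(rand(rng, 2, 256, 16), rand(rng, 2, 256, 16))
        assert f_final.shape == (2, 16)


class TestPredictionHead:
    def test_zero_logit_gives_half(self):
        head = PredictionHead(8, np.random.default_rng(0))
        for layer in head.mlp.layers:
            layer.weight.data[...] = 0.0
            layer.bias.data[...] = 0.0
        p = head(Tensor(np.ones((3, 8), np.float32)))
        assert np.allclose(p.data, 0.5)

    def test_output_open_interval_and_order(self, rng):
        head = PredictionHead(8, np.random.default_rng(0))
        x = rand(rng, 50, 8)
        p = head(x)
        assert p.shape == (50,)
        assert np.all(p.data > 0) and np.all(p.data < 1)

    def test_monotone_in_logit(self):
        logits = np.linspace(-5, 5, 21)
        probs = 1.0 / (1.0 + np.exp(-logits))
        assert np.all(np.diff(probs) > 0)


class TestBCELoss:
    def test_half_probability_positive_label(self):
        loss = bce_loss(np.array([0.5]), np.array([1.0]))
        assert math.isclose(loss.item(), math.log(2.0), rel_tol=1e-5)

    def test_perfect_prediction_vanishes(self):
        loss = bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert loss.item() < 1e-5

    def test_sum_reduction_over_batch(self):
        loss = bce_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert math.isclose(loss.item(), 2.0 * math.log(2.0), rel_tol=1e-5)

    def test_mean_reduction_option(self):
        loss = bce_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]),
                        reduction="mean")
        assert math.isclose(loss.item(), math.log(2.0), rel_tol=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([1.5]), np.array([1.0]))
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([2.0]))


class TestEndToEndFusionContracts:
    def test_drug_atom_permutation_invariance(self, tiny_table):
        """Relabeling real atoms (features + adjacency) leaves p unchanged."""
        from pocketdti.model import DTIModel, ModelConfig

        table, _ = tiny_table
        model = DTIModel(ModelConfig(h=32, n_heads=2, d_plm=32, seed=11))
        model.eval()
        rec = table.records[0]
        cache = model.new_cache()
        cache.add_protein(rec.protein_id, rec.protein_seq)
        cache.add_drug(rec.drug_id, rec.drug_smiles)
        p0, _ = model.predict_record(rec, cache)

        feat = cache.drugs[rec.drug_id]
        rng = np.random.default_rng(0)
        perm = rng.permutation(feat.n_atoms)
        feat.atom_feats = feat.atom_feats[perm]
        feat.adj_norm = feat.adj_norm[np.ix_(perm, perm)]
        p1, _ = model.predict_record(rec, cache)
        assert abs(p0 - p1) < 1e-5

    def test_gradient_reaches_every_parameter(self, tiny_table):
        from pocketdti.fusion import bce_loss
        from pocketdti.model import DTIModel, ModelConfig

        table, _ = tiny_table
        model = DTIModel(ModelConfig(h=32, n_heads=2, d_plm=32, seed=5))
        cache = model.new_cache()
        cache.add_table(table)
        pids = sorted(table.protein_index)[:2]
        dids = sorted(table.drug_index)[:2]
        p, _, aux = model.forward_pairs(cache, pids, dids, [0, 0, 1, 1],
                                        [0, 1, 0, 1])
        labels = np.array([1, 0, 0, 1], np.float32)
        loss = bce_loss(p, labels, reduction="mean")
        # add the self-supervised heads so their parameters receive gradient
        from pocketdti.contrastive import simsiam_loss
        loss = loss + simsiam_loss(aux["drug_pooled_e"], aux["drug_pooled_m"],
                                   model.siam)
        from pocketdti.contrastive import mask_tokens, mlm_loss
        from pocketdti.io_featurize import RepeatPaddedSequence
        pf = cache.proteins[pids[0]]
        mb = mask_tokens(RepeatPaddedSequence(pf.tokens, pf.copy_count,
                                              pf.source_length), seed=0)
        ls, lm = model.mlm_logits(mb.tokens[None], [mb.mask_positions])
        loss = loss + mlm_loss(ls, lm, mb.labels)
        loss.backward()
        params = model.parameters()
        disconnected = [i for i, prm in enumerate(params) if prm.grad is None]
        assert disconnected == []
        # zero-initialised residual branches legitimately pass zero gradient
        # to their upstream weights on the very first step; everything else
        # must receive a non-zero gradient
        nonzero = sum(bool(np.any(prm.grad)) for prm in params)
        assert nonzero / len(params) > 0.7

    def test_initial_forward_finite_and_calibrated(self, tiny_table):
        from pocketdti.model import DTIModel, ModelConfig

        table, _ = tiny_table
        model = DTIModel(ModelConfig(h=32, n_heads=2, d_plm=32, seed=2))
        model.eval()
        for rec in table.records[:6]:
            p, _ = model.predict_record(rec)
            assert np.isfinite(p)
            assert 0.01 < p < 0.99
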