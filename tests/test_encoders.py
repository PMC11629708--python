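"""Encoder contracts: pocket pooling, the protein CNN, the drug GCN, the
stand-in embedders and the adapter/feed-forward heads."""

import numpy as np
import pytest

from pocketdti.autograd import Tensor
from pocketdti.encoders import (
    DrugGCN,
    EmbedderSpec,
    ProjectionHeads,
    ProteinExtractor,
    StandInEmbedder,
    apply_heads,
    drug_gcn,
    embed_drug_plm,
    embed_protein_plm,
    normalized_adjacency,
    pocket_pool,
)
from pocketdti.io_featurize import (
    L_REP,
    PROTEIN_VOCAB_SIZE,
    repeat_pad,
    smiles_to_graph,
    trim_drug,
)


class TestPocketPool:
    def test_constant_rows(self):
        v = np.arange(16, dtype=np.float32)
        m = np.tile(v, (L_REP, 1))
        pooled = pocket_pool(m)
        assert pooled.shape == (256, 16)
        assert np.allclose(pooled, v, atol=1e-6)

    def test_matches_bruteforce_loop(self, rng):
        m = rng.standard_normal((L_REP, 32)).astype(np.float32)
        pooled = pocket_pool(m)
        oracle = np.stack([m[9 * k : 9 * k + 9].mean(axis=0) for k in range(256)])
        assert pooled.shape == (256, 32)
        assert np.allclose(pooled, oracle, atol=1e-6)

    def test_wrong_row_count(self):
        with pytest.raises(ValueError):
            pocket_pool(np.zeros((100, 8), dtype=np.float32))

    def test_linearity(self, rng):
        x = rng.standard_normal((L_REP, 8)).astype(np.float32)
        y = rng.standard_normal((L_REP, 8)).astype(np.float32)
        a, b = 2.5, -1.25
        lhs = pocket_pool(a * x + b * y)
        rhs = a * pocket_pool(x) + b * pocket_pool(y)
        assert np.allclose(lhs, rhs, atol=1e-5)


class TestStandInEmbedders:
    def test_protein_shape_and_determinism(self):
        spec = EmbedderSpec(name="standin-protein", width=24)
        rp = repeat_pad("ACDEFGHIKLMNPQRST")
        a = embed_protein_plm(rp, spec)
        b = embed_protein_plm(rp, spec)
        assert a.shape == (L_REP, 24)
        assert np.array_equal(a, b)

    def test_positionwise_single_residue_difference(self):
        spec = EmbedderSpec(name="standin-protein", width=16)
        s1, s2 = "ACDEFGHIKL", "ACDEFGHIKV"  # differ at the last residue
        e1 = embed_protein_plm(repeat_pad(s1), spec)
        e2 = embed_protein_plm(repeat_pad(s2), spec)
        diff_rows = np.nonzero(np.any(e1 != e2, axis=1))[0]
        # exactly one differing row per tiled copy
        assert len(diff_rows) == repeat_pad(s1).copy_count
        unit = len(s1) + 2
        assert all((r % unit) == len(s1) for r in diff_rows)

    def test_drug_embedding_pad_rows_zero(self):
        spec = EmbedderSpec(name="standin-drug", width=16)
        toks = trim_drug("CCO")
        emb = embed_drug_plm(toks, spec)
        assert emb.shape == (512, 16)
        assert not emb[3:].any()
        assert emb[:3].any()

    def test_missing_checkpoint_errors(self):
        with pytest.raises(FileNotFoundError):
            StandInEmbedder(EmbedderSpec(source="/no/such/ckpt.pt"),
                            PROTEIN_VOCAB_SIZE)


class TestProteinExtractor:
    def make(self, h=16, d=8, seed=0):
        return ProteinExtractor(h, d, np.random.default_rng(seed), h_lut=8)

    def test_shape_contract(self, rng):
        ex = self.make()
        x = Tensor(rng.standard_normal((L_REP, 8)).astype(np.float32))
        m = rng.standard_normal((L_REP, 8)).astype(np.float32)
        out = ex(x, m)
        assert out.shape == (L_REP, 16)

    def test_kernel_widths_are_3_6_9(self):
        ex = self.make()
        assert [c.kernel for c in ex.convs] == [3, 6, 9]

    def test_translation_covariance_with_frozen_norms(self, rng):
        ex = self.make()
        ex.eval()
        ex.freeze_norms()
        x = np.zeros((L_REP, 8), dtype=np.float32)
        block = rng.standard_normal((18, 8)).astype(np.float32)
        x[500:518] = block
        shifted = np.zeros_like(x)
        shifted[509:527] = block
        m = np.zeros((L_REP, 8), dtype=np.float32)
        a = ex(Tensor(x), m).data
        b = ex(Tensor(shifted), m).data
        # interior activations shift by exactly 9 positions
        assert np.allclose(a[480:540], b[489:549], atol=1e-5)

    def test_determinism(self, rng):
        tokens = np.ones(L_REP, dtype=np.int64)
        ex = self.make()
        ex.eval()
        ex.freeze_norms()
        m = rng.standard_normal((L_REP, 8)).astype(np.float32)
        x = ex.embed_tokens(tokens)
        out1 = ex(x, m).data
        out2 = ex(ex.embed_tokens(tokens), m).data
        assert np.array_equal(out1, out2)


class TestDrugGCN:
    def test_single_atom(self):
        gcn = DrugGCN(8, np.random.default_rng(0))
        g = smiles_to_graph("C")
        out = drug_gcn(gcn, g)
        assert out.shape == (512, 8)
        assert out.data[1:].sum() == 0.0  # virtual rows stay zero

    def test_zero_features_zero_biases_give_zero(self):
        gcn = DrugGCN(8, np.random.default_rng(0))
        for layer in [gcn.wt] + gcn.layers:
            layer.bias.data[...] = 0.0
        g = smiles_to_graph("CCO")
        feats = np.zeros((1, 3, 8), dtype=np.float32)
        adj = normalized_adjacency(g.adjacency[:3, :3].astype(np.float32))[None]
        out = gcn(Tensor(feats), adj, np.ones((1, 3), np.float32))
        assert np.allclose(out.data, 0.0)

    def test_permutation_equivariance(self, rng):
        from pocketdti.synthetic import FixtureSpec, generate_dataset

        table, _ = generate_dataset(FixtureSpec(n_drugs=20, n_proteins=1, seed=5))
        gcn = DrugGCN(16, np.random.default_rng(2))
        for smiles in table.drug_index.values():
            g = smiles_to_graph(smiles)
            n = g.real_node_count
            feats = g.node_features[:n].astype(np.float32)
            adj = g.adjacency[:n, :n].astype(np.float32)
            perm = rng.permutation(n)
            out = gcn(Tensor(feats[None]), normalized_adjacency(adj)[None],
                      np.ones((1, n), np.float32)).data[0]
            out_p = gcn(Tensor(feats[perm][None]),
                        normalized_adjacency(adj[np.ix_(perm, perm)])[None],
                        np.ones((1, n), np.float32)).data[0]
            assert np.allclose(out[perm], out_p, atol=1e-4)

    def test_asymmetric_adjacency_rejected(self):
        bad = np.array([[1, 1], [0, 1]], dtype=np.float32)
        with pytest.raises(ValueError, match="symmetric"):
            normalized_adjacency(bad)


class TestProjectionHeads:
    def test_adapter_identity_at_init(self, rng):
        heads = ProjectionHeads(12, 8, np.random.default_rng(0))
        x = rng.standard_normal((5, 12)).astype(np.float32)
        adapted = heads.adapter(Tensor(x))
        assert np.allclose(adapted.data, x, atol=1e-6)

    def test_output_width_h(self, rng):
        for d in (8, 24, 40):
            heads = ProjectionHeads(d, 16, np.random.default_rng(0))
            out = apply_heads(rng.standard_normal((7, d)).astype(np.float32), heads)
            assert out.shape == (7, 16)

    def test_adapter_parameter_budget(self):
        # adapter params must stay well under the embedder they adapt
        d, bottleneck = 64, 16
        heads = ProjectionHeads(d, 64, np.random.default_rng(0),
                                bottleneck=bottleneck)
        adapter_params = sum(int(np.prod(p.shape))
                             for p in heads.adapter.parameters())
        # the smallest realistic protein language model has ~8M parameters;
        # the adapter must stay far below the 10% mark against it
        assert adapter_params < 0.10 * 8_000_000
        # and match its structural size exactly
        assert adapter_params == 2 * d * bottleneck + d + bottleneck


class TestEncoderStack:
    def test_outputs_finite_on_random_inputs(self, rng, small_model, small_cache,
                                             tiny_table):
        table, _ = tiny_table
        pids = sorted(table.protein_index)[:2]
        dids = sorted(table.drug_index)[:3]
        tokens, plm = small_cache.protein_batch(pids)
        p_enc = small_model.encode_proteins(tokens, plm)
        x, adj, amask, tok_plm, tmask = small_cache.drug_batch(dids)
        d_enc = small_model.encode_drugs(x, adj, amask, tok_plm, tmask)
        for t in (p_enc["e_pocket"], p_enc["m_ff"], d_enc["e_d"], d_enc["m_ff_d"]):
            assert np.isfinite(t.data).all()

    def test_bit_stable_across_runs(self, tiny_table):
        from pocketdti.model import DTIModel, ModelConfig

        table, _ = tiny_table
        outs = []
        for _ in range(2):
            model = DTIModel(ModelConfig(h=32, n_heads=2, d_plm=32, seed=7))
            model.eval()
            p, _ = model.predict_record(table.records[0])
            outs.append(p)
        assert outs[0] == outs[1]
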